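"""Readers and writers for the flat-file interfaces of the pipeline.

Sequence formats (FASTA/FASTQ) go through Biopython. GFF3 is handled by a
light parser tailored to the two feature types the pipeline emits and
consumes (``region`` contig descriptors and ``gene`` features carrying
``gene_id`` / ``allele_species`` attributes); coordinates are 1-based
inclusive per the GFF3 standard. Tables are TSV with header rows, via
pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs with a constant placeholder quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffFeature:
    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)


def _fmt_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) if attrs else "."


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text and text != ".":
        for item in text.strip(";").split(";"):
            if "=" in item:
                key, val = item.split("=", 1)
                attrs[key.strip()] = val.strip()
    return attrs


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [f.seqid, f.source, f.type, str(f.start), str(f.end),
                     f.score, f.strand, f.phase, _fmt_attributes(f.attributes)]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            features.append(
                GffFeature(
                    seqid=parts[0], source=parts[1], type=parts[2],
                    start=int(parts[3]), end=int(parts[4]), score=parts[5],
                    strand=parts[6], phase=parts[7],
                    attributes=_parse_attributes(parts[8]),
                )
            )
    return features


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
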