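"""Tn-seq read processing: from junction reads to a QC'd insertion catalog.

Stages, in order: (1) junction detection — find the final 22 bp of the
transposon right arm in each read allowing up to two mismatches, and split
the read into barcode and genomic fragment; (2) barcode error collapsing —
remove off-by-one, then off-by-two, barcode satellites dominated by a much
more abundant neighbour; (3) fragment mapping — exact k-mer seeding plus
full-length Hamming verification against the hybrid genome, both strands;
(4) mapping classification — retain only barcodes whose reads support a
single strong location; (5) genic annotation from GFF3 features.

Every input read is accounted for exactly once in the QC tallies.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GffFeature

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Junction detection


@dataclass
class JunctionLayout:
    """Geometry of a junction read relative to the matched arm 22-mer.

    ``barcode_gap`` is the number of bases between the end of the barcode
    and the start of the matched 22-mer (spacer plus any arm bases upstream
    of the final 22).
    """

    barcode_length: int = 20
    barcode_gap: int = 0
    min_fragment_length: int = 30


@dataclass
class JunctionObservation:
    barcode: str
    genomic_fragment: str
    read_id: str


def _hamming_scan(read: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Hamming distance of ``probe`` at every offset of ``read`` (vectorised)."""
    n = read.size - probe.size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(read, probe.size)
    return (windows != probe).sum(axis=1)


def detect_junction(read: str, arm: str, read_id: str = "",
                    max_mismatches: int = 2,
                    layout: JunctionLayout | None = None
                    ) -> tuple[JunctionObservation | None, str]:
    """Split a read at the transposon right-arm terminus.

    Scans every alignment of the arm's final 22 bases against the read and
    accepts the leftmost offset with Hamming distance <= ``max_mismatches``.
    Returns ``(observation, "ok")`` or ``(None, reason)`` with reason in
    ``{"no_arm", "truncated"}``.
    """
    if layout is None:
        layout = JunctionLayout()
    if len(arm) < 22:
        raise ValueError("arm must be at least 22 bp")
    probe = np.frombuffer(arm[-22:].encode(), dtype=np.uint8)
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    dists = _hamming_scan(arr, probe)
    hits = np.flatnonzero(dists <= max_mismatches)
    if hits.size == 0:
        return None, "no_arm"
    h = int(hits[0])
    bc_end = h - layout.barcode_gap
    bc_start = bc_end - layout.barcode_length
    fragment = read[h + 22:]
    if bc_start < 0 or len(fragment) < layout.min_fragment_length:
        return None, "truncated"
    return JunctionObservation(read[bc_start:bc_end], fragment, read_id), "ok"


# ---------------------------------------------------------------------------
# Barcode error collapsing


def _neighbor_candidates(barcodes: list[str]) -> dict[str, list[str]]:
    """For each barcode, candidate neighbours at Hamming distance <= 2.

    Uses the shared-variant property: d(a, b) <= 2 iff a and b share a
    sequence at distance <= 1 from each.
    """
    variant_map: dict[str, list[int]] = defaultdict(list)
    variants_of: list[list[str]] = []
    for idx, bc in enumerate(barcodes):
        vs = [bc]
        for i in range(len(bc)):
            for b in "ACGT":
                if b != bc[i]:
                    vs.append(bc[:i] + b + bc[i + 1:])
        variants_of.append(vs)
        for v in vs:
            variant_map[v].append(idx)
    out: dict[str, list[str]] = {}
    for idx, bc in enumerate(barcodes):
        cand: set[int] = set()
        for v in variants_of[idx]:
            cand.update(variant_map[v])
        cand.discard(idx)
        out[bc] = [barcodes[j] for j in cand]
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def collapse_error_barcodes(barcode_counts: dict[str, int], distance: int = 1,
                            dominance_ratio: float = 10.0
                            ) -> tuple[dict[str, int], dict[str, int]]:
    """Remove barcodes dominated by an abundant near-neighbour.

    A barcode is eliminated iff some other barcode within Hamming distance
    ``distance`` has a read count >= ``dominance_ratio`` times its own.
    Elimination is simultaneous (every barcode is judged against the full
    input set) and is removal, not merging. Returns
    ``(retained, eliminated)`` count dicts.
    """
    if distance not in (1, 2):
        raise ValueError("distance must be 1 or 2")
    if dominance_ratio <= 1:
        raise ValueError("dominance_ratio must exceed 1")
    barcodes = list(barcode_counts)
    if not barcodes:
        return {}, {}
    neighbors = _neighbor_candidates(barcodes)
    retained, eliminated = {}, {}
    for bc in barcodes:
        count = barcode_counts[bc]
        dominated = False
        for other in neighbors[bc]:
            if _hamming(bc, other) <= distance and \
                    barcode_counts[other] >= dominance_ratio * count:
                dominated = True
                break
        (eliminated if dominated else retained)[bc] = count
    return retained, eliminated


def collapse_all(barcode_counts: dict[str, int], dominance_ratio: float = 10.0
                 ) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Off-by-one collapse, then off-by-two on the survivors."""
    kept1, elim1 = collapse_error_barcodes(barcode_counts, 1, dominance_ratio)
    kept2, elim2 = collapse_error_barcodes(kept1, 2, dominance_ratio)
    return kept2, elim1, elim2


# ---------------------------------------------------------------------------
# Fragment mapping


class GenomeIndex:
    """Exact k-mer index over the forward strand of every contig."""

    def __init__(self, genome: dict[str, str], k: int = 15):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.contig_lengths = {name: len(seq) for name, seq in self.genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((name, i))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _map_oriented(fragment: str, index: GenomeIndex, max_mismatches: int
                  ) -> list[tuple[str, int, int]]:
    """Candidate (contig, start0, mismatches) for one orientation."""
    k, L = index.k, len(fragment)
    # disjoint seeds guarantee detection up to len(offsets)-1 mismatches
    offsets = list(range(0, L - k + 1, k))
    if offsets and offsets[-1] != L - k:
        offsets.append(L - k)
    candidates: set[tuple[str, int]] = set()
    for off in offsets:
        for contig, pos in index.seed_hits(fragment[off:off + k]):
            start = pos - off
            if 0 <= start <= index.contig_lengths[contig] - L:
                candidates.add((contig, start))
    frag_arr = np.frombuffer(fragment.encode(), dtype=np.uint8)
    hits = []
    for contig, start in candidates:
        ref = np.frombuffer(index.genome[contig][start:start + L].encode(),
                            dtype=np.uint8)
        mm = int((ref != frag_arr).sum())
        if mm <= max_mismatches:
            hits.append((contig, start, mm))
    return hits


def map_fragment(fragment: str, index: GenomeIndex, max_map_mismatches: int = 2
                 ) -> list[tuple[str, int, str, int]]:
    """Map a genomic fragment to candidate insertion locations.

    Returns ``(contig, insertion_position, strand, score)`` tuples with
    score = matched bases minus mismatches; the insertion position is the
    1-based coordinate, on the reference strand, of the first genomic base
    3' of the transposon arm. Both strands are searched; fragments shorter
    than k are rejected with ``ValueError``.
    """
    L = len(fragment)
    if L < index.k:
        raise ValueError(f"fragment shorter than k={index.k}")
    out = []
    for contig, start, mm in _map_oriented(fragment, index, max_map_mismatches):
        out.append((contig, start + 1, "+", L - 2 * mm))
    rc = revcomp(fragment)
    for contig, start, mm in _map_oriented(rc, index, max_map_mismatches):
        out.append((contig, start + L, "-", L - 2 * mm))
    out.sort(key=lambda h: (-h[3], h[0], h[1], h[2]))
    return out


# ---------------------------------------------------------------------------
# Mapping classification


def classify_mapping(observations: list[tuple[object, int, int]],
                     full_score: int, strong_margin: int = 2) -> str:
    """Classify a barcode's aggregated mapping evidence.

    ``observations`` are ``(location, score, n_reads)`` with one entry per
    candidate location; a location is *strong* when its score is within
    ``2 * strong_margin`` of ``full_score`` (i.e. at most ``strong_margin``
    mismatches). Returns ``"unique"``, ``"multilocus"``, ``"ambiguous"``, or
    ``"unmapped"`` for an empty list. A single strong location is demoted to
    ambiguous when reads assigned to weaker locations outnumber its own.
    """
    if not observations:
        return "unmapped"
    threshold = full_score - 2 * strong_margin
    strong = [o for o in observations if o[1] >= threshold]
    weak = [o for o in observations if o[1] < threshold]
    if len(strong) == 0:
        return "ambiguous"
    if len(strong) >= 2:
        return "multilocus"
    weak_reads = sum(o[2] for o in weak)
    return "ambiguous" if weak_reads > strong[0][2] else "unique"


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class InsertionCatalog:
    """Final barcode-keyed insertion records plus per-stage QC tallies."""

    records: pd.DataFrame  # barcode, chrom, position, strand, n_reads,
                           # mapping_class, gene_id, allele_species
    qc: dict = field(default_factory=dict)

    def genic(self) -> pd.DataFrame:
        return self.records[~self.records["gene_id"].isin(["intergenic", "plasmid"])]


def annotate_records(records: pd.DataFrame, features: list[GffFeature],
                     contig_lengths: dict[str, int] | None = None
                     ) -> pd.DataFrame:
    """Assign gene_id / allele_species to mapped insertion positions.

    Positions inside a gene feature get that gene's id and species; other
    positions on a chromosome are ``intergenic`` (species from the contig);
    positions on a plasmid contig are labelled ``plasmid`` with species
    ``na``. A position outside every known contig is a corrupt input.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    contig_type: dict[str, str] = {}
    contig_species: dict[str, str] = {}
    for f in features:
        if f.type == "region":
            contig_type[f.seqid] = f.attributes.get("contig_type", "chromosome")
            contig_species[f.seqid] = f.attributes.get("allele_species", "na")
            if contig_lengths is None:
                pass
        elif f.type == "gene":
            trees[f.seqid].addi(f.start, f.end + 1,
                                (f.attributes["gene_id"],
                                 f.attributes.get("allele_species", "na")))
    lengths = contig_lengths or {f.seqid: f.end for f in features if f.type == "region"}
    gene_ids, species = [], []
    for _, row in records.iterrows():
        chrom, pos = row["chrom"], row["position"]
        if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside all contigs")
        if contig_type.get(chrom) == "plasmid":
            gene_ids.append("plasmid")
            species.append("na")
            continue
        hits = trees[chrom][pos]
        if hits:
            gid, sp = next(iter(hits)).data
            gene_ids.append(gid)
            species.append(sp)
        else:
            gene_ids.append("intergenic")
            species.append(contig_species.get(chrom, "na"))
    out = records.copy()
    out["gene_id"] = gene_ids
    out["allele_species"] = species
    return out


# ---------------------------------------------------------------------------
# Orchestration


def build_catalog(reads: list[tuple[str, str]], genome: dict[str, str],
                  features: list[GffFeature], arm: str,
                  layout: JunctionLayout | None = None,
                  max_arm_mismatches: int = 2, max_map_mismatches: int = 2,
                  dominance_ratio: float = 10.0, strong_margin: int = 2,
                  k: int = 15) -> InsertionCatalog:
    """Run the full Tn-seq QC pipeline and return the insertion catalog.

    The QC dict reconciles: every read is counted exactly once among
    accepted / no_arm / truncated, and every junction barcode ends up
    retained or eliminated at a named stage.
    """
    layout = layout or JunctionLayout()
    qc: dict[str, int] = {"input_reads": len(reads)}
    obs_by_barcode: dict[str, list[JunctionObservation]] = defaultdict(list)
    rejects = Counter()
    for read_id, seq in reads:
        obs, reason = detect_junction(seq, arm, read_id, max_arm_mismatches, layout)
        if obs is None:
            rejects[reason] += 1
        else:
            obs_by_barcode[obs.barcode].append(obs)
    qc["reads_rejected_no_arm"] = rejects["no_arm"]
    qc["reads_rejected_truncated"] = rejects["truncated"]
    qc["reads_with_junction"] = sum(len(v) for v in obs_by_barcode.values())

    counts = {bc: len(v) for bc, v in obs_by_barcode.items()}
    qc["barcodes_observed"] = len(counts)
    kept, elim1, elim2 = collapse_all(counts, dominance_ratio)
    qc["barcodes_off_by_one"] = len(elim1)
    qc["barcodes_off_by_two"] = len(elim2)

    index = GenomeIndex(genome, k=k)
    records = []
    class_tally = Counter()
    for bc in kept:
        # assign each read to its best location, then aggregate per location
        per_loc_reads: Counter = Counter()
        per_loc_score: dict[tuple, int] = {}
        frag_len = None
        unmapped_reads = 0
        for obs in obs_by_barcode[bc]:
            frag = obs.genomic_fragment
            if frag_len is None:
                frag_len = len(frag)
            hits = map_fragment(frag, index, max_map_mismatches)
            if not hits:
                unmapped_reads += 1
                continue
            contig, pos, strand, score = hits[0]
            loc = (contig, pos, strand)
            per_loc_reads[loc] += 1
            per_loc_score[loc] = max(per_loc_score.get(loc, -10**9), score)
        observations = [(loc, per_loc_score[loc], n)
                        for loc, n in per_loc_reads.items()]
        cls = classify_mapping(observations, full_score=frag_len or 0,
                               strong_margin=strong_margin)
        class_tally[cls] += 1
        if cls != "unique":
            continue
        threshold = (frag_len or 0) - 2 * strong_margin
        loc, score, n = max(((o for o in observations if o[1] >= threshold)),
                            key=lambda o: o[2])
        records.append({"barcode": bc, "chrom": loc[0], "position": loc[1],
                        "strand": loc[2], "n_reads": n, "mapping_class": "unique"})
    qc["barcodes_multilocus"] = class_tally["multilocus"]
    qc["barcodes_ambiguous"] = class_tally["ambiguous"]
    qc["barcodes_unmapped"] = class_tally["unmapped"]
    qc["barcodes_retained"] = class_tally["unique"]

    if records:
        df = pd.DataFrame(records)
        df = annotate_records(df, features,
                              {name: len(seq) for name, seq in genome.items()})
        df = df.sort_values(["chrom", "position", "barcode"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["barcode", "chrom", "position", "strand",
                                   "n_reads", "mapping_class", "gene_id",
                                   "allele_species"])
    return InsertionCatalog(records=df, qc=qc)
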