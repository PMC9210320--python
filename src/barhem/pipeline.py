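"""End-to-end orchestration: configuration, staging, manifests.

A run directory is produced by composing the stages
simulate -> tnseq-map -> barseq-count -> rh-test (each also runnable
standalone on precomputed inputs). One global seed is fanned out to
per-stage child seeds through ``numpy.random.SeedSequence`` so any stage
reruns identically on its own. Every stage writes its tables as TSV and
its QC tallies as JSON; a manifest records parameters, seeds and
per-stage record counts so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, simdata, tnseq, barseq, rhtest


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    Threshold defaults are the benchmark values: 2 arm/mapping mismatches,
    dominance ratio 10 for satellite collapsing, genotype CV <= 2.0,
    >= 1.1 normalized control reads, >= 3 genotypes per allele, pooled-t
    CV <= 10, hit rule adjusted P < 0.05 with effect size < -0.5, 10,000
    resamples, GO size bounds [5, 200], two-stage promotion below 0.1.
    """

    outdir: str = "barhem_run"
    seed: int = 0
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    # tnseq-map
    max_arm_mismatches: int = 2
    max_map_mismatches: int = 2
    dominance_ratio: float = 10.0
    strong_margin: int = 2
    kmer: int = 15
    # rh-test
    rh: rhtest.RhTestParams = field(default_factory=rhtest.RhTestParams)
    # enrichment
    n_resamples: int = 10_000
    go_min_size: int = 5
    go_max_size: int = 200
    n_stage1: int = 100
    promote_below: float = 0.1


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated invariant at once, naming fields; [] when ok."""
    errors: list[str] = []
    try:
        config.sim.validate()
    except ValueError as exc:
        errors.append(f"sim.{exc}")
    for name in ("max_arm_mismatches", "max_map_mismatches", "strong_margin"):
        if getattr(config, name) < 0:
            errors.append(f"{name} must be >= 0")
    if config.dominance_ratio <= 1:
        errors.append("dominance_ratio must exceed 1")
    if config.kmer < 8:
        errors.append("kmer must be >= 8")
    rh = config.rh
    if rh.cv_max <= 0:
        errors.append("rh.cv_max must be positive")
    if rh.min_norm_reads < 0:
        errors.append("rh.min_norm_reads must be >= 0")
    if rh.min_genotypes < 1:
        errors.append("rh.min_genotypes must be >= 1")
    if rh.cv_t_max <= 0:
        errors.append("rh.cv_t_max must be positive")
    if not 0 < rh.p_max <= 1:
        errors.append("rh.p_max must be in (0, 1]")
    if config.n_resamples < 1 or config.n_stage1 < 1:
        errors.append("resample counts must be >= 1")
    if not 0 < config.promote_below <= 1:
        errors.append("promote_below must be in (0, 1]")
    if not (1 <= config.go_min_size <= config.go_max_size):
        errors.append("go size bounds must satisfy 1 <= min <= max")
    if config.seed < 0:
        errors.append("seed must be non-negative")
    return errors


def _from_mapping(cls, data: dict, path: str = "") -> object:
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "sim":
            kwargs[key] = _from_mapping(simdata.SimConfig, value, "sim")
        elif key == "rh":
            kwargs[key] = _from_mapping(rhtest.RhTestParams, value, "rh")
        elif key == "effect_table":
            kwargs[key] = {g: tuple(v) for g, v in value.items()}
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config with a strict schema (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(RunConfig, data)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(sim: simdata.SimConfig, outdir: Path, seed: int) -> dict:
    seeds = child_seeds(seed, 5)
    genome, features = simdata.generate_hybrid_genome(sim, seeds[0])
    truth = simdata.generate_pool(genome, features, sim, seeds[1])
    reads = simdata.simulate_tnseq_reads(truth, genome, sim, seeds[2])
    counts, sheet = simdata.simulate_competition(truth, sim, seeds[3])
    amplicons = simdata.simulate_barseq_reads(counts, sim, seeds[4])

    io.write_fasta(genome, outdir / "genome.fa")
    io.write_gff3(features, outdir / "annotation.gff3")
    io.write_tsv(truth.insertions, outdir / "truth_insertions.tsv")
    io.write_tsv(truth.clones, outdir / "truth_clones.tsv")
    io.write_tsv(pd.DataFrame(
        {"gene_id": list(truth.true_t_difference),
         "true_t_difference": list(truth.true_t_difference.values())}),
        outdir / "truth_effects.tsv")
    io.write_fastq(reads, outdir / "tnseq_reads.fastq")
    io.write_tsv(counts.reset_index(), outdir / "true_counts.tsv")
    io.write_tsv(sheet, outdir / "samples.tsv")
    fastq_dir = outdir / "barseq"
    fastq_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for sample, recs in amplicons.items():
        fq = fastq_dir / f"{sample}.fastq"
        io.write_fastq(recs, fq)
        manifest_rows.append({"sample_id": sample, "fastq": str(fq)})
    io.write_tsv(pd.DataFrame(manifest_rows), outdir / "barseq_manifest.tsv")
    return {"n_insertions": int(len(truth.insertions)),
            "n_clones": int(len(truth.clones)),
            "n_tnseq_reads": len(reads),
            "n_samples": int(len(sheet))}


def stage_tnseq_map(reads_path: Path, genome_path: Path, gff_path: Path,
                    arm: str, layout: tnseq.JunctionLayout, outdir: Path,
                    max_arm_mismatches: int = 2, max_map_mismatches: int = 2,
                    dominance_ratio: float = 10.0, strong_margin: int = 2,
                    k: int = 15) -> dict:
    reads = io.read_fastq(reads_path)
    genome = io.read_fasta(genome_path)
    features = io.read_gff3(gff_path)
    catalog = tnseq.build_catalog(reads, genome, features, arm, layout,
                                  max_arm_mismatches, max_map_mismatches,
                                  dominance_ratio, strong_margin, k)
    io.write_tsv(catalog.records, outdir / "catalog.tsv")
    io.write_json(catalog.qc, outdir / "tnseq_qc.json")
    return dict(catalog.qc)


def stage_barseq_count(manifest_path: Path, catalog_path: Path,
                       samples_path: Path, upstream_flank: str,
                       downstream_flank: str, outdir: Path,
                       barcode_length: int = 20,
                       max_flank_mismatches: int = 2) -> dict:
    manifest = io.read_tsv(manifest_path)
    catalog = io.read_tsv(catalog_path)
    sheet = io.read_tsv(samples_path)
    reads_by_sample = {row["sample_id"]: io.read_fastq(row["fastq"])
                       for _, row in manifest.iterrows()}
    counts, qc = barseq.count_barcodes(reads_by_sample, catalog["barcode"],
                                       sheet, upstream_flank, downstream_flank,
                                       barcode_length, max_flank_mismatches)
    io.write_tsv(counts.reset_index(), outdir / "counts.tsv")
    io.write_json(qc, outdir / "barseq_qc.json")
    return {"n_barcodes": int(len(counts)), "per_sample": qc}


def stage_rh_test(counts_path: Path, catalog_path: Path, samples_path: Path,
                  params: rhtest.RhTestParams, outdir: Path) -> dict:
    counts = io.read_tsv(counts_path).set_index("barcode")
    catalog = io.read_tsv(catalog_path)
    sheet = io.read_tsv(samples_path)
    results, qc = rhtest.run_rh_test(counts, catalog, sheet, params)
    io.write_tsv(results, outdir / "rh_results.tsv")
    io.write_json(qc, outdir / "rh_qc.json")
    return dict(qc)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> tnseq-map -> barseq-count -> rh-test.

    Any stage failure aborts with the stage name; partial outputs stay in
    place next to a FAILED marker. Returns the run directory.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = child_seeds(config.seed, 4)
    manifest: dict = {"seed": config.seed, "stage_seeds": stage_seeds,
                      "parameters": asdict(config), "stages": {}}
    sim = config.sim
    layout = tnseq.JunctionLayout(barcode_length=sim.barcode_length,
                                  barcode_gap=sim.junction_gap,
                                  min_fragment_length=min(30, sim.genomic_context_bp))
    plan = [
        ("simulate", lambda: stage_simulate(sim, outdir, stage_seeds[0])),
        ("tnseq-map", lambda: stage_tnseq_map(
            outdir / "tnseq_reads.fastq", outdir / "genome.fa",
            outdir / "annotation.gff3", sim.transposon_arm, layout, outdir,
            config.max_arm_mismatches, config.max_map_mismatches,
            config.dominance_ratio, config.strong_margin, config.kmer)),
        ("barseq-count", lambda: stage_barseq_count(
            outdir / "barseq_manifest.tsv", outdir / "catalog.tsv",
            outdir / "samples.tsv", sim.barseq_flank_upstream,
            sim.barseq_flank_downstream, outdir, sim.barcode_length)),
        ("rh-test", lambda: stage_rh_test(
            outdir / "counts.tsv", outdir / "catalog.tsv",
            outdir / "samples.tsv", config.rh, outdir)),
    ]
    for name, fn in plan:
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            io.write_json(manifest, outdir / "manifest.json")
            raise StageError(name, exc) from exc
    io.write_json(manifest, outdir / "manifest.json")
    return outdir
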