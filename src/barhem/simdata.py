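"""Synthetic hybrid-genome, hemizygote-pool and competition simulator.

The generator emulates a barcoded reciprocal-hemizygosity screen in an
interspecies F1 hybrid: a two-species genome (every gene present once per
parental allele, on species-labelled chromosomes), a pool of clones each
carrying a uniquely barcoded transposon insertion, transposon–genome
junction reads (Tn-seq), and barcode-amplicon counts from replicated
competition cultures at an experimental and a control temperature
(Bar-seq). Ground truth — every insertion's barcode, location and the
per-gene allelic fitness effect — is retained so that every downstream
stage of the pipeline can be checked against what was planted.

Model sketch
------------
A clone disrupted in the *cer* allele of gene *g* grows with the fitness of
the intact (*par*) allele, ``w_par_uncovered(g)``, per doubling at the
experimental temperature; all clones are neutral at the control
temperature. After ``D`` doublings of deterministic exponential growth the
expected frequency of clone *c* is proportional to ``f0_c * w_c**D``, and
sequencing draws multinomial counts at a fixed per-sample library size.
The true allelic effect on the temperature statistic *t* is therefore
``D * log2(w_par_uncovered / w_cer_uncovered)`` per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GffFeature

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Study-design parameters for one simulated screen.

    Defaults mirror the benchmark experiment this generator emulates:
    20-bp barcodes, a median Tn-seq depth of 47 reads per insertion, a
    1.38% per-base sequencing error rate, 12 experimental + 12 control
    replicate competitions, and 10–15 doublings of pooled growth.
    """

    n_genes: int = 20
    gene_length_bp: int = 300
    intergenic_bp: int = 100
    barcode_length: int = 20
    inserts_per_allele_mean: float = 5.0
    tnseq_depth_mean: float = 47.0
    barseq_depth_mean: float = 50.0
    base_error_rate: float = 0.0138
    frac_multilocus: float = 0.0
    n_replicates_exp: int = 12
    n_replicates_ctrl: int = 12
    doublings: float = 12.0
    #: gene_id -> (w_cer_uncovered, w_par_uncovered): per-doubling relative
    #: fitness at the experimental temperature of a clone whose intact
    #: allele is the named species. Genes absent default to (1, 1).
    effect_table: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    # pool construction
    min_inserts_per_gene_allele: int = 0
    frequency_lognorm_sigma: float = 0.5
    # read construction; arbitrary fixed sequences, carried in the config so
    # that detection stages take them as parameters rather than constants
    transposon_arm: str = "ACGCTGATCGTAGCTAGCTTGACCATGGTA"
    tnseq_read_prefix: str = "TTCGAACG"
    barcode_arm_spacer: str = "GATCC"
    barseq_flank_upstream: str = "GTCGACCTGCAGCGTACG"
    barseq_flank_downstream: str = "GATGTCCACGAGGTCTCT"
    genomic_context_bp: int = 50
    plasmid_length_bp: int = 2000

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        counts = {
            "n_genes": self.n_genes,
            "gene_length_bp": self.gene_length_bp,
            "intergenic_bp": self.intergenic_bp,
            "barcode_length": self.barcode_length,
            "n_replicates_exp": self.n_replicates_exp,
            "n_replicates_ctrl": self.n_replicates_ctrl,
            "genomic_context_bp": self.genomic_context_bp,
            "plasmid_length_bp": self.plasmid_length_bp,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer (got {value!r})")
        if self.barcode_length < 8:
            raise ValueError(f"barcode_length must be >= 8 (got {self.barcode_length})")
        for name in ("base_error_rate", "frac_multilocus"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1] (got {value!r})")
        for name in ("inserts_per_allele_mean", "tnseq_depth_mean", "barseq_depth_mean",
                     "doublings", "frequency_lognorm_sigma"):
            value = getattr(self, name)
            if value < 0 or (name != "frequency_lognorm_sigma" and value == 0):
                raise ValueError(f"{name} must be positive (got {value!r})")
        if len(self.transposon_arm) < 22:
            raise ValueError(f"transposon_arm must be at least 22 bp (got {len(self.transposon_arm)})")
        if self.min_inserts_per_gene_allele < 0:
            raise ValueError("min_inserts_per_gene_allele must be >= 0")
        for gene, pair in self.effect_table.items():
            if len(pair) != 2 or any(w < 0 for w in pair):
                raise ValueError(f"effect_table[{gene!r}] must be two fitness values >= 0")

    def with_effects(self, effect_table: dict[str, tuple[float, float]]) -> "SimConfig":
        return replace(self, effect_table=dict(effect_table))

    @property
    def junction_gap(self) -> int:
        """Bases between barcode end and the arm's final-22-mer start."""
        return len(self.barcode_arm_spacer) + (len(self.transposon_arm) - 22)


@dataclass
class SimTruth:
    """Ground truth for one simulated pool.

    ``insertions`` has one row per (barcode, location); ``clones`` one row
    per barcode, with its initial frequency and per-doubling fitness at the
    experimental temperature. ``true_t_difference`` maps every gene to
    ``doublings * log2(w_par_uncovered / w_cer_uncovered)``, the planted
    allelic effect on the temperature statistic.
    """

    insertions: pd.DataFrame
    clones: pd.DataFrame
    true_t_difference: dict[str, float]


# ---------------------------------------------------------------------------
# Genome


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_hybrid_genome(config: SimConfig, seed: int | None = None
                           ) -> tuple[dict[str, str], list[GffFeature]]:
    """Build a two-species hybrid genome plus a plasmid contig.

    One chromosome per species, each carrying the same ``n_genes`` gene
    models (ids ``YG0001``…) separated by intergenic spacers; sequences are
    drawn independently per species so every genomic span is unique and
    junction fragments map unambiguously. Returns the genome as
    ``{contig: sequence}`` and GFF3 features (``region`` per contig with a
    ``contig_type`` attribute, ``gene`` per gene and allele with
    ``gene_id`` and ``allele_species`` attributes; 1-based inclusive).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome: dict[str, str] = {}
    features: list[GffFeature] = []
    gene_ids = [f"YG{i + 1:04d}" for i in range(config.n_genes)]
    for species in ("cer", "par"):
        chrom = f"chr1_{species}"
        parts = [_random_seq(rng, config.intergenic_bp)]
        pos = config.intergenic_bp
        gene_feats = []
        for gid in gene_ids:
            start = pos + 1  # 1-based
            end = pos + config.gene_length_bp
            gene_feats.append(
                GffFeature(chrom, "barhem_sim", "gene", start, end, ".", "+", ".",
                           {"ID": f"{gid}_{species}", "gene_id": gid,
                            "allele_species": species})
            )
            parts.append(_random_seq(rng, config.gene_length_bp))
            parts.append(_random_seq(rng, config.intergenic_bp))
            pos = end + config.intergenic_bp
        seq = "".join(parts)
        genome[chrom] = seq
        features.append(
            GffFeature(chrom, "barhem_sim", "region", 1, len(seq), ".", "+", ".",
                       {"ID": chrom, "contig_type": "chromosome",
                        "allele_species": species})
        )
        features.extend(gene_feats)
    plasmid = _random_seq(rng, config.plasmid_length_bp)
    genome["plasmid"] = plasmid
    features.insert(
        0,
        GffFeature("plasmid", "barhem_sim", "region", 1, len(plasmid), ".", "+", ".",
                   {"ID": "plasmid", "contig_type": "plasmid"}),
    )
    return genome, features


# ---------------------------------------------------------------------------
# Pool


def _draw_distinct_barcodes(rng: np.random.Generator, n: int, length: int,
                            min_distance: int = 3, max_attempts_factor: int = 200
                            ) -> list[str]:
    """Draw ``n`` random barcodes with pairwise Hamming distance >= 3.

    Two barcodes are within distance 2 iff they share a sequence at
    distance <= 1 from each, so a hash of every accepted barcode's
    distance-<=1 neighbourhood gives an O(L) rejection test per candidate.
    """
    if min_distance != 3:
        raise ValueError("only min_distance=3 is supported")
    if n > 4 ** length / (1 + 3 * length):
        raise ValueError(
            f"requested pool of {n} barcodes exceeds distinct-barcode capacity "
            f"at length {length}")
    taken: set[str] = set()
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > max_attempts_factor * n:
            raise ValueError(
                f"could not place {n} barcodes with pairwise distance >= 3 "
                f"at length {length}")
        cand = _random_seq(rng, length)
        variants = [cand]
        for i in range(length):
            for b in "ACGT":
                if b != cand[i]:
                    variants.append(cand[:i] + b + cand[i + 1:])
        if any(v in taken for v in variants):
            continue
        taken.update(variants)
        barcodes.append(cand)
    return barcodes


def _insertion_regions(features: list[GffFeature], genome: dict[str, str],
                       context_bp: int) -> list[dict]:
    """Genic and intergenic spans eligible for insertion, per chromosome.

    Positions within ``context_bp`` of a chromosome end are excluded so
    every junction read has a full-length genomic context.
    """
    regions = []
    chrom_species = {f.seqid: f.attributes.get("allele_species")
                     for f in features if f.type == "region"
                     and f.attributes.get("contig_type") == "chromosome"}
    for chrom, species in chrom_species.items():
        length = len(genome[chrom])
        genes = sorted((f for f in features if f.type == "gene" and f.seqid == chrom),
                       key=lambda f: f.start)
        cursor = 1
        for g in genes:
            if g.start > cursor:
                regions.append({"chrom": chrom, "start": cursor, "end": g.start - 1,
                                "gene_id": "intergenic", "allele_species": species})
            regions.append({"chrom": chrom, "start": g.start, "end": g.end,
                            "gene_id": g.attributes["gene_id"],
                            "allele_species": g.attributes["allele_species"]})
            cursor = g.end + 1
        if cursor <= length:
            regions.append({"chrom": chrom, "start": cursor, "end": length,
                            "gene_id": "intergenic", "allele_species": species})
    # clip the trailing context window off every region
    clipped = []
    for r in regions:
        limit = len(genome[r["chrom"]]) - context_bp
        end = min(r["end"], limit)
        if end >= r["start"]:
            clipped.append({**r, "end": end})
    return clipped


def generate_pool(genome: dict[str, str], features: list[GffFeature],
                  config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw a pool of uniquely barcoded insertions with known ground truth.

    Insertion counts per region are Poisson with a common per-bp rate of
    ``inserts_per_allele_mean / gene_length_bp`` (optionally floored at
    ``min_inserts_per_gene_allele`` for genic regions); positions are
    uniform within regions. A fraction ``frac_multilocus`` of barcodes
    receives a second, independently placed insertion. Initial clone
    frequencies are lognormal and normalised to sum to one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    regions = _insertion_regions(features, genome, config.genomic_context_bp)
    rate_per_bp = config.inserts_per_allele_mean / config.gene_length_bp
    rows = []
    for r in regions:
        span = r["end"] - r["start"] + 1
        n = int(rng.poisson(rate_per_bp * span))
        if r["gene_id"] != "intergenic":
            n = max(n, config.min_inserts_per_gene_allele)
        if n == 0:
            continue
        positions = np.sort(rng.integers(r["start"], r["end"] + 1, size=n))
        for p in positions:
            rows.append({"chrom": r["chrom"], "position": int(p),
                         "gene_id": r["gene_id"],
                         "allele_species": r["allele_species"]})
    if not rows:
        raise ValueError("pool is empty: increase inserts_per_allele_mean or region sizes")
    n_clones = len(rows)
    barcodes = _draw_distinct_barcodes(rng, n_clones, config.barcode_length)
    multilocus = rng.random(n_clones) < config.frac_multilocus
    insertion_rows = []
    for bc, row, multi in zip(barcodes, rows, multilocus):
        insertion_rows.append({"barcode": bc, **row, "multilocus": bool(multi)})
        if multi:
            # redraw until the second location genuinely differs
            while True:
                extra = regions[rng.integers(len(regions))]
                pos = int(rng.integers(extra["start"], extra["end"] + 1))
                if (extra["chrom"], pos) != (row["chrom"], row["position"]):
                    break
            insertion_rows.append({"barcode": bc, "chrom": extra["chrom"],
                                   "position": pos, "gene_id": extra["gene_id"],
                                   "allele_species": extra["allele_species"],
                                   "multilocus": True})
    insertions = pd.DataFrame(insertion_rows)

    freqs = rng.lognormal(mean=0.0, sigma=config.frequency_lognorm_sigma, size=n_clones)
    freqs /= freqs.sum()
    fitness = np.ones(n_clones)
    by_barcode = insertions.groupby("barcode", sort=False)
    fit_map = {}
    for bc, grp in by_barcode:
        w = 1.0
        for _, ins in grp.iterrows():
            gid = ins["gene_id"]
            if gid in config.effect_table:
                w_cer_unc, w_par_unc = config.effect_table[gid]
                # disrupting the cer allele leaves the par allele intact
                w *= w_par_unc if ins["allele_species"] == "cer" else w_cer_unc
        fit_map[bc] = w
    fitness = np.array([fit_map[bc] for bc in barcodes])
    clones = pd.DataFrame({"barcode": barcodes, "initial_frequency": freqs,
                           "fitness_experimental": fitness,
                           "multilocus": multilocus})
    truth_effects = {}
    for i in range(config.n_genes):
        gid = f"YG{i + 1:04d}"
        w_cer_unc, w_par_unc = config.effect_table.get(gid, (1.0, 1.0))
        if w_cer_unc > 0 and w_par_unc > 0:
            truth_effects[gid] = config.doublings * math.log2(w_par_unc / w_cer_unc)
        else:
            truth_effects[gid] = -math.inf if w_par_unc == 0 else math.inf
    return SimTruth(insertions=insertions, clones=clones,
                    true_t_difference=truth_effects)


# ---------------------------------------------------------------------------
# Reads


def _apply_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Substitute bases uniformly at ``rate`` per base (never to itself)."""
    if rate == 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        hit = rng.random(arr.size) < rate
        n_hit = int(hit.sum())
        if n_hit:
            # shift each erroneous base to one of the other three
            cur = np.searchsorted(_BASES, arr[hit])
            arr[hit] = _BASES[(cur + rng.integers(1, 4, size=n_hit)) % 4]
        out.append(arr.tobytes().decode())
    return out


def simulate_tnseq_reads(truth: SimTruth, genome: dict[str, str],
                         config: SimConfig, seed: int | None = None
                         ) -> list[tuple[str, str]]:
    """Junction reads: prefix, barcode, spacer, transposon arm, genomic context.

    Per insertion location the read count is Poisson(``tnseq_depth_mean``);
    per-base substitution errors at ``base_error_rate`` are applied to the
    whole read, so off-by-one barcode satellites arise naturally. Returns
    ``(read_id, sequence)`` pairs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    ctx = config.genomic_context_bp
    reads: list[tuple[str, str]] = []
    clean: list[str] = []
    ids: list[str] = []
    for idx, ins in truth.insertions.iterrows():
        depth = int(rng.poisson(config.tnseq_depth_mean))
        if depth == 0:
            continue
        chrom_seq = genome[ins["chrom"]]
        start0 = ins["position"] - 1
        context = chrom_seq[start0:start0 + ctx]
        template = (config.tnseq_read_prefix + ins["barcode"] +
                    config.barcode_arm_spacer + config.transposon_arm + context)
        for j in range(depth):
            ids.append(f"tn_{idx}_{j}")
            clean.append(template)
    noisy = _apply_errors(clean, config.base_error_rate, rng)
    reads = list(zip(ids, noisy))
    return reads


def simulate_competition(truth: SimTruth, config: SimConfig,
                         seed: int | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Competition growth followed by multinomial sequencing.

    Expected clone frequencies at the experimental temperature are
    ``f0 * w**doublings`` renormalised; control frequencies are ``f0``. Each
    sample's library size is ``round(barseq_depth_mean * n_clones)`` and
    counts are one multinomial draw. Returns the barcode x sample count
    matrix and a sample sheet (``sample_id, temperature, replicate``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    clones = truth.clones
    if (clones["fitness_experimental"] < 0).any():
        raise ValueError("fitness must be >= 0")
    f0 = clones["initial_frequency"].to_numpy()
    w = clones["fitness_experimental"].to_numpy()
    exp_freq = f0 * np.power(w, config.doublings)
    exp_freq = exp_freq / exp_freq.sum()
    ctrl_freq = f0 / f0.sum()
    library = int(round(config.barseq_depth_mean * len(clones)))
    samples, columns = [], {}
    for i in range(config.n_replicates_exp):
        sid = f"exp_{i + 1:02d}"
        samples.append({"sample_id": sid, "temperature": "experimental",
                        "replicate": i + 1})
        columns[sid] = rng.multinomial(library, exp_freq)
    for i in range(config.n_replicates_ctrl):
        sid = f"ctrl_{i + 1:02d}"
        samples.append({"sample_id": sid, "temperature": "control",
                        "replicate": i + 1})
        columns[sid] = rng.multinomial(library, ctrl_freq)
    counts = pd.DataFrame(columns, index=pd.Index(clones["barcode"], name="barcode"))
    sheet = pd.DataFrame(samples)
    return counts, sheet


def simulate_barseq_reads(counts: pd.DataFrame, config: SimConfig,
                          seed: int | None = None
                          ) -> dict[str, list[tuple[str, str]]]:
    """Barcode amplicon reads per sample: flank, barcode, flank, with errors."""
    config.validate()
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in counts.columns:
        col = counts[sample]
        ids, clean = [], []
        for barcode, n in col.items():
            template = (config.barseq_flank_upstream + barcode +
                        config.barseq_flank_downstream)
            for j in range(int(n)):
                ids.append(f"bs_{sample}_{barcode}_{j}")
                clean.append(template)
        noisy = _apply_errors(clean, config.base_error_rate, rng)
        out[sample] = list(zip(ids, noisy))
    return out
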