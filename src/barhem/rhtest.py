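"""Reciprocal hemizygosity testing on pooled competition counts.

Each Tn-seq-validated barcode reports an inferred hemizygote genotype: a
hybrid clone with one species' allele of a gene disrupted and the other
intact. Per genotype, the temperature effect in experimental replicate *i*
is ``t_i = log2(a_exp,i / a_ctrl_mean)`` on normalized abundances.
Genotypes are filtered on reproducibility (CV of t <= 2) and coverage
(mean control abundance >= 1.1 normalized reads); genes need at least
three genotypes per allele and per-allele pooled-t CV <= 10. The two
pooled per-allele t vectors are compared with a two-sided Mann–Whitney
test, Benjamini–Hochberg corrected across genes; the effect size is the
difference of the per-allele means of genotype-mean t (cer-insert minus
par-insert). Hits require adjusted P < 0.05 and effect size < -0.5, i.e. a
thermotolerance defect specific to disruption of the *S. cerevisiae*
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RhTestParams:
    cv_max: float = 2.0
    min_norm_reads: float = 1.1
    min_genotypes: int = 3
    cv_t_max: float = 10.0
    p_max: float = 0.05
    effect_max: float = -0.5
    dropout_pseudoreads: float = 0.5
    #: quantity whose per-genotype CV the <= cv_max filter tests:
    #: "control_abundance" (normalized reads across control replicates, the
    #: denominator of t) or "t" (the t vector itself). The abundance reading
    #: keeps genotypes whose t is reproducibly near zero — under "t" they are
    #: discarded wholesale because CV = sd/|mean| diverges as mean(t) -> 0,
    #: which would also discard the intact-allele genotypes of every true
    #: effect gene.
    cv_on: str = "control_abundance"


# ---------------------------------------------------------------------------
# Normalization and temperature effect


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its total equals the median raw column total.

    Keeps normalized abundances on a raw-read scale so the 1.1-read floor
    remains meaningful. A sample with zero total is an error.
    """
    totals = counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    target = float(np.median(totals))
    return counts.astype(float) * (target / totals)


def temperature_effect(norm: pd.DataFrame, sheet: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Per-genotype t vectors over experimental replicates.

    Returns ``(t, a_ctrl_mean, exclusions)``: ``t`` is barcode x
    experimental-sample with ``t_i = log2(a_exp,i / a_ctrl_mean)``
    (``-inf`` where the experimental abundance is zero); genotypes with
    zero mean control abundance are excluded and reason-coded.
    """
    exp_samples = sheet.loc[sheet["temperature"] == "experimental", "sample_id"].tolist()
    ctrl_samples = sheet.loc[sheet["temperature"] == "control", "sample_id"].tolist()
    if not exp_samples or not ctrl_samples:
        raise ValueError("sample sheet must contain experimental and control samples")
    a_ctrl_mean = norm[ctrl_samples].mean(axis=1)
    excluded = a_ctrl_mean.index[a_ctrl_mean == 0].tolist()
    keep = a_ctrl_mean.index[a_ctrl_mean > 0]
    with np.errstate(divide="ignore"):
        t = np.log2(norm.loc[keep, exp_samples].div(a_ctrl_mean.loc[keep], axis=0))
    exclusions = {"zero_control_abundance": excluded}
    return t, a_ctrl_mean.loc[keep], exclusions


def floor_dropouts(t: pd.DataFrame, a_ctrl_mean: pd.Series,
                   pseudoreads: float = 0.5) -> pd.DataFrame:
    """Replace -inf (zero experimental abundance) with log2(pseudo / a_ctrl_mean).

    Keeps fully dropped-out clones — the strongest phenotypes — in the test
    at a half-pseudoread abundance instead of discarding them.
    """
    floor = np.log2(pseudoreads / a_ctrl_mean)
    out = t.copy()
    for col in out.columns:
        mask = np.isneginf(out[col])
        out.loc[mask, col] = floor[mask]
    return out


# ---------------------------------------------------------------------------
# Filters


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return math.inf
    return values.std(ddof=1) / abs(mean)


def filter_genotypes(t: pd.DataFrame, a_ctrl_mean: pd.Series,
                     cv_max: float = 2.0, min_norm_reads: float = 1.1,
                     cv_matrix: pd.DataFrame | None = None
                     ) -> tuple[pd.Index, dict[str, list[str]]]:
    """Drop irreproducible or under-covered genotypes, reason-coded.

    A genotype is dropped when the CV (sd/|mean|, sample sd) of its row of
    ``cv_matrix`` exceeds ``cv_max``, when its mean control abundance is
    below ``min_norm_reads``, or when fewer than two replicates make the
    CV undefined. ``cv_matrix`` defaults to ``t`` itself; pass the
    normalized control abundances to filter on measurement noise instead
    of on the temperature effect.
    """
    if cv_matrix is None:
        cv_matrix = t
    drops: dict[str, list[str]] = {"low_abundance": [], "high_cv": [],
                                   "cv_undefined": []}
    retained = []
    for bc in t.index:
        row = cv_matrix.loc[bc].to_numpy(dtype=float)
        if a_ctrl_mean[bc] < min_norm_reads:
            drops["low_abundance"].append(bc)
        elif row.size < 2:
            drops["cv_undefined"].append(bc)
        elif _cv(row) > cv_max:
            drops["high_cv"].append(bc)
        else:
            retained.append(bc)
    return pd.Index(retained), drops


def gene_gate(t: pd.DataFrame, genotype_info: pd.DataFrame,
              min_genotypes: int = 3, cv_t_max: float = 10.0
              ) -> tuple[dict[str, dict], dict[str, list[str]]]:
    """Pool per-allele t vectors per gene and apply the gene-level gates.

    ``genotype_info`` maps barcode -> (gene_id, allele_species) for the
    retained genotypes. A gene is excluded when either allele has fewer
    than ``min_genotypes`` genotypes, then when the CV of either pooled
    per-allele t vector exceeds ``cv_t_max``. Returns
    ``{gene: {"cer": t-array, "par": t-array, "n_cer": .., "n_par": ..}}``
    plus reason-coded exclusions.
    """
    exclusions: dict[str, list[str]] = {"too_few_genotypes": [], "high_pooled_cv": []}
    eligible: dict[str, dict] = {}
    info = genotype_info.loc[genotype_info.index.intersection(t.index)]
    for gene, grp in info.groupby("gene_id"):
        by_allele = {}
        n_genotypes = {}
        for species in ("cer", "par"):
            barcodes = grp.index[grp["allele_species"] == species]
            n_genotypes[species] = len(barcodes)
            by_allele[species] = t.loc[barcodes].to_numpy(dtype=float).ravel()
        if min(n_genotypes.values()) < min_genotypes:
            exclusions["too_few_genotypes"].append(gene)
            continue
        if any(_cv(by_allele[s]) > cv_t_max for s in ("cer", "par")):
            exclusions["high_pooled_cv"].append(gene)
            continue
        eligible[gene] = {"cer": by_allele["cer"], "par": by_allele["par"],
                          "n_cer": n_genotypes["cer"], "n_par": n_genotypes["par"]}
    return eligible, exclusions


# ---------------------------------------------------------------------------
# Testing


def test_gene(t_cer: np.ndarray, t_par: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on the pooled per-allele t vectors.

    Exact null distribution when both samples have <= 8 values and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    t_cer = np.asarray(t_cer, dtype=float)
    t_par = np.asarray(t_par, dtype=float)
    if t_cer.size == 0 or t_par.size == 0:
        raise ValueError("both t vectors must be non-empty")
    pooled = np.concatenate([t_cer, t_par])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (t_cer.size <= 8 and t_par.size <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(t_cer, t_par, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(p_raw: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def effect_sizes(t: pd.DataFrame, genotype_info: pd.DataFrame,
                 genes: list[str]) -> pd.Series:
    """Allelic effect size per gene: mean genotype-mean t, cer minus par.

    Each genotype contributes the average of its t values over experimental
    replicates; genotypes are weighted equally within an allele.
    """
    genotype_mean = t.mean(axis=1)
    info = genotype_info.loc[genotype_info.index.intersection(t.index)]
    out = {}
    for gene in genes:
        grp = info[info["gene_id"] == gene]
        means = {
            s: genotype_mean[grp.index[grp["allele_species"] == s]].mean()
            for s in ("cer", "par")
        }
        out[gene] = means["cer"] - means["par"]
    return pd.Series(out, name="effect_size")


def run_rh_test(counts: pd.DataFrame, catalog: pd.DataFrame,
                sheet: pd.DataFrame, params: RhTestParams | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Full reciprocal hemizygosity test from raw counts to gene calls.

    ``catalog`` must carry barcode-indexed (or ``barcode``-column) columns
    ``gene_id`` and ``allele_species``. Normalization uses all barcodes
    (sample totals), after which intergenic and plasmid insertions are
    eliminated. Returns the per-gene results table (gene_id, n_cer, n_par,
    U, p_raw, p_adj, effect_size, is_hit) and a QC dict of every exclusion
    tally.
    """
    params = params or RhTestParams()
    if "barcode" in catalog.columns:
        catalog = catalog.set_index("barcode")
    norm = normalize(counts)
    genic = catalog[~catalog["gene_id"].isin(["intergenic", "plasmid"])
                    & catalog["allele_species"].isin(["cer", "par"])]
    norm = norm.loc[norm.index.intersection(genic.index)]
    qc: dict = {"genotypes_input": int(len(norm)),
                "genotypes_nongenic_removed": int(len(counts) - len(norm))}
    t_raw, a_ctrl_mean, excl_zero = temperature_effect(norm, sheet)
    t = floor_dropouts(t_raw, a_ctrl_mean, params.dropout_pseudoreads)
    if params.cv_on == "control_abundance":
        ctrl_samples = sheet.loc[sheet["temperature"] == "control", "sample_id"]
        cv_matrix = norm.loc[t.index, list(ctrl_samples)]
    elif params.cv_on == "t":
        cv_matrix = t
    else:
        raise ValueError(f"cv_on must be 'control_abundance' or 't' (got {params.cv_on!r})")
    retained, drops = filter_genotypes(t, a_ctrl_mean, params.cv_max,
                                       params.min_norm_reads, cv_matrix)
    qc["genotypes_zero_control"] = len(excl_zero["zero_control_abundance"])
    qc.update({f"genotypes_dropped_{k}": len(v) for k, v in drops.items()})
    qc["genotypes_retained"] = len(retained)
    t_kept = t.loc[retained]
    info = genic.loc[genic.index.intersection(retained), ["gene_id", "allele_species"]]
    eligible, gene_excl = gene_gate(t_kept, info, params.min_genotypes,
                                    params.cv_t_max)
    qc.update({f"genes_excluded_{k}": len(v) for k, v in gene_excl.items()})
    qc["genes_tested"] = len(eligible)
    if not eligible:
        empty = pd.DataFrame(columns=["gene_id", "n_cer", "n_par", "U", "p_raw",
                                      "p_adj", "effect_size", "is_hit"])
        return empty, qc
    genes = sorted(eligible)
    rows = []
    for gene in genes:
        e = eligible[gene]
        U, p = test_gene(e["cer"], e["par"])
        rows.append({"gene_id": gene, "n_cer": e["n_cer"], "n_par": e["n_par"],
                     "U": U, "p_raw": p})
    results = pd.DataFrame(rows)
    results["p_adj"] = adjust_bh(results["p_raw"])
    results["effect_size"] = effect_sizes(t_kept, info, genes).to_numpy()
    results["is_hit"] = (results["p_adj"] < params.p_max) & \
        (results["effect_size"] < params.effect_max)
    qc["genes_hit"] = int(results["is_hit"].sum())
    return results, qc
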