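"""Resampling-based downstream analyses on the hit list.

All tests share one null model: random gene sets drawn from the genome
matched to the focal set's size and essential-gene fraction, so that
essentiality — a strong confounder of both GO membership and screen
behaviour — cannot drive apparent enrichment. P-values are plain
exceedance proportions over N resamples (no smoothing), so they lie on the
grid {0, 1/N, ..., 1} and are exactly reproducible for a fixed seed.

Included tests: GO-term overrepresentation among hits (exceedance counted
strictly, "more genes in the term", with a >= variant available);
effect-size GO enrichment via a two-stage scheme (a cheap first pass, then
a deep pass for terms with initial P below a promotion threshold);
physical-interaction enrichment via the internal-edge ratio r; and
per-gene McDonald–Kreitman Fisher tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rhtest import adjust_bh


# ---------------------------------------------------------------------------
# Term filtering


def filter_terms(annotation: dict[str, set[str]], genome_genes: set[str],
                 min_size: int = 5, max_size: int = 200,
                 restrict_to: set[str] | None = None
                 ) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Apply the GO-term size and redundancy filters.

    Membership is intersected with the genome gene list; terms outside
    ``[min_size, max_size]`` are removed; among groups with identical
    membership the lexicographically smallest term id is retained and the
    others recorded as aliases. If ``restrict_to`` is given (e.g. the hit
    set), terms with no member in it are dropped. Returns
    ``(retained terms, alias -> retained_id)``.
    """
    sized = {}
    for term, members in annotation.items():
        mem = set(members) & genome_genes
        if min_size <= len(mem) <= max_size:
            sized[term] = mem
    by_membership: dict[frozenset, list[str]] = {}
    for term in sorted(sized):
        by_membership.setdefault(frozenset(sized[term]), []).append(term)
    retained: dict[str, set[str]] = {}
    aliases: dict[str, str] = {}
    for members, terms in by_membership.items():
        keep = terms[0]
        retained[keep] = set(members)
        for alias in terms[1:]:
            aliases[alias] = keep
    if restrict_to is not None:
        retained = {t: m for t, m in retained.items() if m & restrict_to}
    return retained, aliases


# ---------------------------------------------------------------------------
# Matched resampling


def matched_resample(k: int, p_ess: float, genome_genes: list[str],
                     essentiality: dict[str, bool],
                     rng: np.random.Generator) -> list[str]:
    """Draw ``k`` genes without replacement, matching an essential fraction.

    ``round(k * p_ess)`` genes come from the essential stratum and the rest
    from the non-essential stratum; a stratum smaller than its requested
    draw is an error.
    """
    essential = [g for g in genome_genes if essentiality.get(g, False)]
    nonessential = [g for g in genome_genes if not essentiality.get(g, False)]
    n_ess = int(round(k * p_ess))
    n_non = k - n_ess
    if n_ess > len(essential):
        raise ValueError(f"essential stratum ({len(essential)}) smaller than draw ({n_ess})")
    if n_non > len(nonessential):
        raise ValueError(f"non-essential stratum ({len(nonessential)}) smaller than draw ({n_non})")
    out = []
    if n_ess:
        out.extend(rng.choice(essential, size=n_ess, replace=False))
    if n_non:
        out.extend(rng.choice(nonessential, size=n_non, replace=False))
    return [str(g) for g in out]


def _essential_fraction(genes: set[str], essentiality: dict[str, bool]) -> float:
    if not genes:
        return 0.0
    return sum(bool(essentiality.get(g, False)) for g in genes) / len(genes)


# ---------------------------------------------------------------------------
# GO overrepresentation


@dataclass
class ResampleResult:
    observed: float
    exceedances: int
    n_resamples: int
    p: float


def go_overrep(hits: set[str], annotation: dict[str, set[str]],
               essentiality: dict[str, bool], genome_genes: list[str],
               n_resamples: int = 10_000, seed: int = 0,
               strict: bool = True, min_size: int = 5,
               max_size: int = 200) -> pd.DataFrame:
    """Overrepresentation of each term among the hit genes.

    Per term the observed statistic is the hit-member count; the null is the
    member count of essentiality-matched random sets of the same size as
    the hit list. With ``strict`` (default) a resample counts against the
    term only when it has strictly more members ("more genes in the term");
    ``strict=False`` counts ties as well. BH correction across terms.
    """
    if not hits:
        raise ValueError("hit set is empty")
    genome_set = set(genome_genes)
    terms, _ = filter_terms(annotation, genome_set, min_size, max_size,
                            restrict_to=set(hits))
    rng = np.random.default_rng(seed)
    p_ess = _essential_fraction(set(hits), essentiality)
    k = len(set(hits) & genome_set)
    term_ids = sorted(terms)
    observed = {t: len(terms[t] & set(hits)) for t in term_ids}
    exceed = dict.fromkeys(term_ids, 0)
    for _ in range(n_resamples):
        sample = set(matched_resample(k, p_ess, genome_genes, essentiality, rng))
        for t in term_ids:
            n = len(terms[t] & sample)
            if (n > observed[t]) if strict else (n >= observed[t]):
                exceed[t] += 1
    rows = [{"term_id": t, "n_observed": observed[t], "n_members": len(terms[t]),
             "exceedances": exceed[t], "n_resamples": n_resamples,
             "p": exceed[t] / n_resamples} for t in term_ids]
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = adjust_bh(df["p"])
    return df


# ---------------------------------------------------------------------------
# Effect-size GO enrichment


def go_effectsize(effects: pd.Series, annotation: dict[str, set[str]],
                  essentiality: dict[str, bool],
                  n_stage1: int = 100, n_stage2: int = 10_000,
                  promote_below: float = 0.1, seed: int = 0,
                  min_size: int = 5, max_size: int = 200) -> pd.DataFrame:
    """Terms enriched for large allelic effect magnitudes, two-stage.

    ``effects`` maps gene -> effect size for every gene with screen data;
    genes without data are excluded from both term membership and the
    resampling universe. Per term, ``e_true`` is the median |effect| of its
    members with data; the null resamples matched gene sets of the same
    size and counts ``e_resample >= e_true``. Terms with stage-1 P below
    ``promote_below`` are re-run at ``n_stage2`` resamples; BH applies to
    the final P values.
    """
    universe = [g for g in effects.index if np.isfinite(effects[g])]
    universe_set = set(universe)
    abs_effect = effects.loc[universe].abs()
    terms, _ = filter_terms(annotation, universe_set, min_size, max_size)
    rng = np.random.default_rng(seed)
    term_ids = sorted(terms)

    def one_pass(term: str, n: int) -> ResampleResult:
        members = terms[term]
        e_true = float(abs_effect.loc[sorted(members)].median())
        p_ess = _essential_fraction(members, essentiality)
        k = len(members)
        exceed = 0
        for _ in range(n):
            sample = matched_resample(k, p_ess, universe, essentiality, rng)
            e_res = float(abs_effect.loc[sample].median())
            if e_res >= e_true:
                exceed += 1
        return ResampleResult(e_true, exceed, n, exceed / n)

    rows = []
    for t in term_ids:
        r1 = one_pass(t, n_stage1)
        promoted = r1.p < promote_below
        final = one_pass(t, n_stage2) if promoted else r1
        rows.append({"term_id": t, "n_members": len(terms[t]),
                     "e_true": final.observed, "exceedances": final.exceedances,
                     "n_resamples": final.n_resamples, "promoted": promoted,
                     "p": final.p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = adjust_bh(df["p"])
    return df


# ---------------------------------------------------------------------------
# Interaction enrichment


def _clean_edges(edges: list[tuple[str, str]]) -> set[frozenset]:
    """Undirected, deduplicated, self-loop-free edge set."""
    out = set()
    for a, b in edges:
        if a != b:
            out.add(frozenset((a, b)))
    return out


def internal_edge_ratio(genes: set[str], edges: set[frozenset]) -> float | None:
    """Edges internal to ``genes`` over edges touching ``genes``; None if none touch."""
    touching = [e for e in edges if e & genes]
    if not touching:
        return None
    internal = sum(1 for e in touching if e <= genes)
    return internal / len(touching)


def interaction_enrich(hits: set[str], edges: list[tuple[str, str]],
                       genome_genes: list[str], essentiality: dict[str, bool],
                       n_resamples: int = 10_000, seed: int = 0) -> dict:
    """Are hit genes more interconnected than matched random gene sets?

    The observed statistic ``r_true`` is the fraction of hit-incident edges
    that join two hits; the null recomputes the same ratio on
    essentiality-matched resamples (a resample with no incident edges
    contributes r = 0). One-sided P = #{r_resample >= r_true} / N. If the
    hits touch no edges, r_true and P are reported as None.
    """
    edge_set = _clean_edges(edges)
    r_true = internal_edge_ratio(set(hits), edge_set)
    if r_true is None:
        return {"r_true": None, "exceedances": None, "n_resamples": n_resamples,
                "p": None}
    rng = np.random.default_rng(seed)
    p_ess = _essential_fraction(set(hits), essentiality)
    k = len(set(hits) & set(genome_genes))
    exceed = 0
    for _ in range(n_resamples):
        sample = set(matched_resample(k, p_ess, genome_genes, essentiality, rng))
        r = internal_edge_ratio(sample, edge_set)
        if r is None:
            r = 0.0
        if r >= r_true:
            exceed += 1
    return {"r_true": r_true, "exceedances": exceed, "n_resamples": n_resamples,
            "p": exceed / n_resamples}


# ---------------------------------------------------------------------------
# McDonald–Kreitman


def mk_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene McDonald–Kreitman tests.

    ``counts`` is indexed by gene with columns Dn, Ds, Pn, Ps (fixed
    nonsynonymous/synonymous differences and polymorphisms). Per gene a
    two-sided Fisher exact test on [[Dn, Ds], [Pn, Ps]], BH-corrected
    across genes, plus the neutrality index NI = (Pn/Ps)/(Dn/Ds) where
    defined (NaN otherwise).
    """
    required = ["Dn", "Ds", "Pn", "Ps"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (counts[required] < 0).any().any():
        raise ValueError("MK counts must be non-negative")
    rows = []
    for gene, row in counts.iterrows():
        dn, ds, pn, ps = (int(row[c]) for c in required)
        _, p = stats.fisher_exact([[dn, ds], [pn, ps]], alternative="two-sided")
        ni = (pn / ps) / (dn / ds) if ps > 0 and ds > 0 and dn > 0 else float("nan")
        rows.append({"gene_id": gene, "Dn": dn, "Ds": ds, "Pn": pn, "Ps": ps,
                     "p_raw": float(p), "neutrality_index": ni})
    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_bh(df["p_raw"])
    return df
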