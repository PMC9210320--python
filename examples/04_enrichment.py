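"""Downstream resampling analyses on a hit list.

Builds a toy genome with gene-set annotations, an interaction network and
essentiality labels, then runs GO overrepresentation, effect-size
enrichment, interaction enrichment and McDonald-Kreitman tests.
"""

import numpy as np
import pandas as pd

from barhem import enrichment

rng = np.random.default_rng(0)
genome = [f"gene{i:03d}" for i in range(60)]
essential = {g: i % 5 == 0 for i, g in enumerate(genome)}
hits = set(genome[:8])

# one term concentrated in the hits, one unrelated
annotation = {"GO:stress": set(genome[:6]) | set(genome[20:22]),
              "GO:other": set(genome[30:40])}

overrep = enrichment.go_overrep(hits, annotation, essential, genome,
                                n_resamples=10_000, seed=1)
print("GO overrepresentation (null: essentiality-matched random gene sets):")
print(overrep[["term_id", "n_observed", "p", "p_adj"]].to_string(index=False))

effects = pd.Series(rng.normal(0, 0.3, len(genome)), index=genome)
effects[list(hits)] -= 1.5  # hit genes carry large allelic effects
eff = enrichment.go_effectsize(effects, annotation, essential,
                               n_stage1=100, n_stage2=10_000, seed=2)
print("\nEffect-size enrichment (two-stage, median |effect| per term):")
print(eff[["term_id", "e_true", "promoted", "p", "p_adj"]].to_string(index=False))

edges = [("gene000", "gene001"), ("gene001", "gene002"),
         ("gene002", "gene003"), ("gene010", "gene050")] + \
        [(genome[i], genome[i + 30]) for i in range(4, 10)]
inter = enrichment.interaction_enrich(hits, edges, genome, essential,
                                      n_resamples=10_000, seed=3)
print(f"\ninteraction enrichment: r_true={inter['r_true']:.3f} "
      f"p={inter['p']:.4f}  (fraction of hit-touching edges that join two hits)")

mk = enrichment.mk_test(pd.DataFrame(
    [{"Dn": 18, "Ds": 4, "Pn": 6, "Ps": 22},
     {"Dn": 9, "Ds": 11, "Pn": 10, "Ps": 10}], index=["fast", "neutral"]))
print("\nMcDonald-Kreitman tests (NI < 1 suggests adaptive divergence):")
print(mk[["gene_id", "neutrality_index", "p_raw", "p_adj"]].to_string(index=False))
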