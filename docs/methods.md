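# Methods

## The screen and its statistic

A reciprocal hemizygosity screen compares, gene by gene, two classes of
clones in one pooled competition: hybrids whose *S. cerevisiae* allele is
disrupted by a barcoded transposon (leaving the *S. paradoxus* allele
intact, "par uncovered") and their reciprocal counterparts. Clone
abundance is read out by barcode sequencing before and after growth at an
experimental temperature, with a matched control-temperature arm.

For a genotype (barcode) with normalized abundance `a_exp,i` in
experimental replicate `i` and mean normalized control abundance
`a_ctrl,mean`, the temperature effect is

    t_i = log2(a_exp,i / a_ctrl,mean),   i = 1..n_exp.

Per gene, the t values of all genotypes and replicates are pooled per
allele and the two vectors compared with a two-sided Mann–Whitney U test
(exact null when both sides have ≤8 values and no ties, otherwise the
normal approximation with tie correction), BH-corrected across genes. The
effect size is the difference of per-allele means of genotype-mean t
(cer-insert minus par-insert); a hit requires adjusted P < 0.05 **and**
effect size < −0.5, i.e. a thermotolerance defect specific to losing the
*cerevisiae* allele.

## Read processing

**Junction detection.** The final 22 bp of the transposon right arm are
scanned against each read at every offset; the leftmost hit with Hamming
distance ≤ 2 is accepted, splitting the read into barcode (upstream, at a
configurable gap) and genomic fragment (downstream). Ties go to the
leftmost offset for determinism.

**Barcode satellite collapsing.** A sequencing error in a barcode creates
an "off-by-one" satellite of a much more abundant parent. A barcode is
eliminated iff another barcode within Hamming distance 1 has ≥10× its read
count; the same rule is then applied at distance ≤2 to the survivors.
Elimination is simultaneous against the full input set and is removal, not
merging. The dominance ratio 10 is a parameter: at a 1.38% per-base error
rate, true satellites are ≳50× rarer than their parents, so 10 separates
them while keeping genuinely distinct clones that happen to be neighbours
(candidate search uses the shared-variant hash — two barcodes are within
distance 2 iff their distance-≤1 neighbourhoods intersect — and is tested
against an all-pairs oracle).

**Mapping.** Fragments are mapped by exact k-mer seeding (k = 15, disjoint
seed offsets guarantee detection up to 2 mismatches) with full-length
Hamming verification on both strands; score = matched bases − mismatches.
This replaces a production short-read aligner deliberately: at the scale
of the simulated genomes it is deterministic, exhaustive within its
mismatch bound, and directly checkable. The insertion position convention
is the 1-based coordinate, on the reference strand, of the first genomic
base 3′ of the transposon arm.

**Classification.** A candidate location is *strong* when its best match
has ≤ `strong_margin` (default 2) mismatches. Barcodes with ≥2 strong
locations are `multilocus`; one strong location with more reads assigned
to weaker locations is `ambiguous`; only `unique` barcodes (one strong
location holding at least as many reads as all weaker ones) enter the
catalog. Every input read is accounted once in the QC tallies.

**Bar-seq.** Counting is catalog-restricted and exact-match: barcodes
read out between the two priming flanks (each located with ≤2 mismatches)
are tallied only when they match a Tn-seq-validated barcode; everything
else is an orphan and discarded. No error-tolerant rescue is attempted at
this stage — erroneous Bar-seq barcodes are simply orphans.

## Filters and their defaults

| parameter | default | role |
|---|---|---|
| arm / mapping mismatches | 2 | junction and fragment matching tolerance |
| dominance ratio | 10 | satellite collapsing |
| genotype CV max | 2.0 | reproducibility filter (see below) |
| min normalized control reads | 1.1 | coverage floor on the t denominator |
| min genotypes per allele | 3 | gene eligibility |
| pooled-t CV max | 10 | gene-level reproducibility gate |
| hit thresholds | P_adj < 0.05, effect < −0.5 | calling |
| resamples | 10,000 (two-stage 100 → 10,000, promote < 0.1) | enrichment |
| GO term size | [5, 200] | term filtering |

**What the genotype CV filter measures.** The CV ≤ 2.0 filter is applied,
by default, to the genotype's normalized abundance across the control
replicates — the denominator of t, whose measurement noise propagates
into every t_i. The alternative reading, CV of the t vector itself
(`RhTestParams.cv_on = "t"`), is implemented but not the default, for a
structural reason: CV(t) = sd/|mean| diverges as mean(t) → 0, so it
discards genotypes whose temperature effect is reproducibly *zero* —
including the intact-allele genotypes of every true-effect gene, which
then starves the ≥3-genotypes-per-allele gate. Under a pure null it
retains only ~20% of genotypes regardless of sequencing depth
(P(|mean| > sd/2) for a mean that is noise around zero is scale-free).
A filter meant to remove irreproducible measurements should not be
triggered by a true value of zero.

**Dropouts.** A genotype absent from all control samples is excluded
(t undefined). A zero experimental count with positive control mean gives
t_i = −∞; before filtering and testing it is replaced by
log2(0.5 / a_ctrl,mean) — a half-pseudoread floor that keeps fully
dropped-out clones, the strongest phenotypes, in the test. The pseudoread
mass is configurable.

**Normalization target.** Each sample's counts are scaled so its total
equals the *median* raw column total. This keeps normalized abundances on
a raw-read scale, so the 1.1-read floor retains its meaning, and makes
all t values exactly invariant to rescaling any sample's counts.

## Resampling nulls

All enrichment tests draw null gene sets matched to the focal set's size
and essential-gene fraction: `round(k·p_ess)` genes from the essential
stratum, the rest from the non-essential stratum, without replacement.
P-values are plain exceedance proportions (no smoothing), so they lie on
{0, 1/N, …, 1} and are reproducible bit-for-bit given a seed; a reported
0 should be read as "< 1/N". Overrepresentation counts resamples with
*strictly* more term members than observed (the `strict=False` flag
counts ties too, which is the convention the hypergeometric oracle in the
tests uses — with a discrete statistic the two differ at ties).
Interaction enrichment uses the internal-edge ratio r = (edges joining
two focal genes) / (edges touching any focal gene) on an undirected,
deduplicated, self-loop-free edge set; a resample touching no edges
contributes r = 0, and a focal set with no incident edges yields NA
rather than a number.

## The simulator

The generator emulates the screen the pipeline is built for: a hybrid
genome with every gene present once per species on species-labelled
chromosomes plus a gene-free plasmid contig; a pool of clones with unique
20-bp barcodes (pairwise Hamming distance ≥ 3, so injected errors are
unambiguous satellites); junction and amplicon reads with uniform
per-base substitution errors at 1.38%; and a competition of 12
experimental + 12 control replicates.

Growth is deterministic exponential: a clone with per-doubling relative
fitness w at the experimental temperature reaches expected frequency
∝ f0·w^D after D doublings (D defaults to 12, inside the 10–15 range a
pooled competition maintains in log phase); sequencing then draws one
multinomial per sample at a fixed library size (depth × pool size).
Drift between back-dilutions is omitted — bottlenecking in such
competitions is modest, with diversity retained at the order of the pool
size — so the only stochasticity after pool construction is multinomial
sampling. The identifiable truth is
`true t-difference = D·log2(w_par_uncovered / w_cer_uncovered)` per gene.

Defaults (sequencing error 1.38%, Tn-seq depth 47, 12+12 replicates,
20-bp barcodes) mirror the benchmark experiment; pool sizes and gene
counts are desk-scale (tests use 8–200 genes) so the whole suite runs in
well under a minute per screen.

**What the simulator does not model,** and hence what passing tests do
not show about real data: base-quality-dependent errors and indels; PCR
duplicates and amplification jitter; SNP-level sequence divergence
between the two species' alleles (allele identity is carried by
chromosome labels, and the two allele sequences are independent random
draws — real homeologous genes are ~90% identical, making read mapping
harder than here); biological replicate-to-replicate variance beyond
sampling noise; and clone-specific insertion-position effects on fitness.
The null calibration results in particular describe multinomial
sampling noise only.

Two properties of the idealized null are worth knowing when reading
calibration numbers. First, the pooled Mann–Whitney treats the 12
replicate t values of each genotype as independent, but they share the
genotype's control-mean denominator (intra-genotype correlation ≈ 1/13
independent of depth), so raw p-values among *tested* genes run
anti-conservative (~15–25% below 0.05 under a pure null); the BH + effect
threshold hit rule still yields zero null hits. Second, the pooled-t
CV ≤ 10 gate removes genes whose per-allele mean t sits exactly at zero,
which under a pure null is many of them; real screens, where every clone
has some nonzero temperature response, are gated far less.

## Numerical and design choices

- One global seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence`, so any stage rerun standalone reproduces
  its in-pipeline output byte-for-byte.
- Ties in junction detection and in best-location assignment break
  leftmost (then lexicographic) for determinism.
- BH is applied once across all tested genes per screen (not per allele),
  and once across all tested terms per enrichment run.
- `effect_size` weights genotypes equally within an allele (not
  read-weighted): each inferred hemizygote genotype is one biological
  observation of the allele.
- The off-by-two barcode filter reuses the same dominance criterion as
  the off-by-one pass (configurable); an unconditional distance-2 purge
  would also delete genuine clones in dense pools.
- Degenerate inputs fail loudly with the offending field or sample named:
  zero-total samples, positions outside contigs, empty t vectors, strata
  smaller than their matched draw.

## Known limitations

- The k-mer mapper does not do gapped alignment; indel-bearing junction
  reads are dropped (counted as unmapped), which the error model never
  produces but real data would.
- `classify_mapping` judges "strong" against a single fragment length per
  barcode; reads of heterogeneous lengths are normalized by their own
  length upstream.
- Enrichment assumes the term→gene map is already propagated (no GO
  graph reasoning) and that edge lists are curated externally.
- At very low Bar-seq depth (≲15 reads/clone) satellite parents fall
  below the dominance threshold and error barcodes survive into the
  catalog; they are subsequently removed by the abundance floor, but
  catalog size inflates. Depth ≥ ~40 behaves cleanly.
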