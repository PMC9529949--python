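# Methods

## Coordinate model

Every interval in the system is 0-based, half-open `[start, end)` — the
BED convention. GTF gene lines are converted on read (`[start-1, end)`);
the TSV gene dialect carries half-open coordinates directly. "Overlap"
always means ≥ 1 shared base under these semantics, so touching intervals
do not overlap. Strand is parsed and preserved but never used in
assignment: enhancer–gene windowing is strand-agnostic. Chromosome names
are exact strings; an opt-in switch strips or adds the `chr` prefix at
parse time but is off by default so that mismatched annotations fail
loudly rather than silently matching nothing.

## eRRG identification

An eRNA region is the window of `half_width` bp (default 3,000) on either
side of the enhancer midpoint `floor((start+end)/2)`. The floor makes
even-length enhancers deterministic; the window start is clamped at the
chromosome origin, and — because chromosome sizes are not an input — the
end is not clamped. Regions overlapping any gene body of any biotype are
discarded ("known genes" is read without restriction).

The contact domain is operationalized as a window of total length
`domain_length` (default 185,000, the median contact-domain length
reported for mammalian genomes) centered on the eRNA midpoint:
`[max(0, m - L//2), m + (L - L//2))`, so odd lengths keep the full
configured width. A gene is assigned on ≥ 1 bp overlap with that window.
This fixed symmetric window was chosen over per-locus Hi-C boundaries
because it is parameter-light and requires no chromatin input; it is the
main approximation of the method.

Per-resource gene sets are intersected at the **gene level** — a gene
counts if every resource yields it from *some* enhancer, not necessarily
the same locus. Overlapping enhancer records within a resource are kept
as-is (resources count enhancers before assignment); duplicate
(region, gene) pairs are deduplicated only at the gene-set level.

The interval index is an interval tree per chromosome with deterministic
hit ordering (start, then id). Its contract is exact agreement with the
all-pairs double-loop scan, which the test suite enforces on random
instances up to 5,000 enhancers × 4 resources × 1,000 genes.

## Expression statistics

Per-gene mean and CV (`100·sd/mean`, sample sd, NaN at mean 0) are
computed on the expression unit supplied; the package does not pick a
unit for this contrast. Random gene sets are drawn size-matched, without
replacement, from a universe defaulting to all genes with nonzero
expression somewhere (`--universe {all, expressed}` is the switch); the
per-gene values of all draws are **pooled** for the rank-sum comparison
(per-set averaging was the alternative; pooling uses every draw at full
resolution).

The rank-sum test uses the exact null distribution (enumeration) when the
pooled sample has ≤ 12 tie-free observations, otherwise the normal
approximation with midranks, tie correction and continuity correction.
FDR is Benjamini–Hochberg step-up, capped at 1, stable under input order.

The built-in two-group DE procedure is deliberately simple: per-gene
rank-sum on `log2(CPM + pseudocount)` and a fold change of group CPM
means with the same pseudocount. It is a self-contained stand-in for a
negative-binomial count model so that the pipeline can run and be tested
end-to-end; for real cohorts an external DE table (gene, log2fc, pvalue,
fdr) should be supplied and is accepted everywhere downstream. Thresholds
are strict as conventionally printed: FDR < 0.05 **and** |log2FC| > 1, so
a gene at exactly log2FC = 1 is not called.

The resampling null draws `n_reps` random sets of the eRRG set's size and
counts up/down calls per draw; the mean converges to the hypergeometric
expectation `set_size·K/N`, which the tests check to 3 standard errors.

## Group contrasts

**Methylation.** Δβ = mean(high) − mean(low); "hypo" therefore means
hypomethylated in the high-risk group. The per-probe test is Welch's t on
the beta values with BH adjustment — a documented substitute for the
unexported internals of the array-processing toolkits usually used on
450k data; beta values must be complete (imputation is upstream) and in
[0, 1]. Constant probes get p = 1 rather than NaN. Calls require
FDR < 0.05 and |Δβ| > 0.15, both strict.

**Mutations.** Gene×sample status is binarized (≥ 1 qualifying variant);
silent variants do not qualify by default (`--include-silent` flips
this — the rule is a choice, not a community standard). SNV classes are
the six pyrimidine-collapsed substitutions, purine-reference SNVs mapped
through the reverse complement. Differential mutation per gene is a 2×2
Fisher exact test (mutated/not × high/low) on genes with ≥ `min_mutated`
(default 5) mutated samples — the floor avoids degenerate tables and is
exposed as a flag. Calls use the **raw** p < 0.05, matching common
practice for this analysis; a BH column is emitted alongside for
transparency. Co-occurrence uses the two-sided Fisher test per unordered
pair with the odds-ratio direction as the label (OR > 1 co-occurring,
otherwise exclusive); one-sided variants were not implemented.

## Survival

The risk score is the pure linear predictor Σ βg·xg — no intercept, no
refitting — because the median split is invariant under monotone
transforms, so intercept handling cannot change the groups. Ties at the
median go to the low-risk group, preserving "high = strictly above
median"; an even, tie-free cohort splits exactly in half. Kaplan–Meier
estimation and the log-rank test are delegated to lifelines and held to
hand-computed product-limit and O−E/variance oracles in the tests
(the four-subject worked example gives χ² = 49/17 ≈ 2.882). Expression
units for scoring must match the coefficients' training units; the CLI
offers `--transform log2cpm` for count matrices.

## Synthetic data

The generator emulates a tumor cohort study at desk scale and is a pure
function of its config (single seeded RNG stream; regeneration is
byte-identical). The genome is a grid of 250 kb blocks, each holding at
most one gene and one enhancer, spaced so a contact-domain window never
reaches a neighboring block's gene — this makes the planted truth
unambiguous. Block roles plant each outcome: *target* blocks (gene +
enhancer shared by all resources, midpoint 12 kb past the gene end so the
±3 kb region is intergenic but the ±92.5 kb window covers the gene),
*decoy* blocks (resource-private enhancer → eRRG of one resource only),
*filtered* blocks (enhancer inside a gene → removed by the overlap
filter), *background* genes and enhancer *deserts*. Ground truth is
computed by a plain nested-loop scan over (enhancer, gene) pairs,
independent of the pipeline's interval index, so it doubles as an oracle.

Default ("demo") conditions: 4 chromosomes × 12.5 Mb, 160 genes (55%
protein-coding, the rest lncRNA), 40 enhancers per resource with 50%
shared across resources (20 planted eRRGs), 120 tumor / 40 normal
samples, negative-binomial counts with dispersion 0.2 and log-normal
baseline means (~15), a 7× baseline boost for planted eRRGs, planted
log2FC = 2 on 35%/20% (up/down) of the eRRGs, 1,200 probes with 40
planted DMPs at Δβ = 0.3 (90% hypomethylated in high-risk, sd 0.05),
background mutation rate 0.15 per gene per sample with 5 planted genes at
0.40 vs 0.05 between risk groups and a substitution mix dominated by C>T
(45%), a 12-gene signature with N(0, 0.4) coefficients, exponential
survival with log-hazard 1.0 per SD of risk score (baseline median ~2
years) and 20% uniform censoring. These sizes run the full pipeline in
seconds; they are scaled-down analogues of a real cohort, and the planted
DE fractions are larger than typically observed so the planted sets stay
non-trivial at 20 eRRGs.

What the generator does **not** emulate: linkage/TAD structure beyond the
block grid, overlapping genes (a separate stress fixture covers gene
removal/rescue logic), batch effects, purity/ploidy, per-group global
mutation burden differences, and library-size variation beyond what NB
sampling induces. Consequently, passing tests demonstrate correctness of
the assignment logic and calibration of the statistics under the stated
models — not robustness to the full messiness of real tumor data. One
specific caveat: with a shared NB dispersion, the CV contrast between
eRRGs and random genes is weak (high expression lowers CV only through
the Poisson term, and planted fold changes inflate eRRG CV), so the
generator guarantees the mean contrast but not a lower eRRG CV.

## Numerical choices and degenerate inputs

- Exact rank-sum enumeration threshold: pooled n ≤ 12 and tie-free;
  beyond that the corrected normal approximation (the two agree to ~3
  decimals at the boundary). A fully constant pooled sample returns p = 1.
- Fisher odds ratios use the sample cross-product with ∞ (one zero
  product) and NaN (both zero) conventions; NaN pairs label as
  "exclusive" since no co-occurrence evidence exists.
- Betas are clipped (not resampled) into [0, 1]; with sd 0.05 the
  distortion is negligible except within ~2 sd of the boundaries.
- `median_split` raises on all-identical scores; `erna_region` and the
  domain window reject non-positive widths; empty filter results warn
  rather than raise.
- All sampling takes an explicit integer seed; no global RNG state is
  touched anywhere.

## Known limitations

- The fixed-length contact domain ignores real domain boundaries; genes
  just outside 92.5 kb are never assigned, genes inside are always
  candidates regardless of insulation.
- Gene-level intersection across resources does not require the same
  enhancer locus to replicate across resources.
- The built-in DE test has no dispersion sharing and loses power relative
  to count models at small n; it exists for self-containedness.
- Survival analysis stops at the median-split log-rank comparison;
  Cox/Lasso fitting, time-dependent ROC and nomograms are out of scope.
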