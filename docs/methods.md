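# Methods

## Normalization model

Raw probe counts from a digital hybridization lane are modeled as
`count[i, s] = a[i] · L[s] · ε[i, s]` — a probe abundance, a
multiplicative lane effect, and multiplicative noise — on top of an
additive non-specific background. The three normalization steps each
remove one component:

1. **Positive-control scaling.** Spiked control probes at a known
   titration share the lane effect but not the biology, so the
   geometric mean `g_s` of a sample's positive-control counts estimates
   `L[s]` up to a constant. Each sample is scaled by
   `factor_s = mean(g) / g_s` (arithmetic mean of the per-sample
   geometric means; a geometric-mean center is available via
   `NormParams.pos_mean_type`). Geometric rather than arithmetic
   per-sample summaries keep the six-point titration's decades from
   being dominated by the top spike.
2. **Background thresholding.** Negative-control probes have no target;
   `threshold_s = mean(neg_s) + k_sd · sd(neg_s)` (sample SD, n−1;
   `k_sd = 2` by default). Endogenous values at or below the threshold
   are set to zero ("floor", the default — a *threshold*, not a
   subtraction); a "subtract-and-clamp" mode exists for users who want
   background-corrected magnitudes. The boundary is inclusive so a
   count exactly at threshold is called background.
3. **Content normalization.** Differences in input amount are removed
   by scaling to the geometric mean of the top `top_n = 100` endogenous
   probes. The probe set is chosen **once**, by mean abundance across
   samples, so the per-sample factors are comparable; a per-sample top
   set would conflate composition changes with input amount.

The step order (controls → background → content) follows the
conventional nCounter sequence; the platform literature states the
scalers but not the order, and the order matters only at the
background boundary. Zeros entering a geometric mean are replaced by a
pseudocount (default 0.5, configurable). With all counts positive the
pipeline is exactly invariant to a uniform rescaling of any single
sample's raw counts (shares change by < 1e-9); with zeros the
pseudocount breaks this only at the last decimal places.

Replicate QC is the Pearson correlation of normalized endogenous
profiles within each replicate group; zero-variance profiles yield an
undefined r reported as missing. Replicates are merged by per-probe
arithmetic mean; shares are recomputed on the merged profile.

## Cargo selection

Ranking is a stable descending sort with lexicographic tie-breaks, so
the output is independent of input row order. Two selection rules are
exposed because the field's "dominant set" is defined informally:

* `select_by_share_floor(ranked, floor=0.007)` — keep every miRNA
  holding more than 0.7% of total signal (the default, matching the
  convention that the excluded tail tops out below 0.7%);
* `select_by_cumulative_fraction(ranked, f=0.79)` — the minimal prefix
  reaching 79% of signal.

Both report coverage (summed share) and the dominance ratio (mean
selected value / mean excluded value; infinite with a flag when the
tail is all zeros). Minimality of the cumulative rule is tested by
exhaustive prefix enumeration.

## Target consensus

Per-source predictions are deduplicated (max score wins), miRNA names
are matched case-insensitively with the species prefix (`hsa-`)
ignored, gene symbols uppercase — no alias resolution is attempted.
The consensus keeps edges supported by `min_support ≥ 5` of the
available sources (support = distinct sources, never inflated by
duplicates); the integrated score is the arithmetic mean of the source
scores ("max" available) since the upstream aggregators do not publish
their formulas. Confidence bands are empirical tertiles of the
integrated score over retained edges; ties at a boundary stay in the
upper band (deterministic, and consistent with "above the bottom
third"), and identical scores collapse to a single "top" band with a
warning.

## Enrichment

The over-representation statistic is the one-sided hypergeometric
upper tail `P(X ≥ k)` with `X ~ Hypergeom(N, K, n)` on a common
background (default: the annotation universe; a user background is
intersected with the universe first). Implementation defers to
`scipy.stats.hypergeom`; the test suite pins it against an exhaustive
draw-enumeration oracle on the full grid `N ≤ 12` and closed-form
summation spot checks to `N = 30`.

The significance filter is deliberately two-gated:

* `passes_p`: raw p < `p_max = 1e-6`. Raw p, not the BH q (reported
  alongside), because the extreme cutoff already provides family-wise
  control — under the null generator, 200 simulated datasets produce a
  false positive at most once.
* `passes_fold`: fold enrichment strictly above
  `mean + sd_mult · sd` (sample SD, `sd_mult = 1`) of the fold
  distribution over terms with `k ≥ 1`. Zero-overlap terms are
  excluded from the filter population: they are never candidates and
  would only drag the mean toward zero. "One variance above the mean"
  and "one SD above the mean" appear interchangeably in the field for
  this filter; SD is used, since a variance is not commensurable with
  fold units.

Terms failing significance with `1e-6 ≤ p < 0.1` can be listed as
trends. GO-graph ancestor propagation is out of scope — terms are the
flat sets given in the GMT.

## Network

The tripartite graph has typed nodes (miRNA / gene / term) and edges:
`targets` (miRNA→gene, carrying support and score), `annotated`
(gene→term), and `summary` (miRNA→term, weight = distinct shared
genes). Gene nodes are restricted to genes of significant terms; gene
term-membership is stored both as explicit term nodes and as a
`processes` gene attribute (`|`-joined for GraphML safety), supporting
both an enrichment-map view and a summary view from one structure.
`rank_candidates` orders miRNAs by distinct targets within a term
scope (ties lexicographic); `unique_targets` subtracts the union of
all other cargo miRNAs' targets. No layout is computed — proximity in
published maps is a viewer artifact. GraphML export round-trips
exactly (integer weights restored on read); SIF is one edge per line.

## Synthetic-data generator

The generator emulates the profiling regime, not any real organism's
identifiers; probes are `syn-mir-###`, genes `GENE####`.

* **Counts.** Probe abundances are log-normal(μ = 4.0, σ = 1.9) drawn
  by stratified (Latin-hypercube) sampling — one draw per probability
  stratum, permuted — so the marginal stays log-normal while the
  realized spectrum, and hence the top-tail share, is stable across
  seeds. σ = 1.9 follows from the target regime: for a log-normal, the
  share of total mass above the upper `p` quantile is `Φ(σ − z_p)`;
  the top 23 of 171 probes (p ≈ 0.135, z ≈ 1.11) carrying ≈ 79%
  requires σ ≈ 1.9. Counts are Poisson around
  `abundance · lane · exp(N(0, 0.2))`, with lane effects uniform in
  (0.8, 1.2); positive controls follow the standard 128→0.125 fM
  titration at 60 counts/fM; negatives are Poisson(8). Frozen
  calibration (100 seeds, `scripts/calibrate_generator.py`): top-23
  coverage median 0.774, within [0.70, 0.85] in 94/100 seeds;
  replicate Pearson r ≥ 0.88, median 0.975.
* **Target DB.** True miRNA→gene edges are planted at density 0.02
  over a 2000-gene universe (the designated "planted" miRNA gets a
  2.5× boosted density, making it the broadest regulator); each of 6
  sources reports a true edge with probability 0.85 and score
  Beta(6, 2), a false pair with probability 0.05 and score Beta(2, 4).
  Support at ≥ 5 of 6 then retains ~78% of true edges and ~2e-6 of
  false ones, so consensus precision is ~100% vs ~7% for the union
  (calibration: support-5 precision beat support-1 in 20/20 seeds).
* **Annotations.** 50 terms of 15–40 genes; null terms sample the
  universe uniformly. A planted term takes the top of the size range
  and draws its effect fraction (strong 0.9, moderate 0.5) from genes
  truly targeted by the selected miRNAs, preferring *coordinately
  targeted* genes (≥ 2 cargo miRNAs, sampled weighted by that degree,
  with a fallback when too few exist) and taking half its picks from
  the planted miRNA's own targets. Coordinate targeting is the regime
  the analysis is meant to detect — processes convergently regulated
  by many cargo species — and it is also what lets planted genes
  survive the bottom-tertile confidence drop. Frozen calibration:
  planted strong term recovered as significant in 100/100 seeds
  (direct consensus flow), planted miRNA ranked first in 100/100.

Sub-generators (counts / DB / annotations) are seeded by spawning one
`SeedSequence`, so each output is reproducible independently of how the
others were consumed.

**What passing tests do not show.** The generator's sources are
conditionally independent given edge truth; real prediction databases
share algorithms and training data, so real consensus filtering is
less powerful than the calibration suggests. Annotations here are
flat, disjoint-by-construction random sets; real GO terms overlap
heavily and inherit along the graph, inflating folds for related
terms. Probe-level sequence effects (GC content, cross-hybridization)
are not modeled.

## Numerical choices and degenerate inputs

* Sample (n−1) SD everywhere an SD is taken.
* Cumulative-fraction selection tolerates 1e-12 float slack at the
  boundary; `f = 1` always selects everything.
* A single negative control gives SD 0 (threshold = its value · 1).
* All-equal folds: threshold equals the common fold and nothing passes
  (the fold gate is strict).
* Dominance ratio over an all-zero tail is `inf` with an explicit
  flag, never an exception.
* Pipeline summaries are JSON with sorted keys; reruns on identical
  inputs are byte-identical.

## Problem sizes

Default simulations use 171 probes × 2 replicates, 23 cargo miRNAs ×
2000 genes × 6 sources, and 50 annotation terms — small enough that
the full test suite (including the 200-dataset null calibration and
100-seed recovery runs) completes in about a minute and a half, while
keeping every statistical regime of interest (extreme p cutoffs,
tertile boundaries, heavy-tailed abundances) exercised at realistic
proportions.

## Known limitations

* No RCC (vendor) file parsing; counts enter as CSV.
* No housekeeping-probe normalization mode (the class is accepted and
  ignored) and no differential-abundance testing.
* Gene identity is uppercase-symbol string match; no alias or
  orthology mapping.
* The published landscape counts from the original mirDIP/GO analyses
  are version-dependent and not reproducible from first principles;
  the pipeline reproduces the procedure, and the acceptance checks are
  therefore property-based on synthetic ground truth plus the
  supplementary read-count statistics when that workbook is supplied
  locally.
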