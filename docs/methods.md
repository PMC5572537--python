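# Methods

This note records the statistical models implemented in `rgstable`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer should know
about.

## The screening model

The screen assumes expression is compared on the TPM scale after
between-sample normalization.  Given raw counts `y_gj` (gene g, sample j):

* **Detectable-expression filter.**  A reference gene must be measurable in
  every sample, so any gene with a zero count anywhere is removed before
  scoring.  The filter is deliberately strict: a gene absent in one lesion
  type is useless as a qPCR reference even if abundant elsewhere.
* **TMM.**  Scaling factors are estimated against the sample whose
  75th-percentile CPM is closest to the cohort mean of 75th percentiles.
  Per-gene log-ratios M and log-abundances A are computed over genes with
  nonzero counts in both samples; the extreme 30 % by M and 5 % by A are
  trimmed two-sidedly (rank-based, average ranks on ties); the factor is
  2^(weighted mean of surviving M) with inverse delta-method binomial
  variance weights; finally factors are rescaled to geometric mean 1.
  Quantiles are computed with linear interpolation (R type 7) throughout
  the package.
* **TPM.**  `rate_g = effective_count_g / length_g`, column-rescaled to
  sum 10⁶.  Gene length is the union of exonic bases across isoforms
  (strand-agnostic), computed from a GENCODE-dialect GTF or supplied as a
  table.  Two variants exist behind a flag: `raw` uses raw counts;
  `tmm` (default) divides counts by the sample's TMM factor first.  The
  library size itself cancels in the TPM ratio, so only the factor
  matters.  The default follows the pipeline's normalize-then-transform
  order; with the original cohort's deposited counts unavailable offline,
  the choice between the variants could not be settled empirically, so
  both remain available.
* **Scores.**  CoV uses the n−1 standard deviation; MFC is max/min (well
  defined because of the filter); the selection score is their product,
  and candidates are genes with score ≤ the lower-quartile (type-7)
  threshold, reported sorted by ascending score.  Ties at the threshold
  are included, which is why the candidate count can deviate slightly
  from a quarter of the genes.
* **BCV.**  The negative-binomial dispersion φ (Var = μ + φμ²) is profiled
  on a 43-point log-spaced grid spanning 10⁻⁶–10.  At each grid value the
  per-gene mean is re-fit by Fisher-scoring Newton iterations with
  per-sample offsets `library_size × TMM factor`.  The common dispersion
  maximizes the summed profile likelihood; each gene then maximizes its
  own likelihood plus `prior_df / (n_samples − 1)` times the cohort-average
  per-gene likelihood, a weighted-likelihood shrinkage that recovers the
  common estimate as `prior_df → ∞`.  Maximizers are refined by quadratic
  interpolation between grid points.  `prior_df = 10` by default — enough
  shrinkage to stabilize 29-sample estimates without masking genuinely
  dispersed genes.  This estimator is an intentionally transparent
  approximation of empirical-Bayes tagwise dispersion estimation; exact
  agreement with any particular implementation is not claimed, and the
  tests assert parameter recovery on simulations instead (median BCV
  < 0.05 on Poisson data; within [0.32, 0.48] for φ = 0.16 at n = 100).

## geNorm

Ct replicates are averaged arithmetically, then converted to relative
quantities `q = E^(minCt − Ct)` with amplification efficiency `E = 2` by
default (no per-primer efficiencies are assumed; per-gene values can be
passed).  For genes j, k the pairwise variation `V_jk` is the n−1 standard
deviation over samples of `log2(q_j/q_k)`; `M_j` is the mean of `V_jk`
over partners.  Ranking removes the highest-M gene repeatedly until two
remain (ties broken lexicographically and logged); the recorded M of each
gene is its M at removal.  `V(n/n+1)` is the standard deviation of the
log2 ratio of geometric-mean normalization factors built from the top n
versus top n+1 genes; the smallest n with V < 0.15 is recommended.  The
conventional "M ≤ 0.5 indicates homogeneous samples" guideline is exposed
as an annotation, never enforced.

## NormFinder

Log2 relative quantities `y_igj` (gene i, group g, sample j) are first
centred per sample across genes, removing sample-specific effects such as
cDNA input.  Within each group the model computes the gene's group mean
deviation `a_ig`, its intragroup variance `s²_ig` (n−1), and the
intergroup difference `d_ig = a_ig −` (group-size-weighted mean over
groups), with sampling variance

    v_ig = ((k−1)/k)² s²_ig/n_g + Σ_{i'≠i} s²_{i'g} / (k² n_g).

The spread of real intergroup differences is estimated per group as
`γ²_g = max(0, Var_i(d_ig) − mean_i(v_ig))` and each `d_ig` is shrunk by
`γ²/(γ² + v_ig)` — genes are not rewarded for noisy estimates of a
near-zero difference.  The stability value is

    ρ_i = mean_g ( |d̃_ig| + sqrt( s²_ig + v_ig γ²_g/(γ²_g + v_ig) ) ).

The variance term deliberately includes the intragroup variance itself,
not only the posterior uncertainty of the bias: with `γ² = 0` the value
reduces to the pure intragroup spread, and with a single group to
`sqrt(s²)` — both reductions fail if the term contains only the posterior
part (every ranking would collapse to ties whenever no real intergroup
variation exists).  The best pair is found exhaustively: each pair's log
signals are averaged into a virtual gene, appended to the panel, and the
full model re-fit; the pair whose virtual gene scores lowest wins.  Note
that this criterion rewards pairs whose intergroup drifts cancel — by
design, since their average is the less biased normalizer — so on panels
dominated by drifting genes it may prefer an anti-correlated unstable
pair over two individually stable genes.  All intergroup quantities are
measured relative to the panel average; a panel whose average drifts
makes truly stable genes look deviant.  This identifiability limit is
inherent to the model, not to this implementation.

## Comparative Ct

`ΔCt_s = Ct_target,s − mean(Ct_refs,s)` (the arithmetic mean of reference
Cts equals the geometric mean of reference quantities at equal
efficiencies), `ΔΔCt_s = ΔCt_s − mean over calibrator samples`, fold
`= 2^−ΔΔCt` (Livak; efficiency fixed at 2).  Replicate triplets with Ct
standard deviation above 0.5 cycles are flagged, not dropped.  Group
comparison runs one-way ANOVA and Tukey HSD on the fold changes (the
plotted scale); a flag switches the tests to the ΔΔCt scale, which is
preferable when fold changes are strongly right-skewed, and the choice is
recorded in the result's notes.  Groups of identical values short-circuit
to F = 0, p = 1 rather than relying on the F distribution at zero
variance.

## Over-representation analysis

Upper-tail hypergeometric p per gene set (sets intersected with the
universe first), Benjamini–Hochberg FDR across sets, and the enrichment
percentage `100 × overlap / set size`.  The recommended universe is the
set of genes surviving the detectable-expression filter — the population
the candidate list was actually drawn from.

## The synthetic cohort

`simulate_counts` emulates the statistical structure the screen assumes:

* 29 samples in four lesion groups (13 AK, 7 IEC, 5 SCC, 4 normal skin)
  by default; group sizes and labels are configurable.
* Counts are negative binomial with `Var = μ + φμ²`, so BCV = √φ by
  construction and dispersion-recovery tests have exact ground truth.
* Baseline means are log-uniform on [0.5, 5000] (a realistic bulk RNA-seq
  dynamic range); library-size factors log-normal with CV 0.25; per-group
  log2 fold-changes N(0, 1) for unstable genes.
* Designed-stable genes (10 % by default) have zero fold-change in every
  group and dispersion at the low end of the range (0.01, i.e. BCV 0.1).

`simulate_ct` inverts the comparative-Ct model for a chosen gene panel:
`Ct = intercept − log(expression)/log(E) + N(0, noise_sd)` per technical
replicate (defaults: intercept 34, E = 2, noise 0.2 cycles, triplicates).
Expression is the *sample's* abundance: the group mean multiplied by a
gamma variate with the gene's dispersion (mean 1, variance φ — the mixing
distribution behind the NB counts).  The same biological variability that
spreads the sequencing counts therefore spreads the Ct values, which is
what lets geNorm and NormFinder distinguish designed-stable genes from
dispersed ones within groups.  Technical replicates share the sample's
abundance and differ only by cycle noise.

What the generator does **not** emulate: batch effects beyond library
size, patient pairing between samples, isoform-level variation,
amplification-efficiency differences between primers, and the heavy
zero-inflation of real annotation-wide count matrices (the real cohort
discards roughly two-thirds of annotated genes as undetectable; the
simulated cohort with default settings discards roughly a quarter).
Passing tests on this cohort therefore demonstrate correctness of the
algorithms under the stated model, not robustness to those artefacts.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the screen at the full
cohort scale (57,278 genes × 29 samples, a few seconds), BCV recovery at
250 genes × 100 samples, and the geNorm/NormFinder panel studies at 20
seeded replicates of 8-gene panels — sizes chosen so every study runs
comfortably on a laptop while keeping Monte-Carlo error well inside the
asserted bands.  Every random draw flows from an explicit
`numpy.random.default_rng` seed; there is no hidden global state, and
identical seeds reproduce results bit-for-bit.

## Known limitations

* TMM factors for samples with very few shared nonzero genes fall back to
  1 (no trimmed genes left), with the symmetric rank-trimming documented
  above rather than edgeR's exact index arithmetic in corner cases.
* The BCV grid bounds (10⁻⁶–10) cap recoverable dispersions; estimates at
  the boundary are not refined.
* NormFinder's pair search scales quadratically in panel size (all pairs
  re-fit the model); fine for realistic panels (≤ 30 genes), slow beyond.
* `aggregate_ct` silently averages replicates; wells flagged by
  `aggregate_replicates` are reported but still included — exclusion is
  the analyst's decision.
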