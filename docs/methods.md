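# Methods

This note records the models, defaults and numerical choices behind
`episttp`, and what the simulation-based tests do and do not establish.

## Generative model of the factorial experiment

The simulator emulates a 4-genotype (WT, *Dusp1*KO, *Zfp36aa*, double
mutant) × 2-treatment (untreated, LPS) design with `n_replicates = 3`
independent samples per condition, on a linear-intensity platform.
Per gene *g*, the log2 mean of a condition is

```
m(g, genotype, treatment) = mu_g
                          + [LPS] * lambda_g
                          + [LPS] * genotype effect
```

with genotype effects under LPS: `delta_g` for *Dusp1*KO, `zeta_g` for
*Zfp36aa*, and `(1 - phi_g) * delta_g + zeta_g` for the double mutant.
`phi_g in [0, 1]` is the fraction of the DUSP1 effect mediated by TTP
phosphorylation; by construction the generative contrast
(DoubleMut − Zfp36aa) equals `(1 - phi) * delta`, the quantity DE2
estimates. Observed intensities are `2^(m + N(0, sigma))` — log-normal
replicate noise, the multiplicative error structure implied by
ratio-based analysis.

Defaults (all log2): baseline `mu ~ N(8, 1.5)`; 30% of genes LPS-induced
with `lambda ~ N(2.5, 1)`; half of the induced genes DUSP1-responsive with
`delta ~ N(1, 0.5)`; `phi` a mixture of a point mass at 0 (weight 0.3,
TTP-independent genes) and Beta(4.5, 5.5) (mean 0.45), so fully and
partially TTP-dependent genes both occur; `zeta = -0.5` applied only to
direct TTP targets (genes with `phi > 0`), reflecting their
underexpression when TTP cannot be inactivated; replicate noise
`sigma = 0.2`, a typical replicate SD for processed two-colour array
intensities. The untreated baseline is genotype-independent by default
(`lps_only_effects`), since the dysregulation of interest is
LPS-dependent. These defaults are fixtures chosen to be biologically
plausible, not estimates fitted to any real dataset.

What the simulator does **not** model: probe-level artifacts (spatial
trends, background), between-array normalization error, correlated genes,
heavy-tailed outliers beyond the dispersion-filter regime, and indirect
autocrine effects at late timepoints. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated error model,
not robustness to every property of real arrays.

## Probe filtering

Linear intensities are filtered before statistics:

* **Low intensity** — keep a probe only if, in at least one qualifying
  group (default: LPS-treated WT or LPS-treated *Dusp1*KO), at least 2 of
  3 replicates *strictly* exceed 100. "Exceed" is read as strict
  inequality, so a replicate at exactly 100 does not count. Missing
  values (`NA`) count as failures.
* **Dispersion** — drop a probe if in *any* replicate group the sample SD
  (n−1 denominator, the default of mainstream statistics software)
  exceeds the group mean. Applying the rule to every group is the
  conservative reading; groups of size 1 are skipped with a warning.

Filtering is per analyzed timepoint: callers subset the design before
filtering when several timepoints coexist.

## ANOVA, contrasts and FDR

Genotype and treatment are crossed fixed factors; the per-probe analysis
is the classical balanced two-way sums-of-squares decomposition,
vectorized across probes (an exact computation, oracle-tested against a
loop-based implementation). A mixed model is not fitted: no random factor
is identifiable in the data the pipeline consumes. Pairwise contrasts of
cell means are t-tested against the pooled residual variance (error df =
ab(n−1)); probes with zero residual variance are flagged untestable
rather than given p = 0. Fold changes are ratios of group geometric
means. BH step-up q-values come from
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; the
brute-force step-up definition is kept in the test suite as an
independent oracle. Induction summaries gate on q < 0.05 and count
transcripts above fold thresholds (1, 3, 5, 10), with integer-rounded
percentages.

## Epistasis statistics

DE1 and DE2 are differences of log2 replicate means over LPS-treated
samples (equivalently, log2 geometric-mean ratios, and equal to the mean
of all pairwise replicate log-ratios). Two error models test DE1 ≠ DE2:

* **pairwise** (default): Welch t-test between the 3×3 pairwise log-ratio
  samples of each background. The nine ratios are built from six values
  and are therefore dependent; measured on null simulations, ~17% of
  probes reach p < 0.01. The model is retained because it mirrors the
  conventional pairwise-comparison recipe, but its tiers should be read
  as a ranking, not calibrated error rates.
* **groupwise**: t-test of the difference of mean ratios with
  replicate-propagated variance and Satterthwaite df. Measured type I
  error at p < 0.01 is ~0.5%; all calibration tests use this model.

**Regression.** The default slope is the through-origin estimator
`sum(xy)/sum(x^2)` with a t CI on n−1 df (free-intercept OLS available;
the null line passes through the origin, which motivates the default).
Because x = log2 DE1 carries measurement error of variance
V = (s²_KO + s²_WT)/n, the raw slope is attenuated by roughly
`sum(delta^2) / (sum(delta^2) + nV)` — about 2% under default conditions,
which is negligible against a ±0.05 recovery tolerance but fatal for CI
coverage of the null slope 1. `fit_epistasis_regression` therefore
accepts `x_error_var` and applies the method-of-moments correction
`slope = sum(xy)/(sum(x^2) − nV)`, with `de_noise_variance()` estimating
V from replicate variances. Null-calibration tests use the corrected
estimator; the uncorrected one remains the default because it is the
plain textbook procedure and the attenuation is documented. A seeded
percentile bootstrap CI (2000 resamples over transcripts) is available as
a robustness check. Tiers: ns (p ≥ 0.01), significant (0.0001 ≤ p <
0.01), highly significant (p < 0.0001).

Under heterogeneous `phi`, the through-origin slope converges to the
`delta²`-weighted mean of `(1 − phi)` — strongly affected genes weigh
more — and recovery tests compare against that realized target.

## Clustering

Row profiles (per-genotype/treatment mean log2 expression relative to
LPS-treated WT) are standardized and clustered agglomeratively with
average linkage on 1 − Pearson correlation, the conventional choice for
expression heat maps; the tree is cut to exactly k clusters
(`scipy.cluster.hierarchy`). Heat-map clustering tools differ in metric and linkage defaults, so exact
membership reproduction across tools is not a goal; planted-archetype recovery (ARI ≥
0.9 at noise σ = 0.2) is the tested property. Constant rows, whose
correlation is undefined, are assigned to the nearest centroid in
Euclidean distance with a warning. Box-and-whisker summaries use
linear-interpolation quantiles and 1.5×IQR whiskers.

## Decay and ΔΔCt

Chase series (percent of t = 0 after reference-gene and zero-timepoint
normalization) are fitted by OLS of ln(value) on time — unweighted in log
space, i.e. equal relative error — giving k = −slope, SE(k) from the
regression, t½ = ln 2 / k and the R² of the log fit. A plateau model
`y = p + (100 − p) e^(−kt)`, `p ∈ [0, 100)`, is available behind a flag
(`scipy.optimize.curve_fit`); it is unstable on 4–5-point chases and is
not the default. Fitted k ≤ 0 is reported as "no measurable decay" with
infinite half-life, not an error. Genotype comparisons are z-tests on the
rate constants (the directly fitted, approximately Gaussian parameters),
not on half-lives. Estimation accuracy is information-limited by the
chase window: with sampling confined to 0–90 min and σ = 0.05 noise, a
4-hour half-life has SE(k)/k ≈ 17%, so median relative errors around 11%
are the attainable floor there; shorter half-lives recover well under
10%. ΔΔCt follows the standard 2^−ΔΔCt form with a reference gene and
calibrator sample.

## Motif scanning

Exact overlapping occurrences of the TTP consensus heptamer `UAUUUAU`
(optionally the stricter nonamer `UUAUUUAUU`), single-stranded (mRNA
sense), T/U-equivalent and case-insensitive; `N` never matches.
Overlaps are counted because functional AREs cluster and the nonamer is
built from overlapping heptamers. The UTR simulator plants exact
non-overlapping copies and rejects sequences with accidental extras, so
planted counts are ground truth.

## Problem sizes and determinism

Simulation-based checks use 600 genes × 24 samples × 20 seeded runs for
the epistasis/null analyses, 2000 genes for induction bookkeeping, 200
profiles for clustering, and 1000 random instances for the exact oracle
comparisons — sizes at which the measured quantities are stable to well
within their tolerances while the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeds;
`scripts/acceptance.py` derives independent sub-seeds from `--seed` via
`SeedSequence`. Identical seeds give bit-identical outputs.

## Known limitations

* The pairwise error model is anticonservative by construction (see
  above); interpret its tiers comparatively.
* The attenuation correction assumes homogeneous replicate noise across
  genes (it uses the average replicate variance).
* The ANOVA is fixed-effects and balanced-design only; unbalanced inputs
  are rejected rather than approximated.
* The simulator's independence across genes understates the correlation
  structure of real transcriptomes, so FDR behaviour on real data may
  differ from the simulated calibration.
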