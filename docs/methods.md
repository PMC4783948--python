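# Methods

This note documents the statistical model, the estimation pipeline, the
synthetic-data generator, and the numerical and design choices behind
`dppin`, in the spirit of a package methods appendix.

## Model and estimands

Each target protein *i* in a candidate PPI network is modelled as a linear
combination of its interactors, with no intercept:

    x_i(n) = Σ_{j ∈ N(i)} α_ij x_j(n) + ω_i(n)                    (per sample n)

α_ij (dimensionless "association ability") is estimated by ordinary least
squares within one condition. Row regressions are independent, so the
assembled matrix A is generally asymmetric (α̂_ij ≠ α̂_ji). The
differential network for time point *k* is D^k = A_case(k) − A_control on
the union node index (an edge retained in only one condition contributes
its full coefficient), and the per-protein relevance statistic is
TRV_i = Σ_j |d_ij|.

**What least squares actually estimates.** When the same model generates
the data as a simultaneous system (x = Ax + w solved at its fixed point),
the regressors are endogenous: x_j depends on ω_i through feedback whenever
α_ji ≠ 0. Row-wise OLS then converges to the *linear projection*
coefficients, not the structural α. For an isolated reciprocal pair the
projection of x_1 on x_2 is (α_12 + α_21)/(1 + α_21²): reciprocal
coefficients of opposite sign cancel almost completely, making the edge
invisible to any row-wise method, while same-signed pairs give a strong
(though biased) projection. Two consequences run through the package:

* the generator draws one interaction sign per undirected edge (shared by
  both directions), so edges remain estimable;
* unbiased coefficient recovery is only claimed — and only tested — in the
  feedback-free regime (exogenous interactors, or the acyclic simulation
  mode below). Support recovery and differential ranking, the quantities
  the pipeline reports, are robust to the projection bias because the bias
  is identical in both conditions for unperturbed edges and cancels in D.

## Estimation pipeline

Per target protein, within one condition:

1. **Ranking.** Candidates (the protein's PPI neighbors inside the
   candidate network) are ordered by descending |Pearson r| with the
   target; zero-variance candidates get r = 0; ties break lexicographically.
2. **Order selection.** Gated forward selection over that ranking. A
   candidate is accepted when (a) its incremental coefficient passes a
   two-sided Student's *t*-test at level `screen_alpha / M_i` (Bonferroni
   over the candidate pool) and (b) it lowers the Gaussian AIC,
   n·ln(RSS/n) + 2k. Failing candidates are skipped, not stopping points.
   Two deliberate choices here:
   * *Why a significance gate at all?* The ranking picks the best of M_i
     correlations; plain AIC-argmin over that prefix admits a spurious
     first interactor in roughly 60% of pure-noise replicates (measured at
     n = 30, M_i = 5) because the 2k penalty is calibrated for a fixed,
     not a selected, regressor. The Bonferroni gate restores familywise
     inclusion error ≈ `screen_alpha` under the null.
   * *Why skip instead of stop?* With a hard stop, a weak early-ranked
     candidate blocks every later one; in recovery experiments this
     accounted for almost half of all missed true edges.
   The accepted count is capped at min(M_i, n − 2, `order_cap`), keeping
   residual degrees of freedom positive.
3. **Pruning.** At the chosen order, classical OLS *t*-tests
   (σ̂² = RSS/(n − k), cov = σ̂²(XᵀX)⁻¹, pseudo-inverse when singular)
   remove coefficients with p > `alpha` (default 0.05); the model is refit
   once on the survivors. With zero residual degrees of freedom pruning is
   skipped with a warning and flagged in diagnostics.

Least squares uses the SVD-based minimum-norm solution, so rank-deficient
designs are handled without failure. An exact-fit guard (ε = 1e−12) keeps
the AIC finite. AIC ties go to the smaller order; with the skip rule the
recorded trace is strictly decreasing, so the chosen order is its argmin.

The control network is fitted once from all control samples pooled across
time points (per-time-point control fitting is available by flag): two
control arrays per time point cannot support a regression, and the design
treats the uninjured state as a single network.

**Intercept.** The model has none by construction. An optional flag
mean-centers target and regressors before fitting, which yields the
with-intercept slopes; the intercept's degree of freedom is not charged to
the *t*-test df (a documented one-df approximation).

## Significance screening

TRV p-values come from a condition-label permutation test: pool the case
samples at the time point with the (pooled) control samples, reassign
labels b times respecting group sizes, refit both networks, recompute TRV,
and report p = (1 + #{TRV* ≥ TRV}) / (1 + b). This respects exchangeability
under the null, requires no distributional assumptions, and is never zero.
When fewer than b distinct assignments exist, permutations are sampled with
replacement and a warning is issued. Raw p-values are reported (a
Benjamini–Hochberg column can be added downstream); the default screen is
p < 0.05 intersected with fold change > 1.5 (`require_fc` turns the FC
filter off). Screening is monotone in both thresholds.

Edge classification for visualization computes the mean and *population*
(ddof = 0) standard deviation over the nonzero entries of D; entries
≥ mean + STD are red, ≤ mean − STD blue, others neutral; zero spread or
fewer than two nonzero entries labels everything neutral (deterministic
boundary behavior).

## Quantile normalization

All sample columns are forced to the vector of across-column rank means
(pooled across all samples by default; per-time-point by flag). Ties within
a column receive the mean of the target values their ranks span. The exact
"identical multiset" property and idempotence hold for tie-free columns;
with ties the tie rule takes precedence (column sums are still equalized).
The implementation is cross-checked against limma's `normalizeQuantiles`
in the test suite.

## Synthetic data generator

The generator exists so that every pipeline stage can be scored against
known structure. It emulates a small two-condition time-course microarray
study: a gene universe of 20–100+ proteins, 3 case + 2 control arrays per
time point in the study-like bundle (larger by option), a PPI list mixing
the true support with false-positive edges, and expression drawn from the
model itself.

* **Support and coefficients.** Undirected support sampled at
  `edge_density` (default 0.1 for the 20-node test scenario; 0.04 for the
  100-node bundle, mean degree ≈ 2–4, typical of curated PPI neighborhoods).
  Coefficient magnitudes uniform in `coupling_range` = (0.4, 0.6), sign
  shared per edge, magnitudes independent per direction.
* **Perturbation.** A recorded fraction (default 30%) of edges differs
  between conditions: both directed entries change by exactly
  `delta_alpha` = 1 against their sign (α → α − sign(α)·Δ). Because
  couplings are about Δ/2, this flips the association's sign rather than
  inflating it, so the case matrix's spectral radius — and hence the
  common stability rescale applied to all matrices (radius ≤ 0.8) — stays
  essentially unchanged and perturbed edges remain as detectable as
  unperturbed ones. (An additive ±Δ perturbation was rejected: it inflates
  the case radius, and the common rescale then crushes *all* couplings
  below detectability at n = 40.)
* **Sampling.** Fixed-point mode solves x(n) = (I − A)⁻¹ w(n) with
  w ~ N(baseline, noise_sd²) i.i.d. per protein, the unique
  self-consistent reading of the simultaneous model under spectral radius
  < 1; each sample satisfies x = Ax + w to machine precision. Acyclic mode
  (`mode="acyclic"`) generates nodes in index order from the strictly
  lower triangle of A — a feedback-free sensitivity variant in which OLS
  on the generating parents is consistent; it backs the coefficient-RMSE
  test.
* **Intensity scale.** The study-like bundle uses baseline = 3.0 (30× the
  noise sd) so intensities are naturally positive, as microarray data sit
  far above their noise floor; coefficient perturbations then shift group
  means through (I − A)⁻¹ and fold-change screening has real signal. Any
  residual negative tail is shifted to min ≥ 1 and the shift recorded
  (an earlier 10× baseline left shifts comparable to the means, which
  compressed all fold changes toward 1). The 20-node recovery scenario
  uses baseline 0 — recovery is scale-free and needs no intensity
  dressing.
* **Determinism.** One integer seed fixes the entire bundle byte-for-byte.

**What the generator does not emulate:** probe-level effects, background
correction, batch effects, heavy-tailed intensity noise, hub-dominated
degree distributions, or PPI evidence codes. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not performance on real microarray data — where
endogeneity, tiny replicate numbers and annotation noise will dominate.

## Problem sizes used in the test suite

Calibration tests use 200–500 replicates at n = 30; the recovery benchmark
averages 20 seeded trials of a 20-node, 40+40-sample scenario; the
permutation-uniformity check uses b = 100 on a 10+10-sample null scenario;
the end-to-end run uses the 100-protein, four-time-point bundle with
b = 200 permutations. These sizes give stable Monte-Carlo estimates while
keeping the whole suite around half a minute.

## Known limitations

* Per-row OLS on simultaneous data estimates projections, not structural
  coefficients (see above); TRV remains valid as a *differential* measure.
* With 3 case arrays per time point (the study-like design) the order cap
  n − 2 = 1 allows at most one interactor per protein; the per-time-point
  case networks are then extremely sparse and TRV is dominated by the
  control network. Results on such designs are qualitative.
* The permutation p-value granularity is 1/(b + 1); with the study-like
  design only C(11, 3) = 165 distinct label assignments exist, bounding
  how small a p-value can meaningfully be.
* Fold-change screening requires positive means; use ANOVA screening for
  data that can be negative (e.g. log-ratio arrays).
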