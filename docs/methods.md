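# Methods

## Model

`mixrhlp` fits the mixture of regressions with hidden logistic processes
(mixRHLP) to multi-subject univariate time series observed on a shared time
grid t_1 < … < t_{N_t} (typically rescaled to [0, 1]). Two kinds of latent
structure are modeled jointly:

* **Clusters** (between-subject): subject i carries a latent class
  Z_i ∈ {1..K} with mixing proportions α_k = P(Z_i = k).
* **Regimes** (within-subject): given Z_i = k, the latent regime at time t_j,
  H_ij ∈ {1..R}, follows a multinomial logistic model in time,

      π_kr(t_j) = P(H_ij = r | t_j, Z_i = k)
                = exp(ω_kr0 + ω_kr1 t_j) / Σ_s exp(ω_ks0 + ω_ks1 t_j),

  with the last regime as the reference class (ω_kR· ≡ 0). Regimes can switch
  back and forth — the logistic curves describe smoothly drifting occupancy
  probabilities, not one-directional stages — though the log-odds relative to
  the reference are monotone in time, a known restriction of the model.

Given cluster and regime, the observation is Gaussian around a polynomial
trend of order d:

      y_i(t_j) | H_ij = r, Z_i = k  ~  N(X_j β_kr, σ²_kr),
      X_j = (1, t_j, …, t_j^d).

Time points are conditionally independent given the cluster, so the
observed-data log-likelihood is

      l(Θ) = Σ_i log Σ_k α_k Π_j Σ_r π_kr(t_j) N(y_i(t_j); X_j β_kr, σ²_kr).

All probability arithmetic is carried out in log space with log-sum-exp; the
per-subject products underflow in linear space from roughly N_t ≥ 160
onwards. The design matrix is the raw (non-orthogonalized) Vandermonde basis
so that reported coefficients are plain polynomial coefficients.

A single α_k is shared by all subjects in cluster k: there are no subject
covariates in the model, so subject-specific proportions would be
unidentifiable.

## Estimation

Parameters are estimated by EM:

* **E-step.** Cluster responsibilities τ_ik ∝ α_k p_k(y_i) and, within each
  cluster, per-cell regime responsibilities
  γ_ijkr ∝ π_kr(t_j) N(y_i(t_j); X_j β_kr, σ²_kr).
* **M-step.** α_k is the mean of τ_ik; β_kr solves a weighted least-squares
  problem with cell weights τ_ik γ_ijkr; σ²_kr is the correspondingly
  weighted mean squared residual (pooled over all (k, r) under the
  homoskedastic option), floored at `variance_floor` (default 1e-6, guarding
  the classical degenerate-variance spike of Gaussian mixtures); ω_k
  maximizes the weighted multinomial logistic log-likelihood with fractional
  targets by Newton–Raphson (IRLS), warm-started at the current ω_k with
  step-halving (up to 30 halvings), so the inner objective never decreases
  and EM retains its monotone-ascent guarantee. A gradient step is the
  fallback when the Hessian solve fails.

Convergence is declared when the relative log-likelihood change
|Δl|/(|l|+1) falls below `tol` (default 1e-8, at most `max_iter` = 1000
iterations). The surface is multimodal, so `fit` runs `n_starts` (default
10) independent EM chains and keeps the best final log-likelihood.
Initialization assigns subjects uniformly at random to clusters (repairing
empty clusters), fits per-cluster OLS polynomials on R contiguous time
blocks to seed β and σ², and starts ω at zero (uniform regime
probabilities); a variant orders subjects by series mean before
partitioning. Everything is deterministic given the seed. A fit can also be
started from user-supplied parameters (one chain), which the recovery tests
use to check the estimator near the truth, separate from questions of basin
finding.

Degenerate corners behave sensibly: K = R = 1 collapses to ordinary
polynomial regression (the tests verify exact agreement with closed-form
OLS), and a cluster whose responsibility mass vanishes simply keeps its last
parameters with α_k ≈ 0.

## Model selection

For a fit with q = |Θ| free parameters — q = (K−1) + 2K(R−1) + KR(d+1) + KR
(heteroskedastic) or + 1 (homoskedastic) — and n = N_t × N_p cells:

      BIC   = log(n) q − 2 l_M        saBIC = log((n+2)/24) q − 2 l_M
      AIC   = 2 q − 2 l_M             AICc  = AIC + (2q² + 2q)/(n − q − 1)

The smallest value wins. n = N_t × N_p is used deliberately even though
cells within a subject are dependent: it is the convention the criteria
above are defined with for this model class. AICc is reported as NaN when
n ≤ q + 1. `grid_search` fits every (K, R, d) combination — the default grid
K, R ∈ {1..4}, d ∈ {1, 2} gives 32 candidates — records failures without
aborting, and ranks survivors per criterion with ties broken by parsimony
(lexicographic (K, R, d)). `SelectionReport.best` optionally applies a
parsimony window: among the top-w fits by a criterion, prefer the smallest
|Θ| (w = 1 by default). |Θ| was chosen as the parsimony ordering because no
natural total order exists on (K, R, d) triples.

## Classification and label matching

MAP labels: cluster_i = argmax_k τ_ik, and regime_ij = argmax_r of the
regime posterior under the subject's MAP cluster (ties to the smallest
index). Because the likelihood is invariant to label permutations, accuracy
against simulation truth is computed after optimal matching: a Hungarian
assignment on the K×K cluster confusion matrix, then, within matched
clusters, a Hungarian assignment on each R×R regime confusion matrix.
Regimes are matched within clusters because regime r of one cluster has no
intrinsic correspondence to regime r of another. Optimal assignment (rather
than greedy matching) makes the resulting measure invariant to any
simultaneous relabeling — a property the tests verify.

Regime accuracy pools all (subject, time) cells that were observed *before*
imputation; imputed cells are excluded. Whether to pool cells or average
per-subject first is a genuine convention choice; the pooled value is the
primary measure and the per-subject mean is reported alongside it.

When scoring parameter recovery, the fitted parameters are carried through
the same matched permutations; after reordering regimes, the logistic row
landing on the reference slot is subtracted from all rows of its cluster
(ω is identified only up to subtraction of the reference row).

## Simulator and study design

`simulate` draws from the generative process on an inclusive equally spaced
grid over [0, 1]: Z_i ~ Cat(α), H_ij ~ Cat(π_{Z_i ·}(t_j)) independently
across j, then the Gaussian emission. `benchmark_parameters(sigma)` provides
the two-cluster, three-regime, linear (K=2, R=3, d=1) truth used throughout
the studies: α = (0.5, 0.5); cluster 1 has ω rows (−2, 3), (1, −2.5), (0, 0)
and β rows (0, −1.5), (0.6, −0.9), (1.2, −0.3); cluster 2 has ω rows
(−1, 2), (0.5, −2), (0, 0) and β rows (0.6, 0.3), (1.2, 0.9), (1.8, 1.5);
σ is common to all regimes and clusters (levels 0.10, 0.15, 0.20). The two
clusters mix three downward and three upward lines whose regime occupancy
drifts over the session; the trajectories are hard to separate by eye at
these noise levels, which is what makes the recovery study informative.

Missingness is MCAR: each cell is masked independently with probability
`p_miss` (levels 0, 0.1, 0.2). By default each subject's first and last
grid points are protected so that linear interpolation is defined without
extrapolation; with protection disabled, edge gaps are filled with the
nearest observed value. `impute_linear` then fills interior gaps by linear
interpolation in time. The full factorial design crosses
N_p ∈ {20, 60, 100}, N_t ∈ {20, 160, 300}, σ ∈ {0.10, 0.15, 0.20} and
p_miss ∈ {0, 0.1, 0.2}.

The Monte Carlo harness (`montecarlo.run_condition`) runs
simulate → mask → impute → fit per replicate, fitting either the generating
specification alone or the full 32-model heteroskedastic grid, and records
criterion values and the true model's rank, label-matched estimates, and
accuracies on pre-imputation observed cells. Parameter error is summarized
per group G ∈ {α_1, β_0, β_1, σ, ω_0, ω_1} as

      rmse_G = (1/|G|) Σ_g sqrt( (1/M) Σ_r (θ̂_{r,g} − θ_g)² ),

with variances compared on the σ (standard deviation) scale and the ω groups
restricted to non-reference rows. Ranks are computed among successfully
fitted models; run-level summaries are untrimmed (no outlier removal), with
medians reported alongside means as the robust alternative.

### Problem sizes used by the bundled studies

The acceptance studies are scaled-down replications chosen to be
informative at workstation scale: M = 20 replicates for the accuracy and
RMSE measures (favorable condition N_p=20, N_t=160, σ=0.1, p_miss=0;
large-sample condition N_p=100, N_t=300), and M = 5 replicates for the full
32-model grid study. Study fits use 4 random starts, `max_iter` 300 and
`tol` 1e-7 — at these sample sizes the EM chains agree to ~1e-8 in final
log-likelihood across starts, so further effort changes nothing.

### A note on the α₁ group at small N_p

With N_p subjects and well-separated clusters, the EM estimate of α₁ is in
effect the empirical cluster-1 fraction, whose sampling standard deviation
around the true 0.5 is sqrt(0.25/N_p) — about 0.112 at N_p = 20. The
α₁-group RMSE at the 20-subject condition therefore hovers near 0.112 no
matter how good the estimator is; it drops below 0.05 at N_p = 100. This is
a property of the study design (an irreducible sampling floor), not of the
fitting algorithm.

## Preprocessing

For irregular two-channel event streams (e.g. left/right hand heights on a
touch screen): `rescale_time` maps each subject's session affinely onto
[0, 1]; `ratio_channel` forms right/left per event, dropping (and counting)
events with non-positive left values; `aggregate_bins` averages events in
`n_bins` equal intervals of [0, 1), assigning bin b to grid point b/n_bins
and events at exactly t = 1 to the final point — 200 bins thus yield 201
shared occasions — with empty bins becoming missing cells;
`winsorize_upper` caps values above the 95th percentile (ratios explode
when the denominator hand approaches zero). The winsorization quantile uses
linear interpolation between order statistics — winsorized values depend on
this convention, so it is fixed and stated. The quantile scope is pooled
across the sample by default, with a per-subject option; both are defensible
readings of "the 95th percentile of the ratios" and the choice is logged by
the CLI. After `impute_linear`, the panel is complete and ready for fitting.

`simulate.synthetic_tablet_events` generates entirely synthetic event
streams shaped like such recordings (irregular times, a silent gap, two
behavioral groups settling from ratio ≈ 1 through noisy exploration to
ratio ≈ 2) for end-to-end pipeline tests.

## What the simulations do and do not show

The simulator draws from the exact model being fitted, on an equally spaced
grid, with exactly Gaussian noise and truly MCAR missingness. Passing
recovery tests therefore demonstrates the correctness of the estimator and
the measures under the model's own assumptions. They say nothing about
misspecification: real behavioral streams are irregularly sampled (the
aggregation step itself induces structured missingness), noise is
non-Gaussian with occasional spikes (hence the winsorization step), regime
switches may depend on the current regime (a Markov structure this model
ignores), and log-odds need not be monotone in time. The synthetic tablet
emulator exercises the preprocessing path but is likewise a stylized stand-in
for real recordings.

## Known limitations

* Univariate emissions only; no subject covariates in α or ω; no
  autoregressive or Markov regime dependence.
* The logistic process forces monotone log-odds relative to the reference
  regime.
* A shared time grid is required; irregular data must be aggregated first,
  trading temporal resolution for completeness.
* No standard errors or observed information; point estimates and
  information criteria only.
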