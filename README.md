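# mixrhlp

Model-based clustering and regime segmentation of multi-subject time series
via **mixtures of regressions with hidden logistic processes (mixRHLP)**.

Many behavioral, physiological and learning processes vary *qualitatively*
both between subjects (latent groups with distinct dynamics) and within a
subject over time (regimes or phases that switch back and forth). `mixrhlp`
captures both at once: subjects belong to one of K latent clusters, and
within cluster k the series follows one of R regimes at each time point,

    P(H_ij = r | t_j, Z_i = k) = exp(ω_kr0 + ω_kr1 t_j) / Σ_s exp(ω_ks0 + ω_ks1 t_j),
    y_i(t_j) | H_ij = r, Z_i = k ~ N(X_j β_kr, σ²_kr),   X_j = (1, t_j, …, t_j^d),

so each regime is a polynomial trend with Gaussian noise and regime
occupancy drifts smoothly over the session. Estimation is by multi-start EM
with an IRLS inner loop for the logistic coefficients; model selection over
(K, R, d) uses BIC, sample-adjusted BIC, AIC and AICc. The package also
ships a faithful simulator of the generative process (for Monte Carlo
recovery studies) and a preprocessing pipeline that turns irregular event
streams into the complete shared-grid panel the model needs.

Intended users: quantitative researchers in the behavioral and social
sciences (and anyone with multi-subject sensor streams) who want clusters of
regime-switching trajectories rather than clusters of static features.

## Worked example

Simulate 20 subjects at 160 time points from the built-in two-cluster,
three-regime benchmark model (σ = 0.1), fit the generating specification,
and classify:

```bash
$ mixrhlp simulate --np 20 --nt 160 --sigma 0.1 --seed 7 --out data.csv
wrote 20x160 panel to data.csv

$ mixrhlp fit --data data.csv --k 2 --r 3 --d 1 --starts 4 --seed 0 --out fit.json
start 0: loglik = -295.5198
start 1: loglik = -295.5198
start 2: loglik = -295.5198
start 3: loglik = -295.5198
best loglik = -295.5198 (20 iterations, converged=True)
wrote fit to fit.json

$ mixrhlp classify --data data.csv --fit fit.json --out labels.csv
wrote labels to labels.csv
```

All four EM starts land on the same optimum (log-likelihood −295.52,
converged in 20 iterations). The stored fit contains the estimated mixing
proportions α ≈ (0.60, 0.40) — the empirical cluster split of this draw —
and the information criteria (BIC 809.0, saBIC 723.2, AIC 645.0,
AICc 645.5). `labels.csv` holds the MAP cluster and regime per (subject,
time) cell with their posterior probabilities:

```
 subject     time  cluster  regime  cluster_prob  regime_prob
       1 0.000000        1       2           1.0     0.999986
       1 0.006289        1       2           1.0     0.999999
       1 0.012579        1       2           1.0     1.000000
```

Subject 1 is assigned to cluster 1 with posterior ≈ 1 and starts the session
in regime 2, matching how the benchmark model's occupancy curves behave near
t = 0. The same workflow is available from Python (`simulate`, `fit`,
`classify`, `grid_search` in `mixrhlp`), and `mixrhlp select` fits the full
32-model grid (K, R ∈ 1..4, d ∈ 1..2) and writes a ranked criterion table.

For irregular raw event streams, `mixrhlp preprocess` rescales each
subject's session to [0, 1], takes right/left channel ratios, averages them
in 200 equal intervals (yielding 201 shared occasions, empty bins becoming
missing cells), winsorizes above the 95th percentile and imputes linearly —
producing a complete panel ready for `fit`.

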