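# Methods

This document records the statistical model, estimation choices, defaults and
known limitations of `clpn`. Notation: *n* persons, *T* waves, *p* nodes.

## Model

For person *i*, the stacked observation vector over waves is multivariate
normal. The generative decomposition is

```
y_it = μ + η_i + u_it,            η_i ~ N(0, Σ_B),   Σ_B = K_B^{-1}
u_it = B u_{i,t-1} + ζ_it,        ζ_it ~ N(0, Σ_ζ),  Σ_ζ = K_ζ^{-1}
```

with the within-person process started from its stationary distribution
`Σ_0`, the solution of the discrete Lyapunov equation `Σ_0 = B Σ_0 Bᵀ + Σ_ζ`.
The implied covariance of the stacked `T·p` vector has blocks

```
Cov(y_s, y_t) = Σ_B + B^{s-t} Σ_0     (s ≥ t).
```

Stationarity (`spectral radius of B < 1`) is required and validated.

### Networks

- **Temporal**: `W[k, j] = B[k, j] · sqrt(Σ0[j, j] / Σ0[k, k])` — the
  standardized lag-1 regression of node *k* on node *j*. Directed, includes
  autoregressive diagonal; `p²` possible edges.
- **Contemporaneous**: partial correlations
  `-K_ζ[j, k] / sqrt(K_ζ[j, j] · K_ζ[k, k])`. Undirected, `p(p-1)/2` edges.
- **Between-person**: same transform applied to `K_B`.

## Estimation

### Likelihood and missing data

The log-likelihood is full-information ML (FIML): each person contributes the
density of their *observed* sub-vector of the stacked normal, so any
missing-at-random pattern (item- or wave-level) is handled without imputation.
Persons are grouped by missingness pattern so each distinct pattern's
Cholesky factorization is computed once.

### Two-stage default, direct option

`PanelGVAR.fit(method="auto")` uses a **two-stage** procedure:

1. **Saturated stage** — estimate the unstructured stacked mean and covariance
   by EM under missingness (closed form when data are complete). If the
   saturated covariance is rank-deficient a warning is raised; if it is not
   invertible the fit fails with an explicit error.
2. **Structured stage** — maximize the structured model's discrepancy against
   the saturated moments.

`method="direct"` instead maximizes the raw FIML log-likelihood; it agrees
with the two-stage estimates on complete data and is available as a check.

Starting values come from a closed-form **moment estimator**: with lag-0 and
lag-1 moment averages `A0, A1, A2` across waves,

```
B   = (A1 − A2)(A0 − A1)^{-1}
Σ_0 = (I − B)^{-1}(A0 − A1)
Σ_B = A0 − Σ_0
```

This estimator is consistent here because person means are modeled, not
subtracted — subtracting observed person means in short panels induces
Nickell-style bias, which this construction avoids. It is also the fast
refit engine inside the bootstrap.

Covariance matrices are parameterized through their Cholesky factors, so all
iterates are positive definite. Standard errors come from the numeric Hessian
of the log-likelihood at the optimum (computed automatically when the number
of free parameters is at most 150, on request otherwise).

### Fit indices

From the structured, saturated and independence log-likelihoods the usual
SEM-style indices are reported: `χ² = 2(ll_sat − ll_M)` with degrees of
freedom equal to the number of constrained moments, CFI, TLI, and RMSEA with
a 90% confidence interval obtained by root-finding on the noncentral-χ²
distribution. CFI/TLI are clamped to [0, 1] with a warning when outside.

## Structure selection

Edges are selected by EBIC (γ = 0.5) **independently per network**, each over
its own penalty path:

- **Contemporaneous and between networks**: graphical-lasso paths on the
  residual and between-person covariance estimates; EBIC
  `-2·ll + E·log(n_eff) + 4γE·log p` with *E* the number of selected edges.
- **Temporal network**: candidate masks from soft-thresholding the
  standardized `B`; each masked model is re-solved in closed form (restricted
  regressions on the stationary moments) and scored by the observed-data ML
  discrepancy `n·F_ML` against the saturated stacked covariance plus
  `npar·log n + 4γ·npar·log p`.

Each penalty path starts just above the largest off-diagonal magnitude of its
network, so the empty model is always a candidate and a truly empty network
can be selected. Per-network selection matters: the three networks carry
different information per edge, and a single shared penalty systematically
over- or under-selects one of them.

## Bootstrap, stability and triage

The case bootstrap resamples persons with replacement (implemented as dense
integer weights, so pattern-grouped computations are reused). For each
replicate the model is refit (moment estimator by default; full ML optional)
and, if selection is enabled, the structure is re-selected.

- **Confidence intervals**: percentile 95% intervals from the dense-weight
  replicate distribution of each standardized edge.
- **Inclusion frequency**: fraction of replicates in which selection keeps
  the edge.
- **Triage rule**: an edge is *significant* when Wald `p < 0.001` (bootstrap-z
  fallback when Wald SEs are unavailable), inclusion ≥ 0.5, and |d| ≥ 0.100.

Reports: `stability_report` (count, total, percent of edges with inclusion
≥ 0.5 per network) and `ci_accuracy_report` (percent of CIs excluding zero),
both rounded to one decimal.

## Effect sizes and group comparison

Edge weights *r* convert to Cohen's *d* via `d = 2r / sqrt(1 − r²)` (inverse
`r = d / sqrt(d² + 4)`), with `var(d)` by the delta method. Groups of edge
effects are compared by **robust variance estimation**: weighted least
squares of *d* on design indicators with cluster weights `1/(k_j·v̄_j)`,
CR2 (Bell–McCaffrey) small-sample adjustment of the sandwich covariance, and
Satterthwaite degrees of freedom.

## Synthetic cohorts

`clpn.cohort` generates data from known parameters for validation and power
analysis: a 14-node SWAN-like scenario (depression and anxiety symptoms plus
inflammatory markers, with a planted strong biomarker→somatic pathway),
random sparse scenarios with controllable density, and a null scenario with
no cross edges. Simulation draws `η_i`, a stationary initial deviation, then
innovations wave by wave, and applies MCAR masking at the configured rate —
deterministic given the scenario seed.

## Defaults

| Setting | Default |
| --- | --- |
| estimation | two-stage FIML (`method="auto"`) |
| SEs | numeric Hessian, auto when ≤ 150 free parameters |
| EBIC γ | 0.5 |
| penalty path | 100 models (30 inside bootstrap), geometric, empty model included |
| bootstrap | 1000 reps recommended; percentile 95% CIs |
| triage | p < 0.001, inclusion ≥ 0.5, |d| ≥ 0.100 |
| bootstrap failure tolerance | ≤ 10% failed replicates, else error |

## Limitations

- Lag-1 dynamics only; higher-order lags are not modeled.
- Missingness is assumed (conditionally) ignorable; FIML is biased under MNAR.
- The moment estimator used inside the bootstrap is consistent but less
  efficient than full ML; CIs at very small *n* are accordingly conservative.
- Structure selection scores candidate masks without full re-optimization of
  the remaining parameters at every penalty value; closed-form restricted
  solutions are used instead, which is exact for the temporal block given the
  saturated moments but approximate for jointly reselected precisions.
- Gaussian likelihood throughout: heavily skewed biomarkers should be
  transformed (e.g. log CRP) before analysis, and ordinal scales with few
  categories are treated as continuous after linear rescaling.
- Between-person partial correlations are cross-sectional in nature;
  "vulnerability" vs "scar" style interpretations require design, not just
  estimation.
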