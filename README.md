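# medgp

Sparse multi-output Gaussian processes for online prediction of
irregularly sampled clinical time series.

Inpatient records mix frequently observed vital signs (every 3–4 hours)
with labs drawn roughly once a day, at times that line up neither across
covariates nor across patients. `medgp` models a patient's D covariates
jointly as a zero-mean multi-output Gaussian process, so that an
incoming observation of any covariate can be predicted — with calibrated
uncertainty — from everything measured at or before that moment,
including other covariates.

## The model

The joint kernel is a linear model of coregionalization (LMC) over Q
spectral-mixture (SM) basis kernels. For observations of covariates
d, d′ at times t, t′ with ρ = |t − t′|:

```
k((d,t), (d′,t′)) = Σ_q  B_q[d,d′] · κ_q(ρ),
κ_q(ρ)            = exp(−2π²ρ²v_q) · cos(2πρμ_q),
B_q               = A_q A_qᵀ + diag(λ_q),   A_q ∈ R^{D×R}, λ_q ≥ 0.
```

Each basis kernel has characteristic period 1/μ_q and length scale
1/(2π√v_q); κ_q(0) = 1, so B_q carries all amplitude and
cross-covariate information, and the low-rank-plus-diagonal form keeps
it positive semi-definite. Observations get covariate-specific Gaussian
noise σ_d². With Q=5, D=24, R=8 this is 1114 hyperparameters per
patient (including the 24 noise variances).

A horseshoe-type prior sparsifies the A_q entries through a four-level
gamma chain (shapes α=β=γ=ξ=0.5, each sampled value acting as the rate
of the level below, global rate η), and an exponential prior with scale
β_λ=0.01 shrinks the diagonal weights. Fitting alternates closed-form
MAP updates of the latent scales with conjugate-gradient ascent over
the kernel parameters until the objective changes by less than 0.005
(at most 30 iterations), starting from the best of 1000 random kernels
(length scale ~ U(6, 72) h, period ~ U(24, 72) h, A ~ U(−1.5, 1.5)).

On top of the per-patient fits:

- **population prior** — per-patient basis kernels are summarized by
  their values at hourly lags 1..72 h, clustered with a BIC-selected
  Gaussian mixture, and each cluster's hyperparameters aggregated by
  KDE-density-weighted means; the aggregate B is refactored to
  A, λ by eigendecomposition.
- **online prediction** — a new patient is replayed in time order; each
  observation is predicted from strictly earlier data plus same-time
  observations of other covariates, then one momentum step
  (momentum 0.9, learning rate 1e-5) updates the kernel over a trailing
  72-hour window. A entries the prior set to zero stay frozen at zero.
- **evaluation** — per-covariate MAE and 95 % predictive coverage
  against naive one-lag and independent univariate GP baselines, with
  paired t-tests at a Bonferroni-corrected threshold (0.01/D: 4.17e-4
  for 24 covariates, 0.005 for 2).

A seeded synthetic-cohort generator (`medgp.synthetic`) draws EHR-like
data from known generating models so every stage is testable without
access-restricted clinical data.

## Worked example

```python
import numpy as np
from medgp import MedGP, SimConfig, default_truth, simulate_cohort

truth = default_truth(scenario="two_correlated")   # PT/INR-like pair
cohort, _ = simulate_cohort(SimConfig(
    n_patients=1, truth=truth, stay_range_h=(180, 240),
    sampling_gap_h=np.array([3.5, 3.5]), seed=0))

res = MedGP(cohort.patients[0], Q=2, R=2, n_init=200,
            max_iters=20, seed=0).fit()
print(res.summary())
```

```
MedGP per-patient fit
==========================================================
patient: p000
Q=2  D=2  R=2  sparse_prior=on
iterations: 20  converged: False  final objective: -14.00
----------------------------------------------------------
kernel   period (h)  lengthscale (h)   max |B|  rank(A)
     1         23.4             75.0     0.243        2
     2        168.6            100.9     0.308        1
----------------------------------------------------------
noise variances: PT=0.0958, INR=0.162
```

The generating model had a 24-hour circadian kernel and an aperiodic
long-term kernel with a rank-one shared loading; the fit recovers a
23.4 h period for the first and collapses the second to rank one
(one column of A shrunk below 1e-3). Predictions come with calibrated
intervals:

```python
mean, var = res.predict(np.array([100.0]), "INR")
# INR at t=100 h: -0.372 +/- 0.425   (mean ± 1.96 sd)
```

The same pipeline runs from the shell:

```
medgp simulate --scenario vitals_labs --n 30 --seed 1 --out cohort.csv
medgp fit      --input cohort.csv -Q 2 -R 2 --seed 1 --out models/
medgp aggregate --models models/ --out population.json --seed 1
medgp predict  --input cohort.csv --prior population.json --out traces/
medgp evaluate --traces traces/ --input cohort.csv --out report.csv
```

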