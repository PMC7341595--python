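# Methods

## Model

A patient's record is D irregular univariate series observed over one
stay, indexed in hours since admission. The flattened observation
vector (per-covariate blocks concatenated in a fixed covariate order)
is modeled as a zero-mean multivariate Gaussian whose covariance is a
linear model of coregionalization over Q spectral-mixture basis
kernels,

    K[s,t] = Σ_q B_q[d_s, d_t] · exp(−2π²ρ²v_q) cos(2πρμ_q) + δ_st σ²_{d_s},

with ρ the absolute time lag between observations s and t. Each basis
kernel is normalized (κ_q(0) = 1), so the weight matrices
B_q = A_q A_qᵀ + diag(λ_q) are directly interpretable as
cross-covariate covariance scales; λ ≥ 0 guarantees positive
semi-definiteness. μ_q = 0 recovers a squared-exponential kernel; the
characteristic period is 1/μ_q and the length scale 1/(2π√v_q), and
these conversions are the single source of truth used by
initialization, aggregation and reporting.

The zero-mean assumption makes raw clinical scales implausible, so
fitting standardizes each covariate by its within-patient mean and
standard deviation by default (`standardize=True`), inverting the map
on prediction. Synthetic-cohort experiments that draw data from a
zero-mean generating model fit on the native scale instead
(`standardize=False`): z-scoring a latent function whose length scale
(≈ 4 days) is comparable to the stay removes most of its within-stay
variance and whitens exactly the long-range structure those
experiments measure.

## Sparsity prior

Each A entry has a zero-mean Gaussian prior whose variance ψ is shrunk
through a four-level gamma chain with shapes α=β=γ=ξ=0.5 — a
horseshoe-equivalent construction — in which each sampled value acts
as the **rate** of the level below:

    τ_{q,r} ~ Ga(ξ, η),  φ_{q,r} ~ Ga(γ, τ),  δ_{q,d,r} ~ Ga(β, φ),
    ψ_{q,d,r} ~ Ga(α, δ),  a_{q,d,r} ~ N(0, ψ).

Under this convention small η inflates τ, which deflates φ, inflates
δ, deflates ψ: stronger shrinkage. (Note the sign of the chain
alternates: the *conditional mean of τ decreases* as η grows, yet the
net effect two levels down is looser shrinkage; the unit tests assert
both facts.) λ gets an exponential prior (half-Laplace) with scale
β_λ = 0.01 on the non-negative half-line — the non-negativity is
required by the PSD guarantee. μ_q and v_q carry flat priors inside
box bounds (period 6 h–90 d, length scale 1 h–90 d), implemented as a
smooth quadratic penalty outside the box so the objective stays
differentiable; noise variances get no prior beyond a floor of 1e-6 of
the covariate's sample variance.

The latent scales have conjugate full conditionals: δ, φ, τ are gamma
and ψ is generalized inverse Gaussian. One update sweep sets each to
its conditional mode — for ψ the positive root of
−δψ² + (α−3/2)ψ + a²/2 = 0, for a Gamma(s, r) conditional (s−1)/r when
s > 1 — falling back to the conditional mean s/r when the mode does
not exist or sits at zero (with α=β=0.5 the δ and τ conditionals have
shape exactly 1, so they always take the mean). Updates run in chain
order using the freshest values (Gauss–Seidel). Because the mean
fallback is not an argmax, a sweep can in principle lower the joint
objective; the fitting loop therefore accepts a sweep only if the
prior term does not decrease, which preserves the monotone objective
trace without altering what the update computes.

## Fitting

Per patient, the log posterior Q(θ) = log marginal likelihood
+ log prior is maximized by alternating (1) the closed-form scale
sweep and (2) conjugate-gradient ascent (scipy's CG with analytic
gradients, ≤ 50 inner iterations) over {μ_q, v_q, A, λ, σ²} with the
scales fixed, until |ΔQ| < 0.005 or 30 outer iterations. Positive
parameters are optimized as logarithms; A entries raw. Gradients use
the standard identity ∂L/∂θ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ) with per-block
aggregation for the A and λ derivatives, and are verified against
central finite differences to 1e-4 relative for every parameter class.

Initialization draws `n_init` (default 1000) full candidate kernels —
length scale ~ U(6, 72) h, period ~ U(24, 72) h, A ~ U(−1.5, 1.5),
λ = 0.1, σ² = 0.1 — and keeps the marginal-likelihood argmax (lowest
index on ties, so runs are reproducible). Cholesky factorizations add
escalating jitter (1e-8 of the mean diagonal, ×10 steps, cap 1e-2)
before declaring a numerical failure.

## Population prior and online updating

Each fitted basis kernel whose B has any entry above 1e-3 is
summarized by its 72 values at hourly lags 1..72 h (lag 0 is
identically 1 and excluded; a switch restores a 0..71 h grid).
Features are clustered with Gaussian mixtures for k = 1..Q, each
component with its own **diagonal** covariance (10 restarts, ≤ 2000
iterations), selecting k by BIC. Diagonal rather than unrestricted
covariances is a deliberate choice: with tens of kernels and 72-dim
features lying on a low-dimensional manifold, an unrestricted
covariance has ~2.7k parameters per component and BIC then always
selects one cluster; diagonal components recover planted kernel
families exactly.

Within a cluster, kernels contributed twice by one patient have their
B matrices summed first (the mixture kernel is additive). Then μ, v
and each B entry are aggregated independently by density-weighted
means under a univariate Gaussian KDE with Silverman's bandwidth —
robust to stray kernel estimates, degenerating to the plain mean for
unanimous or single-member clusters, in which case the member is
returned untouched. The aggregate B is symmetrized,
eigenvalue-floored at zero, and refactored as A = top-R scaled
eigenvectors with λ the non-negative diagonal residual — preserving
the diagonal and the PSD guarantee. Clusters are ordered by
descending length scale; noise variances and standardization
statistics are averaged arithmetically across patients. For the
univariate-GP baseline variant, per-parameter aggregation instead
takes the argmax of the product of KDE densities on a 32-point
log-spaced grid, since density-weighted means are unstable with a
single loading per kernel.

Online, a held-out patient's observations are replayed in time order.
The conditioning set for an observation at time t is all data strictly
before t plus same-time observations of *other* covariates — never any
future data, and never a same-covariate simultaneous duplicate. After
each prediction one classical momentum step (v ← 0.9 v + 1e-5 ∇;
θ ← θ + v) ascends the log marginal likelihood (plus box penalty)
restricted to observations in (t − 72 h, t]; prediction always
conditions on the full history, only the gradient is windowed. The
fitted shrinkage-scale states are not carried online, so the gradient
omits the Gaussian-scale prior terms. A entries at or below 1e-3 in
magnitude in the prior are frozen at zero, preserving the learned
sparsity structure; frequencies pinned at zero (squared-exponential
kernels) are likewise frozen. Standardization statistics for a new
patient come from the training cohort, not the patient's own future
data.

## Evaluation protocol

Methods are compared on matched events by per-covariate MAE and 95 %
coverage (100 × fraction of |y − m| ≤ 1.96 sd). The naive one-lag
baseline predicts each observation by the previous value of the same
covariate; it has no predictive distribution, so its coverage is
reported as not applicable. The univariate GP baseline fits each
covariate separately (Q=1; SE fixes μ=0) and runs the same online
protocol with D=1. Paired two-sided t-tests on per-event absolute
errors, pooled across patients, are judged at α/D with α = 0.01,
matching both printed reference thresholds (4.17e-4 at D=24, 0.005 at
D=2). Cross-validation partitions patients into k seeded folds; since
per-patient fits do not depend on fold membership, each patient is
fitted once and folds only select which kernels feed the population
prior.

## Synthetic cohorts

The generator draws length-of-stay uniformly (default 120–280 h,
spanning the median inpatient stays this data structure reflects),
per-covariate observation times by a renewal process with
multiplicative U(0.5, 1.5) gap jitter (vitals ≈ 3.5 h mean gap, labs
≈ 24 h), and the joint latent function exactly via one Cholesky of the
full kernel per patient (capped at ~1500 observations), plus
per-covariate Gaussian noise. Scenarios: `two_correlated` (a PT/INR-
like pair: rank-one shared aperiodic kernel, ℓ = 48 h, plus a 24 h
circadian kernel), `vitals_labs` (D=5: circadian kernel on a vitals
pair, >3-day smooth kernel on a correlated lab triple), and
`independent` (diagonal B, negative control). The generator samples
from the model's own assumption class — stationary, Gaussian,
missing-at-random — which is what parameter-recovery and calibration
tests require; it does not emulate systematic missingness,
artifacts, or disease-phase non-stationarity, so passing tests speak
to correctness of the machinery, not to clinical performance.

## Experiment scales and numerical choices

The seeded study experiments use sizes chosen for a single CPU:
parameter recovery fits 20 single patients (stays 180–240 h, both
covariates at 3.5 h gaps, n_init = 200); calibration replays 18
patients (~2200 events); adaptation compares frozen vs updated replay
over 10 seeds (stays 280–300 h); the end-to-end comparison fits a
30-patient `vitals_labs` cohort with 3-fold patient-level
cross-validation (Q=2, R=2, n_init = 100, ≤ 15 outer iterations). The
end-to-end check uses the non-sparse fit, which attains the best
imputation MAE — at these per-patient data sizes the MAP
hierarchical-gamma shrinkage noticeably deflates amplitudes (the same
direction as the reference comparison of sparse vs non-sparse marginal
likelihoods), and sparsity behavior is validated separately by the
rank-recovery experiment.

Known limitations: exact O(T³) inference limits patients to a few
thousand observations; B-matrix entries are only weakly identified
from a single stay (length-scale/amplitude trade-offs), so population
aggregation — not the per-patient point estimate — is the meaningful
weight estimate; the BIC cluster count is conservative at small cohort
sizes; and the online updater's learning rate (1e-5 on log-scale
parameters) is tuned for stability, not fastest possible adaptation.
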