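"""Exact GP inference: marginal likelihood, gradients, MAP fitting.

The per-patient objective is the log posterior

    Q(theta) = log p(y | x, theta) + log p(theta | scales),

maximized by alternating (1) closed-form updates of the latent
shrinkage scales (``sparse_prior.map_update_scales``) and (2) a
conjugate-gradient ascent over the kernel parameters
{mu_q, v_q, a_{q,(d,r)}, lambda_{q,(d)}, sigma_d^2} with the scales
held fixed, until the change in Q(theta) drops below the convergence
tolerance (default 0.005) or the iteration cap (default 30) is hit.

Positive parameters (mu, v, lambda, sigma^2) are optimized on the log
scale; the A entries are unconstrained.  mu and v carry flat priors
inside box bounds (period 6 h - 90 d, length scale 1 h - 90 d),
implemented as a smooth quadratic penalty outside the box so the
objective stays differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .data_model import PatientSeries, flatten
from .kernels import (
    CoregWeights,
    MedGPModel,
    SMBasisKernel,
    lengthscale_to_v,
    period_to_mu,
)
from .sparse_prior import PriorConfig, PriorState, log_prior, map_update_scales

__all__ = [
    "FitConfig",
    "FitResult",
    "log_marginal",
    "objective",
    "init_random",
    "fit_patient",
    "predict",
]

# flat-prior box bounds on the natural scale (hours)
PERIOD_BOUNDS_H = (6.0, 90.0 * 24.0)
LENGTHSCALE_BOUNDS_H = (1.0, 90.0 * 24.0)
_BOX_PENALTY_WEIGHT = 10.0

_JITTER_START = 1e-8
_JITTER_MAX = 1e-2


@dataclass
class FitConfig:
    """Settings for per-patient MAP fitting.

    n_init random kernels are drawn with length scale ~ U(6, 72) h and
    period ~ U(24, 72) h; A entries ~ U(-1.5, 1.5).  The candidate with
    the highest marginal likelihood seeds the optimizer.
    """

    Q: int = 2
    R: int = 2
    max_iters: int = 30
    tol: float = 0.005
    n_init: int = 1000
    ls_range_h: tuple[float, float] = (6.0, 72.0)
    period_range_h: tuple[float, float] = (24.0, 72.0)
    a_init_range: tuple[float, float] = (-1.5, 1.5)
    seed: int = 0
    use_sparse_prior: bool = True
    eta: float = 0.1
    standardize: bool = True
    inner_maxiter: int = 50  # CG steps per outer iteration
    fix_mu_zero: bool = False  # squared-exponential restriction (mu = 0)
    prior: PriorConfig | None = None

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        for rng_name in ("ls_range_h", "period_range_h", "a_init_range"):
            lo, hi = getattr(self, rng_name)
            if not lo <= hi:
                raise ValueError(f"{rng_name} must be ordered")
        if self.prior is None:
            self.prior = PriorConfig(eta=self.eta)


@dataclass
class FitResult:
    """Outcome of :func:`fit_patient`.

    The model lives in the (optionally standardized) fitting space;
    ``norm_mean``/``norm_sd`` hold the per-covariate statistics needed
    to map predictions back to native units.
    """

    model: MedGPModel
    prior_state: PriorState
    trace: list[float]
    converged: bool
    n_iters: int
    patient_id: str = ""
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Cholesky with escalating jitter


def _chol_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K, adding escalating diagonal jitter
    (relative to the mean diagonal) when K is numerically indefinite."""
    scale = float(np.mean(np.diag(K))) if K.size else 1.0
    if scale <= 0:
        scale = 1.0
    jitter = 0.0
    attempts = []
    while True:
        try:
            L = linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            attempts.append(jitter)
            jitter = _JITTER_START * scale if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX * scale:
                raise FloatingPointError(
                    f"Cholesky failed after jitters {attempts + [jitter]}"
                )


# ---------------------------------------------------------------------------
# Parameter packing (log scale for positives)


class _ParamSpec:
    """Maps a MedGPModel to/from a flat optimization vector.

    Layout: [log mu (Q), log v (Q), A (Q*D*R), log lam (Q*D),
    log sigma2 (D)], with boolean masks for frozen entries (e.g. mu
    pinned at 0 for squared-exponential kernels, or A entries frozen at
    zero during online updating).
    """

    def __init__(
        self,
        Q: int,
        D: int,
        R: int,
        fix_mu_zero: bool = False,
        frozen_A: np.ndarray | None = None,
        frozen_mu: np.ndarray | None = None,
    ):
        self.Q, self.D, self.R = Q, D, R
        self.n_mu = Q
        self.n_v = Q
        self.n_A = Q * D * R
        self.n_lam = Q * D
        self.n_sig = D
        self.size = self.n_mu + self.n_v + self.n_A + self.n_lam + self.n_sig
        # per-kernel mask of frequencies pinned at zero (SE restriction)
        self.frozen_mu = np.zeros(Q, dtype=bool)
        if fix_mu_zero:
            self.frozen_mu[:] = True
        if frozen_mu is not None:
            self.frozen_mu |= np.asarray(frozen_mu, dtype=bool)
        self.free = np.ones(self.size, dtype=bool)
        self.free[: self.n_mu] = ~self.frozen_mu
        if frozen_A is not None:
            off = self.n_mu + self.n_v
            self.free[off : off + self.n_A] = ~frozen_A.ravel()

    def slices(self):
        o = 0
        sl = {}
        for name, n in (
            ("mu", self.n_mu),
            ("v", self.n_v),
            ("A", self.n_A),
            ("lam", self.n_lam),
            ("sig", self.n_sig),
        ):
            sl[name] = slice(o, o + n)
            o += n
        return sl

    def pack(self, model: MedGPModel) -> np.ndarray:
        theta = np.empty(self.size)
        sl = self.slices()
        mu = np.array([k.mu for k in model.basis])
        theta[sl["mu"]] = np.log(np.maximum(mu, 1e-300))
        theta[sl["v"]] = np.log([k.v for k in model.basis])
        theta[sl["A"]] = np.concatenate([w.A.ravel() for w in model.weights])
        theta[sl["lam"]] = np.log(
            np.maximum(np.concatenate([w.lam for w in model.weights]), 1e-300)
        )
        theta[sl["sig"]] = np.log(model.noise_var)
        return theta

    def unpack(self, theta: np.ndarray, names: list[str]) -> MedGPModel:
        sl = self.slices()
        Q, D, R = self.Q, self.D, self.R
        mu = np.exp(theta[sl["mu"]])
        mu[self.frozen_mu] = 0.0
        v = np.exp(theta[sl["v"]])
        A = theta[sl["A"]].reshape(Q, D, R)
        lam = np.exp(theta[sl["lam"]]).reshape(Q, D)
        sig = np.exp(theta[sl["sig"]])
        basis = [SMBasisKernel(mu[q], v[q]) for q in range(Q)]
        weights = [CoregWeights(A[q], lam[q]) for q in range(Q)]
        return MedGPModel(basis, weights, sig, names)


# ---------------------------------------------------------------------------
# Marginal likelihood and its gradient


def _noise_diag(model: MedGPModel, ci: np.ndarray) -> np.ndarray:
    return model.noise_var[ci]


def _log_marginal_flat(
    model: MedGPModel, x: np.ndarray, y: np.ndarray, ci: np.ndarray
) -> float:
    from .kernels import gram

    T = x.size
    if T == 0:
        raise ValueError("need at least one observation")
    K = gram(model, x, ci) + np.diag(_noise_diag(model, ci))
    L, _ = _chol_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * T * np.log(2 * np.pi)
    )


def log_marginal(model: MedGPModel, patient: PatientSeries) -> float:
    """Exact GP log marginal likelihood of a patient's flattened data
    under the SM-LMC kernel plus per-covariate observation noise."""
    x, y, ci = flatten(patient)
    return _log_marginal_flat(model, x, y, ci)


def _box_penalty_terms(log_mu: np.ndarray, log_v: np.ndarray, mu_free: np.ndarray):
    """Quadratic penalty outside the flat-prior box, with gradient.
    ``mu_free`` masks out kernels whose frequency is pinned at zero."""
    pen = 0.0
    g_mu = np.zeros_like(log_mu)
    g_v = np.zeros_like(log_v)
    w = _BOX_PENALTY_WEIGHT
    mu_free = np.asarray(mu_free, dtype=bool)
    if mu_free.any():
        lo = np.log(period_to_mu(PERIOD_BOUNDS_H[1]))
        hi = np.log(period_to_mu(PERIOD_BOUNDS_H[0]))
        below = np.minimum(log_mu - lo, 0.0) * mu_free
        above = np.maximum(log_mu - hi, 0.0) * mu_free
        pen -= 0.5 * w * float(np.sum(below**2 + above**2))
        g_mu = -w * (below + above)
    lo_v = np.log(lengthscale_to_v(LENGTHSCALE_BOUNDS_H[1]))
    hi_v = np.log(lengthscale_to_v(LENGTHSCALE_BOUNDS_H[0]))
    below = np.minimum(log_v - lo_v, 0.0)
    above = np.maximum(log_v - hi_v, 0.0)
    pen -= 0.5 * w * float(np.sum(below**2 + above**2))
    g_v = -w * (below + above)
    return pen, g_mu, g_v


def objective(
    model: MedGPModel,
    prior_state: PriorState | None,
    cfg: FitConfig,
    patient: PatientSeries,
) -> float:
    """Log posterior Q(theta): marginal likelihood plus (when the
    sparse prior is active) the log prior of the kernel weights, plus
    the out-of-box penalty standing in for the flat mu/v priors."""
    val = log_marginal(model, patient)
    mu = np.array([k.mu for k in model.basis])
    log_mu = np.log(np.maximum(mu, 1e-300))
    log_v = np.log([k.v for k in model.basis])
    mu_free = (mu > 0) & (not cfg.fix_mu_zero)
    pen, _, _ = _box_penalty_terms(log_mu, log_v, mu_free)
    val += pen
    if cfg.use_sparse_prior:
        if prior_state is None:
            raise ValueError("sparse prior requires a PriorState")
        val += log_prior(model, prior_state, cfg.prior)
    return val


def _objective_and_grad(
    theta: np.ndarray,
    spec: _ParamSpec,
    x: np.ndarray,
    y: np.ndarray,
    ci: np.ndarray,
    rho: np.ndarray,
    P: np.ndarray,
    cfg: FitConfig,
    prior_state: PriorState | None,
    names: list[str],
) -> tuple[float, np.ndarray]:
    """Value and gradient of the log posterior w.r.t. the packed
    (log-scale) kernel parameter vector, scales held fixed.

    Uses the standard identity dL/dtheta = 1/2 tr((aa^T - K^-1) dK/dtheta)
    with a = K^-1 y, evaluated per parameter block.
    """
    sl = spec.slices()
    Q, D, R = spec.Q, spec.D, spec.R
    model = spec.unpack(theta, names)
    T = x.size

    mu = np.array([k.mu for k in model.basis])
    v = np.array([k.v for k in model.basis])
    A = np.stack([w.A for w in model.weights])
    lam = np.stack([w.lam for w in model.weights])
    sig = model.noise_var

    # assemble K and per-q pieces
    E = np.empty((Q, T, T))
    C = np.empty((Q, T, T))
    Kq = np.empty((Q, T, T))
    Bq = np.empty((Q, D, D))
    K = np.diag(sig[ci]).astype(float)
    rho2 = rho**2
    for q in range(Q):
        E[q] = np.exp(-2.0 * np.pi**2 * rho2 * v[q])
        C[q] = np.cos(2.0 * np.pi * rho * mu[q])
        Kq[q] = E[q] * C[q]
        Bq[q] = A[q] @ A[q].T + np.diag(lam[q])
        K += Bq[q][np.ix_(ci, ci)] * Kq[q]

    L, _ = _chol_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    Kinv = linalg.cho_solve((L, True), np.eye(T))
    val = float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * T * np.log(2 * np.pi)
    )
    G = np.outer(alpha, alpha) - Kinv

    grad = np.zeros(spec.size)
    g_mu = np.empty(Q)
    g_v = np.empty(Q)
    g_A = np.empty((Q, D, R))
    g_lam = np.empty((Q, D))
    for q in range(Q):
        Bfull = Bq[q][np.ix_(ci, ci)]
        if not spec.frozen_mu[q]:
            Sq = np.sin(2.0 * np.pi * rho * mu[q])
            dK_dmu = Bfull * (-2.0 * np.pi * rho * E[q] * Sq)
            g_mu[q] = 0.5 * np.sum(G * dK_dmu) * mu[q]  # chain rule: log mu
        else:
            g_mu[q] = 0.0
        dK_dv = Bfull * (-2.0 * np.pi**2 * rho2 * Kq[q])
        g_v[q] = 0.5 * np.sum(G * dK_dv) * v[q]
        M = G * Kq[q]
        S = P.T @ M @ P  # (D, D) symmetric aggregation over covariate blocks
        g_A[q] = S @ A[q]
        g_lam[q] = 0.5 * np.diag(S) * lam[q]
    g_sig = 0.5 * np.array([np.sum(np.diag(G)[ci == d]) for d in range(D)]) * sig

    # flat-prior box penalty on mu, v
    pen, pg_mu, pg_v = _box_penalty_terms(
        theta[sl["mu"]], theta[sl["v"]], ~spec.frozen_mu
    )
    val += pen
    g_mu += pg_mu
    g_v += pg_v

    if cfg.use_sparse_prior and prior_state is not None:
        val += log_prior(model, prior_state, cfg.prior)
        g_A += -A / prior_state.psi
        g_lam += (-1.0 / cfg.prior.beta_lambda) * lam  # chain rule: log lam

    grad[sl["mu"]] = g_mu
    grad[sl["v"]] = g_v
    grad[sl["A"]] = g_A.ravel()
    grad[sl["lam"]] = g_lam.ravel()
    grad[sl["sig"]] = g_sig
    grad[~spec.free] = 0.0
    return val, grad


def make_objective_closure(
    patient: PatientSeries,
    cfg: FitConfig,
    prior_state: PriorState | None,
    frozen_A: np.ndarray | None = None,
    frozen_mu: np.ndarray | None = None,
):
    """Build (spec, fun) where fun(theta) -> (value, grad) of the log
    posterior over the packed kernel parameters.  Shared by the batch
    fitter and the online updater."""
    x, y, ci = flatten(patient)
    D = patient.n_covariates
    spec = _ParamSpec(cfg.Q, D, cfg.R, cfg.fix_mu_zero, frozen_A, frozen_mu)
    rho = np.abs(x[:, None] - x[None, :])
    P = np.zeros((x.size, D))
    P[np.arange(x.size), ci] = 1.0

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        return _objective_and_grad(
            theta, spec, x, y, ci, rho, P, cfg, prior_state, patient.covariate_names
        )

    return spec, fun


# ---------------------------------------------------------------------------
# Initialization


def _draw_candidate(
    rng: np.random.Generator, cfg: FitConfig, D: int
) -> MedGPModel:
    basis, weights = [], []
    for _ in range(cfg.Q):
        ell = rng.uniform(*cfg.ls_range_h)
        if cfg.fix_mu_zero:
            mu = 0.0
        else:
            mu = period_to_mu(rng.uniform(*cfg.period_range_h))
        basis.append(SMBasisKernel(mu, lengthscale_to_v(ell)))
        A = rng.uniform(*cfg.a_init_range, size=(D, cfg.R))
        weights.append(CoregWeights(A, np.full(D, 0.1)))
    noise = np.full(D, 0.1)
    return MedGPModel(basis, weights, noise, ["?"] * D)


def init_random(
    patient: PatientSeries, cfg: FitConfig, rng: np.random.Generator | None = None
) -> MedGPModel:
    """Random-restart initialization: draw ``cfg.n_init`` candidate
    kernels and keep the one with the highest marginal likelihood
    (lowest index wins ties).  Deterministic given ``cfg.seed``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x, y, ci = flatten(patient)
    best, best_ll = None, -np.inf
    for _ in range(cfg.n_init):
        cand = _draw_candidate(rng, cfg, patient.n_covariates)
        cand.covariate_names = list(patient.covariate_names)
        try:
            ll = _log_marginal_flat(cand, x, y, ci)
        except FloatingPointError:
            continue
        if ll > best_ll:
            best, best_ll = cand, ll
    if best is None:
        raise FloatingPointError("no initialization candidate was evaluable")
    return best


# ---------------------------------------------------------------------------
# Standardization helpers


def standardize_patient(
    patient: PatientSeries,
    mean: np.ndarray | None = None,
    sd: np.ndarray | None = None,
) -> tuple[PatientSeries, np.ndarray, np.ndarray]:
    """Per-covariate z-scoring.  When mean/sd are omitted they are
    computed from the patient's own observations (sd floored at a tiny
    value; empty or constant series get sd = 1)."""
    D = patient.n_covariates
    if mean is None:
        mean = np.array(
            [v.mean() if v.size else 0.0 for v in patient.values]
        )
    if sd is None:
        sd = np.array(
            [v.std() if v.size > 1 and v.std() > 1e-12 else 1.0 for v in patient.values]
        )
    values = [
        (v - mean[d]) / sd[d] if v.size else v.copy()
        for d, v in enumerate(patient.values)
    ]
    out = PatientSeries(
        patient.patient_id,
        list(patient.covariate_names),
        [t.copy() for t in patient.times],
        values,
    )
    return out, np.asarray(mean, float), np.asarray(sd, float)


# ---------------------------------------------------------------------------
# Fitting


def fit_patient(patient: PatientSeries, cfg: FitConfig) -> FitResult:
    """Alternating MAP fit of one patient's SM-LMC model.

    Each outer iteration runs a closed-form sweep over the shrinkage
    scales (guarded so the joint objective never decreases) followed by
    a conjugate-gradient ascent over the kernel parameters; stops when
    |delta Q| < tol or after max_iters iterations.
    """
    if patient.n_obs < 1:
        raise ValueError("patient has no observations")
    work = patient
    norm_mean = norm_sd = None
    if cfg.standardize:
        work, norm_mean, norm_sd = standardize_patient(patient)

    rng = np.random.default_rng(cfg.seed)
    model = init_random(work, cfg, rng)
    state = PriorState.ones(cfg.Q, work.n_covariates, cfg.R)

    spec, fun = make_objective_closure(work, cfg, state)
    q_prev = objective(model, state, cfg, work)
    trace = [q_prev]
    converged = False
    n_iters = 0
    for _ in range(cfg.max_iters):
        n_iters += 1
        if cfg.use_sparse_prior:
            cand = map_update_scales(model, state, cfg.prior)
            # ascent guard: the mean fallback in the scale updates can
            # sit off the conditional mode; keep the sweep only if the
            # prior term (the only part scales touch) does not drop.
            if log_prior(model, cand, cfg.prior) >= log_prior(
                model, state, cfg.prior
            ):
                state = cand
            spec, fun = make_objective_closure(work, cfg, state)

        theta0 = spec.pack(model)

        def neg(theta):
            val, grad = fun(theta)
            return -val, -grad

        res = optimize.minimize(
            neg,
            theta0,
            jac=True,
            method="CG",
            options={"maxiter": cfg.inner_maxiter, "gtol": 1e-6},
        )
        if np.isfinite(res.fun) and -res.fun >= fun(theta0)[0] - 1e-9:
            model = spec.unpack(res.x, work.covariate_names)
        q_cur = objective(model, state, cfg, work)
        if not np.isfinite(q_cur):
            raise FloatingPointError("objective became non-finite during fitting")
        trace.append(q_cur)
        if abs(q_cur - q_prev) < cfg.tol:
            converged = True
            break
        q_prev = q_cur

    # floor the noise variances at 1e-6 of each covariate's sample variance
    sample_var = np.array(
        [v.var() if v.size > 1 else 1.0 for v in work.values]
    )
    model.noise_var = np.maximum(model.noise_var, 1e-6 * np.maximum(sample_var, 1e-12))

    return FitResult(
        model=model,
        prior_state=state,
        trace=trace,
        converged=converged,
        n_iters=n_iters,
        patient_id=patient.patient_id,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
    )


# ---------------------------------------------------------------------------
# Prediction


def predict(
    model: MedGPModel,
    history: PatientSeries | None,
    query: list[tuple[float, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior predictive mean and variance at query points.

    ``query`` is a list of (time_hours, covariate_index) pairs.  The
    predictive variance includes the observation noise sigma_d^2.  With
    empty history the prior is returned: mean 0, variance
    sum_q B_q[d, d] + sigma_d^2.
    """
    from .kernels import gram

    xq = np.array([t for t, _ in query], dtype=float)
    cq = np.array([d for _, d in query], dtype=int)
    prior_var = np.array(
        [sum(model.B(q)[d, d] for q in range(model.Q)) for d in cq]
    ) + model.noise_var[cq]
    if history is None or history.n_obs == 0:
        return np.zeros(xq.size), prior_var

    x, y, ci = flatten(history)
    K = gram(model, x, ci) + np.diag(_noise_diag(model, ci))
    L, _ = _chol_jitter(K)
    Ks = gram(model, x, ci, (xq, cq))  # (T, M)
    alpha = linalg.cho_solve((L, True), y)
    mean = Ks.T @ alpha
    Vs = linalg.solve_triangular(L, Ks, lower=True)
    var = prior_var - np.sum(Vs**2, axis=0)
    var = np.maximum(var, 1e-12)
    return mean, var
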