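"""Spectral-mixture basis kernels and the block-structured SM-LMC kernel.

The multi-output covariance between observation s of covariate d and
observation t of covariate d' is

    k(s, t) = sum_q b_{q,(d,d')} * kappa_q(|x_s - x_t|),

with stationary spectral-mixture basis kernels

    kappa_q(rho) = exp(-2 pi^2 rho^2 v_q) * cos(2 pi rho mu_q),

and cross-covariate weight matrices B_q = A_q A_q^T + diag(lambda_q),
positive (semi-)definite by construction.  kappa_q(0) = 1, so B_q
carries all amplitude information.  The characteristic period of a
basis kernel is 1/mu_q and its length scale is 1/(2 pi sqrt(v_q)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SMBasisKernel",
    "CoregWeights",
    "MedGPModel",
    "sm_eval",
    "build_B",
    "gram",
    "count_hyperparameters",
    "lengthscale_to_v",
    "v_to_lengthscale",
    "period_to_mu",
    "mu_to_period",
]

# Entries of |A| at or below this are treated as structurally zero
# (used for sparsity reporting, population filtering and online freezing).
NEAR_ZERO = 1e-3


def lengthscale_to_v(ell_h: float) -> float:
    """Spectral variance v from characteristic length scale (hours)."""
    return 1.0 / (2.0 * np.pi * ell_h) ** 2


def v_to_lengthscale(v: float) -> float:
    return 1.0 / (2.0 * np.pi * np.sqrt(v))


def period_to_mu(period_h: float) -> float:
    """Frequency mu (cycles/hour) from period (hours)."""
    return 1.0 / period_h


def mu_to_period(mu: float) -> float:
    return 1.0 / mu


@dataclass
class SMBasisKernel:
    """One spectral-mixture basis kernel.

    Parameters
    ----------
    mu : float
        Frequency in cycles per hour (>= 0); 0 gives a pure
        squared-exponential kernel.
    v : float
        Spectral variance in 1/hour^2 (>= 0); controls decay.
    """

    mu: float
    v: float

    def __post_init__(self) -> None:
        if self.mu < 0 or self.v < 0:
            raise ValueError("mu and v must be non-negative")

    @property
    def period_h(self) -> float:
        """Characteristic period 1/mu (hours); inf when aperiodic."""
        return 1.0 / self.mu if self.mu > 0 else np.inf

    @property
    def lengthscale_h(self) -> float:
        """Characteristic length scale 1/(2 pi sqrt(v)) (hours)."""
        return v_to_lengthscale(self.v) if self.v > 0 else np.inf


@dataclass
class CoregWeights:
    """Low-rank-plus-diagonal weights for one basis kernel.

    ``B = A @ A.T + diag(lam)`` is the D x D cross-covariate weight
    matrix; strictly positive definite when all lam > 0.
    """

    A: np.ndarray  # (D, R)
    lam: np.ndarray  # (D,) non-negative

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.lam = np.asarray(self.lam, dtype=float).ravel()
        if self.A.shape[0] != self.lam.size:
            raise ValueError("A rows and lam length must both equal D")
        if np.any(self.lam < 0):
            raise ValueError("lam entries must be non-negative")

    @property
    def D(self) -> int:
        return self.A.shape[0]

    @property
    def R(self) -> int:
        return self.A.shape[1]


def sm_eval(rho, kernel: SMBasisKernel):
    """Evaluate the spectral-mixture kernel at absolute time lag rho >= 0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative (pass absolute time lags)")
    out = np.exp(-2.0 * np.pi**2 * rho**2 * kernel.v) * np.cos(
        2.0 * np.pi * rho * kernel.mu
    )
    return out if out.ndim else float(out)


def build_B(w: CoregWeights) -> np.ndarray:
    """Cross-covariate weight matrix B = A A^T + diag(lam)."""
    return w.A @ w.A.T + np.diag(w.lam)


@dataclass
class MedGPModel:
    """Full SM-LMC model: Q basis kernels, weights and per-covariate noise.

    Parameters
    ----------
    basis : list of SMBasisKernel
    weights : list of CoregWeights
        One per basis kernel, all sharing D.
    noise_var : ndarray, shape (D,)
        Per-covariate residual variances sigma_d^2 (> 0).
    covariate_names : list of str
    """

    basis: list[SMBasisKernel]
    weights: list[CoregWeights]
    noise_var: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        if len(self.basis) != len(self.weights):
            raise ValueError("need one weight matrix per basis kernel")
        self.noise_var = np.asarray(self.noise_var, dtype=float).ravel()
        D = len(self.covariate_names)
        for w in self.weights:
            if w.D != D:
                raise ValueError("weight matrices must match covariate count")
        if self.noise_var.size != D:
            raise ValueError("noise_var must have one entry per covariate")
        if np.any(self.noise_var <= 0):
            raise ValueError("noise variances must be strictly positive")

    @property
    def Q(self) -> int:
        return len(self.basis)

    @property
    def D(self) -> int:
        return len(self.covariate_names)

    def B(self, q: int) -> np.ndarray:
        return build_B(self.weights[q])

    def copy(self) -> "MedGPModel":
        return MedGPModel(
            [SMBasisKernel(k.mu, k.v) for k in self.basis],
            [CoregWeights(w.A.copy(), w.lam.copy()) for w in self.weights],
            self.noise_var.copy(),
            list(self.covariate_names),
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "D": self.D,
            "R": [w.R for w in self.weights],
            "covariate_names": list(self.covariate_names),
            "kernels": [
                {
                    "mu": k.mu,
                    "v": k.v,
                    "A": w.A.ravel().tolist(),
                    "lambda": w.lam.tolist(),
                }
                for k, w in zip(self.basis, self.weights)
            ],
            "noise_var": self.noise_var.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MedGPModel":
        D = d["D"]
        basis, weights = [], []
        for kd, R in zip(d["kernels"], d["R"]):
            basis.append(SMBasisKernel(kd["mu"], kd["v"]))
            weights.append(
                CoregWeights(np.array(kd["A"]).reshape(D, R), np.array(kd["lambda"]))
            )
        return cls(basis, weights, np.array(d["noise_var"]), d["covariate_names"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MedGPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def gram(
    model: MedGPModel,
    x: np.ndarray,
    cov_index: np.ndarray,
    x2: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """SM-LMC Gram matrix on flattened inputs.

    Entry (s, t) is ``sum_q B_q[d_s, d_t] * kappa_q(|x_s - x_t|)``.
    With ``x2`` omitted the result is symmetric PSD (noise excluded).

    Parameters
    ----------
    x, cov_index : arrays of equal length
        Flattened times and 0-based covariate indices.
    x2 : (times, cov_index) pair, optional
        Second input set for a cross-covariance block.
    """
    x = np.asarray(x, dtype=float).ravel()
    ci = np.asarray(cov_index, dtype=int).ravel()
    if x.size != ci.size:
        raise ValueError("x and cov_index lengths differ")
    if ci.size and (ci.min() < 0 or ci.max() >= model.D):
        raise ValueError("cov_index out of range")
    if x2 is None:
        xb, cb = x, ci
    else:
        xb = np.asarray(x2[0], dtype=float).ravel()
        cb = np.asarray(x2[1], dtype=int).ravel()
        if xb.size != cb.size:
            raise ValueError("x2 times and cov_index lengths differ")
        if cb.size and (cb.min() < 0 or cb.max() >= model.D):
            raise ValueError("x2 cov_index out of range")

    rho = np.abs(x[:, None] - xb[None, :])
    K = np.zeros((x.size, xb.size))
    for q in range(model.Q):
        Bq = model.B(q)
        K += Bq[np.ix_(ci, cb)] * sm_eval(rho, model.basis[q])
    return K


def count_hyperparameters(Q: int, D: int, R: int, include_noise: bool = False) -> int:
    """Number of scalar hyperparameters of a Q-kernel, D-covariate,
    rank-R SM-LMC model: per kernel mu, v, the D*R entries of A and the
    D entries of lambda; plus the D noise variances when requested."""
    if Q < 1 or D < 1 or R < 1:
        raise ValueError("Q, D and R must be positive")
    n = Q * (2 + D * R + D)
    if include_noise:
        n += D
    return n
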