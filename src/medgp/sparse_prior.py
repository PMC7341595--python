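"""Structured sparsity prior on the coregionalization weights.

Each element a_{q,(d,r)} of the low-rank factors gets a zero-mean
Gaussian prior whose variance psi is itself shrunk through a four-level
gamma chain (shapes alpha = beta = gamma = xi = 0.5, a horseshoe-
equivalent construction):

    tau_{q,(r)}    ~ Gamma(xi,    rate=eta)          column / global
    phi_{q,(r)}    ~ Gamma(gamma, rate=tau_{q,(r)})  column
    delta_{q,(d,r)}~ Gamma(beta,  rate=phi_{q,(r)})  element
    psi_{q,(d,r)}  ~ Gamma(alpha, rate=delta_{q,(d,r)})
    a_{q,(d,r)}    ~ Normal(0, psi_{q,(d,r)})

Each sampled value acts as the *rate* of the level below, so small eta
chains into strong shrinkage of the weights.  The diagonal weights
lambda_{q,(d)} >= 0 get an exponential (half-Laplace) prior with scale
beta_lambda.

The latent scales are updated in closed form: by conjugacy every full
conditional is a gamma (for delta, phi, tau) or a generalized inverse
Gaussian (for psi), and we take its mode, falling back to the
conditional mean when the mode does not exist or sits at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import MedGPModel

__all__ = ["PriorConfig", "PriorState", "log_prior", "map_update_scales"]

_SCALE_FLOOR = 1e-12


@dataclass
class PriorConfig:
    """Hyperparameters of the sparsity prior.

    eta is the global-shrinkage rate: smaller eta inflates tau, which
    chains into smaller psi and stronger shrinkage of the A entries.
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma: float = 0.5
    xi: float = 0.5
    eta: float = 0.1
    beta_lambda: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "xi", "eta", "beta_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "xi": self.xi,
            "eta": self.eta,
            "beta_lambda": self.beta_lambda,
        }


@dataclass
class PriorState:
    """Latent scales of the gamma chain, shaped to match the model's A.

    psi, delta: (Q, D, R); phi, tau: (Q, R).  All strictly positive.
    """

    psi: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.psi.shape != self.delta.shape or self.psi.ndim != 3:
            raise ValueError("psi and delta must both be (Q, D, R)")
        if self.phi.shape != self.tau.shape or self.phi.shape != (
            self.psi.shape[0],
            self.psi.shape[2],
        ):
            raise ValueError("phi and tau must both be (Q, R)")
        for name in ("psi", "delta", "phi", "tau"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} entries must be strictly positive")

    @classmethod
    def ones(cls, Q: int, D: int, R: int) -> "PriorState":
        return cls(
            np.ones((Q, D, R)), np.ones((Q, D, R)), np.ones((Q, R)), np.ones((Q, R))
        )

    def copy(self) -> "PriorState":
        return PriorState(
            self.psi.copy(), self.delta.copy(), self.phi.copy(), self.tau.copy()
        )


def _stack_A(model: MedGPModel) -> np.ndarray:
    return np.stack([w.A for w in model.weights])  # (Q, D, R)


def log_prior(model: MedGPModel, state: PriorState, cfg: PriorConfig) -> float:
    """Log prior density of the kernel weights and latent scales.

    Sums the Gaussian a|psi terms, the gamma-chain terms, and the
    exponential terms on lambda.  mu_q and v_q carry flat priors within
    their box bounds, contributing zero here (bound handling lives in
    the optimizer).
    """
    A = _stack_A(model)
    if A.shape != state.psi.shape:
        raise ValueError("prior state shape does not match model A matrices")
    lp = float(np.sum(stats.norm.logpdf(A, loc=0.0, scale=np.sqrt(state.psi))))
    lp += float(
        np.sum(stats.gamma.logpdf(state.psi, cfg.alpha, scale=1.0 / state.delta))
    )
    lp += float(
        np.sum(
            stats.gamma.logpdf(
                state.delta, cfg.beta, scale=1.0 / state.phi[:, None, :]
            )
        )
    )
    lp += float(
        np.sum(stats.gamma.logpdf(state.phi, cfg.gamma, scale=1.0 / state.tau))
    )
    lp += float(np.sum(stats.gamma.logpdf(state.tau, cfg.xi, scale=1.0 / cfg.eta)))
    lam = np.stack([w.lam for w in model.weights])
    lp += float(np.sum(-np.log(cfg.beta_lambda) - lam / cfg.beta_lambda))
    return lp


def _gamma_mode_or_mean(shape: float, rate: np.ndarray) -> np.ndarray:
    """MAP point of a Gamma(shape, rate) conditional: mode (shape-1)/rate
    when the mode exists away from zero, conditional mean shape/rate
    otherwise."""
    if shape > 1.0:
        return (shape - 1.0) / rate
    return shape / rate


def map_update_scales(
    model: MedGPModel, state: PriorState, cfg: PriorConfig
) -> PriorState:
    """One closed-form sweep over the latent scales psi, delta, phi, tau.

    Full conditionals under the rate-chained construction:

    - psi  | a, delta  ~ GIG: log-density (alpha - 3/2) log psi
      - delta psi - a^2/(2 psi); mode is the positive root of
      -delta psi^2 + (alpha - 3/2) psi + a^2/2 = 0.
    - delta| psi, phi  ~ Gamma(alpha + beta, psi + phi)
    - phi  | delta, tau~ Gamma(D beta + gamma, sum_d delta + tau)
    - tau  | phi       ~ Gamma(gamma + xi, phi + eta)

    Updates are applied in chain order (Gauss-Seidel), each using the
    freshest values, so the sweep is coordinate ascent on the joint
    log posterior of the scales.
    """
    A = _stack_A(model)
    if A.shape != state.psi.shape:
        raise ValueError("prior state shape does not match model A matrices")
    Q, D, R = A.shape
    new = state.copy()

    # psi: generalized-inverse-Gaussian mode, quadratic root
    p = cfg.alpha - 1.5
    a2 = A**2
    psi_mode = (p + np.sqrt(p * p + 2.0 * new.delta * a2)) / (2.0 * new.delta)
    # a == 0 (and alpha <= 3/2) degenerates the mode to the boundary;
    # fall back to the Gamma(alpha - 1/2, delta) conditional's MAP point.
    shape0 = cfg.alpha - 0.5
    if shape0 > 1.0:
        fallback = (shape0 - 1.0) / new.delta
    elif shape0 > 0.0:
        fallback = shape0 / new.delta
    else:
        fallback = np.full_like(new.delta, _SCALE_FLOOR)
    new.psi = np.where(psi_mode > 0, psi_mode, fallback)
    new.psi = np.maximum(new.psi, _SCALE_FLOOR)

    new.delta = _gamma_mode_or_mean(
        cfg.alpha + cfg.beta, new.psi + new.phi[:, None, :]
    )
    new.delta = np.maximum(new.delta, _SCALE_FLOOR)

    new.phi = _gamma_mode_or_mean(
        D * cfg.beta + cfg.gamma, new.delta.sum(axis=1) + new.tau
    )
    new.phi = np.maximum(new.phi, _SCALE_FLOOR)

    new.tau = _gamma_mode_or_mean(cfg.gamma + cfg.xi, new.phi + cfg.eta)
    new.tau = np.maximum(new.tau, _SCALE_FLOOR)
    return new
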