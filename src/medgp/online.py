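"""Sequential prediction and momentum updating for a new patient.

The patient's observations are replayed in time order.  Each one is
predicted from strictly earlier observations plus same-time
observations of *other* covariates (never any future data), scored
against its 95% predictive interval, and then — when updating is on —
used for one momentum step on the kernel hyperparameters, with the
gradient computed over a trailing 72-hour window of observations.
A-matrix entries that the empirical population prior set to (near)
zero are frozen at zero so the learned sparsity structure survives
patient-specific adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PatientSeries, flatten, unflatten
from .inference import FitConfig, make_objective_closure, predict
from .kernels import MedGPModel
from .population import PopulationPrior

__all__ = ["OnlineConfig", "OnlineTrace", "run_online", "momentum_step"]


@dataclass
class OnlineConfig:
    """Online-updating settings (momentum 0.9, learning rate 1e-5,
    72-hour gradient window by default)."""

    momentum: float = 0.9
    learning_rate: float = 1e-5
    window_h: float = 72.0
    freeze_threshold: float = 1e-3
    update: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.window_h <= 0:
            raise ValueError("window_h must be positive")


@dataclass
class OnlineTrace:
    """Per-event predictions in chronological order.

    ``records`` columns: patient_id, time_hours, covariate, observed,
    pred_mean, pred_var, in_95ci — all in covariate-native units.
    """

    records: pd.DataFrame
    final_model: MedGPModel | None = None

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OnlineTrace":
        return cls(pd.read_csv(path))


def momentum_step(
    grad: np.ndarray, velocity: np.ndarray, cfg: OnlineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Classical momentum ascent step:
    v <- momentum * v + lr * grad;  delta = v.
    Non-finite gradients yield a zero delta and unchanged velocity."""
    if not np.all(np.isfinite(grad)):
        return np.zeros_like(velocity), velocity
    new_v = cfg.momentum * velocity + cfg.learning_rate * grad
    return new_v.copy(), new_v


def _event_table(patient: PatientSeries) -> np.ndarray:
    x, y, ci = flatten(patient)
    order = np.lexsort((ci, x))  # time-major, covariate order breaks ties
    return np.column_stack([x[order], ci[order].astype(float), y[order]])


def run_online(
    patient: PatientSeries,
    prior: PopulationPrior | MedGPModel,
    cfg: OnlineConfig | None = None,
) -> OnlineTrace:
    """Replay one patient online against a population prior.

    When ``prior`` is a :class:`PopulationPrior` carrying training-
    cohort standardization statistics, the patient's values are
    z-scored with those statistics for prediction and updating, and
    predictions are mapped back to native units in the trace.
    """
    if cfg is None:
        cfg = OnlineConfig()
    if isinstance(prior, PopulationPrior):
        model = prior.to_model()
        nm, ns = prior.norm_mean, prior.norm_sd
    else:
        model = prior.copy()
        nm = ns = None
    if model.D != patient.n_covariates:
        raise ValueError("prior covariate count does not match the patient")
    if nm is None:
        nm = np.zeros(model.D)
        ns = np.ones(model.D)

    events = _event_table(patient)
    n = events.shape[0]
    times = events[:, 0]
    covs = events[:, 1].astype(int)
    vals_nat = events[:, 2]
    vals_std = (vals_nat - nm[covs]) / ns[covs]

    Q = model.Q
    R = model.weights[0].R
    frozen_A = np.stack(
        [np.abs(w.A) <= cfg.freeze_threshold for w in model.weights]
    )
    # gradient objective: marginal likelihood with flat-prior box
    # penalty; the fitted shrinkage scales are not carried online
    grad_cfg = FitConfig(
        Q=Q, R=R, n_init=1, use_sparse_prior=False, standardize=False
    )
    frozen_mu = np.array([k.mu == 0 for k in model.basis])

    velocity = None
    rows = []
    for t_idx in range(n):
        t, d, y_obs = times[t_idx], covs[t_idx], vals_std[t_idx]
        cond = (times < t) | ((times == t) & (covs != d))
        hist = unflatten(
            times[cond], vals_std[cond], covs[cond], patient.covariate_names
        )
        mean_s, var_s = predict(model, hist, [(t, int(d))])
        mean_s, var_s = float(mean_s[0]), float(var_s[0])
        in_ci = abs(y_obs - mean_s) <= 1.96 * np.sqrt(var_s)
        rows.append(
            (
                patient.patient_id,
                t,
                patient.covariate_names[d],
                vals_nat[t_idx],
                mean_s * ns[d] + nm[d],
                var_s * ns[d] ** 2,
                bool(in_ci),
            )
        )

        if cfg.update and cfg.learning_rate > 0:
            win = (times > t - cfg.window_h) & (times <= t)
            wseries = unflatten(
                times[win], vals_std[win], covs[win], patient.covariate_names
            )
            spec, fun = make_objective_closure(
                wseries, grad_cfg, None, frozen_A, frozen_mu
            )
            if velocity is None:
                velocity = np.zeros(spec.size)
            theta = spec.pack(model)
            try:
                _, grad = fun(theta)
            except FloatingPointError:
                warnings.warn(
                    f"online update skipped at t={t:.1f} h (numerical failure)"
                )
                continue
            delta, velocity = momentum_step(grad, velocity, cfg)
            model = spec.unpack(theta + delta, patient.covariate_names)

    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "time_hours",
            "covariate",
            "observed",
            "pred_mean",
            "pred_var",
            "in_95ci",
        ],
    )
    return OnlineTrace(df, final_model=model)
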