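"""Seeded generator of EHR-like cohorts from a known SM-LMC model.

Emulates the sampling structure of inpatient records: a handful of
vital signs observed every few hours, labs roughly daily, observation
times unaligned across covariates and patients, per-covariate Gaussian
noise.  The latent multi-output function is drawn exactly from the
zero-mean GP defined by a known ("truth") model via one joint Cholesky
per patient, so parameter-recovery tests have an exact generating
record to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Cohort, PatientSeries, unflatten
from .inference import _chol_jitter
from .kernels import (
    CoregWeights,
    MedGPModel,
    SMBasisKernel,
    gram,
    lengthscale_to_v,
    period_to_mu,
)

__all__ = ["SimConfig", "simulate_cohort", "default_truth", "SCENARIOS"]

_MAX_OBS_PER_PATIENT = 1500


@dataclass
class SimConfig:
    """Study conditions for cohort simulation.

    sampling_gap_h gives each covariate's mean inter-observation gap in
    hours (vitals ~3.5 h, labs ~24 h); actual gaps are jittered
    multiplicatively by U(0.5, 1.5).  Length-of-stay is uniform over
    stay_range_h (default 120-280 h, the range of the median inpatient
    stays this generator emulates).
    """

    n_patients: int
    truth: MedGPModel
    stay_range_h: tuple[float, float] = (120.0, 280.0)
    sampling_gap_h: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stay_range_h
        if not 0 < lo <= hi:
            raise ValueError("stay_range_h must be ordered and positive")
        if self.sampling_gap_h is None:
            self.sampling_gap_h = np.full(self.truth.D, 24.0)
        self.sampling_gap_h = np.asarray(self.sampling_gap_h, dtype=float).ravel()
        if self.sampling_gap_h.size != self.truth.D:
            raise ValueError("one sampling gap per covariate required")
        if np.any(self.sampling_gap_h <= 0):
            raise ValueError("sampling gaps must be positive")


def _draw_times(
    rng: np.random.Generator, stay_h: float, mean_gap: float
) -> np.ndarray:
    """Jittered-gap renewal process on [0, stay_h]."""
    times = []
    t = rng.uniform(0, mean_gap)
    while t <= stay_h:
        times.append(t)
        t += mean_gap * rng.uniform(0.5, 1.5)
    return np.array(times)


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, dict]:
    """Simulate a cohort and return it with the full generating record.

    The record holds, per patient, the flattened times, covariate
    indices, noiseless latent values, and the truth model, for use by
    recovery and calibration tests.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = cfg.truth
    D = truth.D
    # validate the truth kernel is usable before any drawing
    probe = np.linspace(0.0, 10.0, 4)
    Kp = gram(truth, np.tile(probe, D), np.repeat(np.arange(D), probe.size))
    try:
        _chol_jitter(Kp)
    except FloatingPointError as err:
        raise ValueError("truth kernel is not positive semi-definite") from err

    patients = []
    record = {"truth": truth.copy(), "patients": {}}
    for i in range(cfg.n_patients):
        stay = rng.uniform(*cfg.stay_range_h)
        times = [_draw_times(rng, stay, g) for g in cfg.sampling_gap_h]
        total = sum(t.size for t in times)
        if total > _MAX_OBS_PER_PATIENT:
            keep = _MAX_OBS_PER_PATIENT / total
            times = [t[: max(1, int(t.size * keep))] for t in times]
        x = np.concatenate(times) if total else np.empty(0)
        ci = np.repeat(np.arange(D), [t.size for t in times])
        if x.size:
            K = gram(truth, x, ci)
            L, _ = _chol_jitter(K + 1e-10 * np.eye(x.size))
            latent = L @ rng.standard_normal(x.size)
            noise = rng.standard_normal(x.size) * np.sqrt(truth.noise_var[ci])
            y = latent + noise
        else:
            latent = y = np.empty(0)
        pid = f"p{i:03d}"
        patients.append(unflatten(x, y, ci, truth.covariate_names, pid))
        record["patients"][pid] = {
            "x": x,
            "cov_index": ci,
            "latent": latent,
            "stay_h": stay,
        }
    return Cohort(patients, list(truth.covariate_names)), record


def _weights(A_cols: np.ndarray, lam: np.ndarray, R: int) -> CoregWeights:
    """Pad a (D, r) loading block to rank R with zero columns."""
    A_cols = np.atleast_2d(np.asarray(A_cols, float))
    if A_cols.ndim == 2 and A_cols.shape[1] < R:
        A_cols = np.hstack([A_cols, np.zeros((A_cols.shape[0], R - A_cols.shape[1]))])
    return CoregWeights(A_cols, np.asarray(lam, float))


def default_truth(D: int | None = None, scenario: str = "two_correlated") -> MedGPModel:
    """Canned generating models for the study scenarios.

    - ``two_correlated``: D=2, a PT/INR-like pair; a rank-1 long-term
      smooth kernel shared by both covariates plus a 24-h periodic
      kernel.
    - ``vitals_labs``: D=5 (two vitals, a correlated lab triple); one
      >3-day smooth kernel loading the lab triple, one 24-h periodic
      kernel loading the vitals block.
    - ``independent``: diagonal B (no cross-covariate structure),
      negative control; any D (default 2).
    """
    if scenario == "two_correlated":
        if D not in (None, 2):
            raise ValueError("two_correlated is a D=2 scenario")
        basis = [
            SMBasisKernel(0.0, lengthscale_to_v(48.0)),  # long-term smooth
            SMBasisKernel(period_to_mu(24.0), lengthscale_to_v(200.0)),
        ]
        weights = [
            _weights(np.array([[1.0], [0.85]]), [0.0, 0.0], 2),  # rank-1 shared
            _weights(np.array([[0.6], [0.3]]), [0.05, 0.05], 2),
        ]
        noise = np.array([0.05, 0.05])
        names = ["PT", "INR"]
    elif scenario == "vitals_labs":
        if D not in (None, 5):
            raise ValueError("vitals_labs is a D=5 scenario")
        basis = [
            SMBasisKernel(0.0, lengthscale_to_v(96.0)),  # > 3-day smooth
            SMBasisKernel(period_to_mu(24.0), lengthscale_to_v(200.0)),  # circadian
        ]
        weights = [
            # smooth kernel: correlated lab triple (Hct/Hgb/RBC-like)
            _weights(
                np.array([[0.25], [0.2], [1.0], [0.95], [0.9]]),
                [0.05, 0.05, 0.02, 0.02, 0.02],
                2,
            ),
            # periodic kernel: vitals block only
            _weights(
                np.array([[0.8], [0.6], [0.0], [0.0], [0.0]]),
                [0.05, 0.05, 0.0, 0.0, 0.0],
                2,
            ),
        ]
        noise = np.array([0.1, 0.1, 0.05, 0.05, 0.05])
        names = ["HR", "RR", "Hct", "Hgb", "RBC"]
    elif scenario == "independent":
        Dn = 2 if D is None else D
        basis = [
            SMBasisKernel(0.0, lengthscale_to_v(48.0)),
            SMBasisKernel(period_to_mu(24.0), lengthscale_to_v(200.0)),
        ]
        weights = [
            _weights(np.zeros((Dn, 1)), np.linspace(0.8, 1.2, Dn), 2),
            _weights(np.zeros((Dn, 1)), np.linspace(0.3, 0.5, Dn), 2),
        ]
        noise = np.full(Dn, 0.05)
        names = [f"cov{d+1}" for d in range(Dn)]
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose one of {sorted(SCENARIOS)}"
        )
    return MedGPModel(basis, weights, noise, names)


SCENARIOS = {"two_correlated", "vitals_labs", "independent"}


def default_gaps(scenario: str) -> np.ndarray:
    """Per-covariate mean sampling gaps (hours) matching each scenario:
    vitals every ~3.5 h, labs roughly daily."""
    if scenario == "two_correlated":
        return np.array([24.0, 24.0])
    if scenario == "vitals_labs":
        return np.array([3.5, 3.5, 24.0, 24.0, 24.0])
    if scenario == "independent":
        return None  # filled by SimConfig default (daily)
    raise ValueError(f"unknown scenario {scenario!r}")
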