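"""Model/Results front end for per-patient fitting.

``MedGP`` wraps one patient's multivariate series; ``fit()`` runs the
alternating MAP optimizer and returns ``MedGPResults`` carrying the
estimated kernel, the objective trace, and prediction utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import Cohort, PatientSeries, read_cohort
from .inference import FitConfig, FitResult, fit_patient, log_marginal, predict
from .kernels import MedGPModel, NEAR_ZERO, build_B

__all__ = ["MedGP", "MedGPResults"]


class MedGP:
    """Sparse multi-output GP model of one patient's clinical series.

    Parameters
    ----------
    patient : PatientSeries
        Irregular multivariate observations (hours since admission).
    Q : int
        Number of spectral-mixture basis kernels.
    R : int
        Rank of each coregionalization factor A_q.
    **fit_kwargs
        Forwarded to :class:`~medgp.inference.FitConfig` (eta,
        use_sparse_prior, n_init, seed, ...).
    """

    def __init__(self, patient: PatientSeries, Q: int = 2, R: int = 2, **fit_kwargs):
        self.patient = patient
        self.config = FitConfig(Q=Q, R=R, **fit_kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        patient_id: str | None = None,
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "MedGP":
        """Build from a long-format frame with columns patient_id,
        covariate, time_hours, value (one patient; or name one)."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        cohort = read_cohort(buf, covariates=covariates)
        if patient_id is None:
            if cohort.n_patients != 1:
                raise ValueError(
                    "frame holds several patients; pass patient_id"
                )
            patient = cohort.patients[0]
        else:
            match = [p for p in cohort.patients if p.patient_id == str(patient_id)]
            if not match:
                raise ValueError(f"patient {patient_id!r} not in frame")
            patient = match[0]
        return cls(patient, **kwargs)

    def fit(self, **overrides) -> "MedGPResults":
        cfg = self.config
        if overrides:
            cfg = FitConfig(**{**cfg.__dict__, **overrides, "prior": None})
        return MedGPResults(self, fit_patient(self.patient, cfg), cfg)


class MedGPResults:
    """Fitted per-patient SM-LMC model.

    Attributes
    ----------
    model : MedGPModel
        Fitted kernel (in the standardized fitting space when
        standardization is on).
    trace : list of float
        Objective value per outer iteration.
    converged : bool
    """

    def __init__(self, parent: MedGP, result: FitResult, cfg: FitConfig):
        self._parent = parent
        self._result = result
        self.config = cfg
        self.model = result.model
        self.trace = result.trace
        self.converged = result.converged
        self.n_iters = result.n_iters

    @property
    def loglike(self) -> float:
        """Final log marginal likelihood in the fitting space."""
        work = self._fitting_space_patient()
        return log_marginal(self.model, work)

    def _fitting_space_patient(self) -> PatientSeries:
        from .inference import standardize_patient

        if self._result.norm_mean is None:
            return self._parent.patient
        work, _, _ = standardize_patient(
            self._parent.patient, self._result.norm_mean, self._result.norm_sd
        )
        return work

    def predict(
        self, times: np.ndarray, covariate: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior predictive mean/variance (native units) at new
        times for one covariate, conditioning on all observations."""
        d = self._parent.patient.covariate_names.index(covariate)
        work = self._fitting_space_patient()
        mean, var = predict(self.model, work, [(float(t), d) for t in np.atleast_1d(times)])
        if self._result.norm_mean is not None:
            sd = self._result.norm_sd[d]
            mean = mean * sd + self._result.norm_mean[d]
            var = var * sd**2
        return mean, var

    def summary(self) -> str:
        """Plain-text summary of the fitted kernel."""
        m = self.model
        lines = []
        lines.append("MedGP per-patient fit")
        lines.append("=" * 58)
        lines.append(f"patient: {self._parent.patient.patient_id}")
        lines.append(
            f"Q={m.Q}  D={m.D}  R={m.weights[0].R}  "
            f"sparse_prior={'on' if self.config.use_sparse_prior else 'off'}"
        )
        lines.append(
            f"iterations: {self.n_iters}  converged: {self.converged}  "
            f"final objective: {self.trace[-1]:.2f}"
        )
        lines.append("-" * 58)
        lines.append(f"{'kernel':>6} {'period (h)':>12} {'lengthscale (h)':>16} "
                     f"{'max |B|':>9} {'rank(A)':>8}")
        for q, (k, w) in enumerate(zip(m.basis, m.weights)):
            per = f"{k.period_h:.1f}" if np.isfinite(k.period_h) else "aperiodic"
            nz_cols = int(np.sum(np.linalg.norm(w.A, axis=0) > NEAR_ZERO))
            lines.append(
                f"{q + 1:>6} {per:>12} {k.lengthscale_h:>16.1f} "
                f"{np.max(np.abs(build_B(w))):>9.3f} {nz_cols:>8}"
            )
        lines.append("-" * 58)
        noise = ", ".join(
            f"{n}={s:.3g}" for n, s in zip(m.covariate_names, m.noise_var)
        )
        lines.append(f"noise variances: {noise}")
        return "\n".join(lines)
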