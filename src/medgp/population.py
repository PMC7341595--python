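"""Group-level empirical prior over per-patient kernels.

After fitting one SM-LMC model per training patient, the per-patient
basis kernels are summarized by their covariance values on an hourly
grid of lags (1..72 h), clustered with a BIC-selected Gaussian mixture,
and each cluster's hyperparameters are aggregated by density-weighted
means under univariate Gaussian KDEs (Silverman bandwidth).  The
aggregated cross-covariate weight matrix of each cluster is refactored
into low-rank-plus-diagonal form by eigendecomposition so that online
updating can run on the same parameterization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .inference import FitResult
from .kernels import (
    NEAR_ZERO,
    CoregWeights,
    MedGPModel,
    SMBasisKernel,
    build_B,
    sm_eval,
    v_to_lengthscale,
)

__all__ = [
    "KernelFeature",
    "PopulationPrior",
    "featurize",
    "cluster_kernels",
    "aggregate_cluster",
    "build_population_prior",
    "kde_weighted_mean",
    "grid_kde_argmax",
]

FEATURE_LAGS_H = np.arange(1, 73, dtype=float)  # 1 h .. 72 h


@dataclass
class KernelFeature:
    """A basis kernel summarized by its values at hourly lags 1..72 h."""

    values: np.ndarray
    source: tuple[str, int]  # (patient_id, q)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != FEATURE_LAGS_H.size:
            raise ValueError(f"feature must have length {FEATURE_LAGS_H.size}")


def featurize(
    kernel: SMBasisKernel, source: tuple[str, int] = ("", 0), include_lag0: bool = False
) -> KernelFeature:
    """Temporal features: kernel values at 1 h, 2 h, ..., 72 h lags.

    Lag 0 is identically 1 for every spectral-mixture kernel and is
    excluded by default; ``include_lag0`` shifts the grid to 0..71 h.
    """
    lags = FEATURE_LAGS_H - 1.0 if include_lag0 else FEATURE_LAGS_H
    return KernelFeature(sm_eval(lags, kernel), source)


def cluster_kernels(
    features: list[KernelFeature], Q_max: int, seed: int = 0
) -> tuple[np.ndarray, int]:
    """BIC-selected Gaussian-mixture clustering of kernel features.

    Mixtures with k = 1..Q_max components (each component with its own
    diagonal covariance, 10 restarts, up to 2000 iterations) are
    fitted and the k minimizing BIC wins; assignments are by maximum
    responsibility.  Per-component covariances are diagonal because the
    72-dim features far outnumber the kernels contributed by a
    desk-scale cohort: an unrestricted covariance would carry ~2.7k
    parameters per component, making BIC degenerate at these sample
    sizes.
    """
    if not features:
        raise ValueError("need at least one kernel feature")
    X = np.stack([f.values for f in features])
    n = X.shape[0]
    best_bic, best_gm, best_k = np.inf, None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, Q_max + 1):
            if k > n:
                continue
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=10,
                max_iter=2000,
                reg_covar=1e-6,
                random_state=seed,
            )
            try:
                gm.fit(X)
            except ValueError:
                continue
            bic = gm.bic(X)
            if bic < best_bic:
                best_bic, best_gm, best_k = bic, gm, k
    if best_gm is None:
        raise ValueError("no mixture size was feasible for these features")
    return best_gm.predict(X), best_k


def kde_weighted_mean(values: np.ndarray) -> float:
    """Density-weighted mean: sum w_i x_i / sum w_i with w_i the
    Gaussian-KDE density (Silverman bandwidth) at x_i.  Falls back to
    the arithmetic mean when the sample is degenerate."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 1 or np.ptp(values) < 1e-12:
        return float(values.mean())
    try:
        kde = stats.gaussian_kde(values, bw_method="silverman")
        w = kde(values)
    except np.linalg.LinAlgError:
        return float(values.mean())
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        return float(values.mean())
    return float(np.sum(w * values) / np.sum(w))


def refactor_B(B_agg: np.ndarray, R: int) -> CoregWeights:
    """Low-rank-plus-diagonal refactorization of an aggregated B.

    Eigendecomposition of the symmetrized matrix, eigenvalues floored
    at zero; A takes the top-R scaled eigenvectors and lambda absorbs
    the non-negative diagonal residual, preserving the diagonal of B
    wherever possible.
    """
    D = B_agg.shape[0]
    Bs = 0.5 * (B_agg + B_agg.T)
    evals, evecs = np.linalg.eigh(Bs)
    evals = np.maximum(evals, 0.0)
    order = np.argsort(evals)[::-1][:R]
    A = evecs[:, order] * np.sqrt(evals[order])[None, :]
    if A.shape[1] < R:
        A = np.hstack([A, np.zeros((D, R - A.shape[1]))])
    lam = np.maximum(np.diag(Bs) - np.diag(A @ A.T), 0.0)
    return CoregWeights(A, lam)


def aggregate_cluster(
    members: list[tuple[str, SMBasisKernel, CoregWeights]], D: int, R: int
) -> tuple[SMBasisKernel, CoregWeights]:
    """Aggregate one cluster's kernels into a population-level kernel.

    Kernels a patient contributes more than once are combined first by
    summing their B matrices (the mixture kernel is additive).  Then mu,
    v and every B entry are aggregated independently by KDE-weighted
    means, and the aggregate B is refactored to A, lambda.
    """
    if not members:
        raise ValueError("cluster has no members")
    by_patient: dict[str, dict] = {}
    for pid, kern, w in members:
        slot = by_patient.setdefault(pid, {"mu": [], "v": [], "B": np.zeros((D, D))})
        slot["mu"].append(kern.mu)
        slot["v"].append(kern.v)
        slot["B"] += build_B(w)
    mus = np.array([np.mean(s["mu"]) for s in by_patient.values()])
    vs = np.array([np.mean(s["v"]) for s in by_patient.values()])
    Bs = np.stack([s["B"] for s in by_patient.values()])

    # degenerate cases: a single contributor, or unanimous members —
    # return the common kernel and weights untouched (no refactoring)
    if len(by_patient) == 1 or (
        np.ptp(mus) < 1e-14
        and np.ptp(vs) < 1e-14
        and np.max(np.abs(Bs - Bs[0])) < 1e-14
    ):
        kern = SMBasisKernel(float(mus[0]), float(vs[0]))
        per_patient_counts = {pid for pid, _, _ in members}
        if len(members) == len(per_patient_counts):
            w0 = members[0][2]
            return kern, CoregWeights(w0.A.copy(), w0.lam.copy())
        return kern, refactor_B(Bs[0], R)

    mu_agg = max(kde_weighted_mean(mus), 0.0)
    v_agg = max(kde_weighted_mean(vs), 1e-12)
    B_agg = np.zeros((D, D))
    for i in range(D):
        for j in range(i, D):
            B_agg[i, j] = B_agg[j, i] = kde_weighted_mean(Bs[:, i, j])
    return SMBasisKernel(mu_agg, v_agg), refactor_B(B_agg, R)


def grid_kde_argmax(values_per_param: list[np.ndarray], n_grid: int = 32) -> list[float]:
    """Grid-search aggregation used for the univariate-GP variant:
    maximize the product of per-parameter KDE densities over a
    log-spaced grid (32 points per axis spanning each parameter's
    observed range)."""
    grids, kdes = [], []
    for vals in values_per_param:
        vals = np.asarray(vals, float).ravel()
        vals = vals[vals > 0]
        if vals.size == 0:
            grids.append(np.array([1e-6]))
            kdes.append(None)
            continue
        lo, hi = vals.min(), vals.max()
        if hi / max(lo, 1e-300) < 1.0 + 1e-9:
            grids.append(np.array([lo]))
            kdes.append(None)
            continue
        grids.append(np.geomspace(lo, hi, n_grid))
        kdes.append(stats.gaussian_kde(vals, bw_method="silverman"))
    # independent axes: the product is maximized axis by axis
    out = []
    for g, k in zip(grids, kdes):
        if k is None or g.size == 1:
            out.append(float(g[0]))
        else:
            out.append(float(g[np.argmax(k(g))]))
    return out


@dataclass
class PopulationPrior:
    """Clustered, aggregated kernels shared by a patient group.

    coverage[c] is the fraction of patients contributing at least one
    non-zero-weight kernel to cluster c.  norm_mean / norm_sd are the
    training cohort's per-covariate standardization statistics, applied
    to new patients at prediction time.
    """

    basis: list[SMBasisKernel]
    weights: list[CoregWeights]
    noise_var: np.ndarray
    covariate_names: list[str]
    coverage: np.ndarray
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    @property
    def Q_prime(self) -> int:
        return len(self.basis)

    @property
    def D(self) -> int:
        return len(self.covariate_names)

    def to_model(self) -> MedGPModel:
        return MedGPModel(
            [SMBasisKernel(k.mu, k.v) for k in self.basis],
            [CoregWeights(w.A.copy(), w.lam.copy()) for w in self.weights],
            self.noise_var.copy(),
            list(self.covariate_names),
        )

    def to_json(self, path) -> None:
        d = self.to_model().to_dict()
        d["Q_prime"] = self.Q_prime
        d["coverage"] = self.coverage.tolist()
        if self.norm_mean is not None:
            d["norm_mean"] = self.norm_mean.tolist()
            d["norm_sd"] = self.norm_sd.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PopulationPrior":
        with open(path) as fh:
            d = json.load(fh)
        m = MedGPModel.from_dict(d)
        return cls(
            m.basis,
            m.weights,
            m.noise_var,
            m.covariate_names,
            np.array(d.get("coverage", [1.0] * m.Q)),
            np.array(d["norm_mean"]) if "norm_mean" in d else None,
            np.array(d["norm_sd"]) if "norm_sd" in d else None,
        )


def build_population_prior(
    results: list[FitResult],
    Q_max: int | None = None,
    seed: int = 0,
    near_zero: float = NEAR_ZERO,
    include_lag0: bool = False,
) -> PopulationPrior:
    """Cluster and aggregate per-patient fitted kernels into a prior.

    Kernels whose weight matrix is entirely near zero (every |B| entry
    <= ``near_zero``) are dropped before clustering; clusters are
    ordered by descending length scale for stable reporting.
    """
    if len(results) < 1:
        raise ValueError("need at least one fitted model")
    D = results[0].model.D
    Q = results[0].model.Q
    if Q_max is None:
        Q_max = Q

    feats: list[KernelFeature] = []
    members: list[tuple[str, SMBasisKernel, CoregWeights]] = []
    for res in results:
        m = res.model
        if m.D != D:
            raise ValueError("all models must share the covariate set")
        for q in range(m.Q):
            B = m.B(q)
            if np.max(np.abs(B)) <= near_zero:
                continue
            feats.append(featurize(m.basis[q], (res.patient_id, q), include_lag0))
            members.append((res.patient_id, m.basis[q], m.weights[q]))
    if not feats:
        raise ValueError(
            "every kernel was filtered as near-zero; disable filtering "
            "(near_zero=0) or refit"
        )

    assignments, Q_prime = cluster_kernels(feats, Q_max, seed)

    R = results[0].model.weights[0].R
    basis, weights, coverage = [], [], []
    n_patients = len({res.patient_id for res in results})
    for c in range(Q_prime):
        idx = np.flatnonzero(assignments == c)
        cluster_members = [members[i] for i in idx]
        kern, w = aggregate_cluster(cluster_members, D, R)
        basis.append(kern)
        weights.append(w)
        coverage.append(len({m[0] for m in cluster_members}) / max(n_patients, 1))

    order = np.argsort([-v_to_lengthscale(max(k.v, 1e-300)) for k in basis])
    basis = [basis[i] for i in order]
    weights = [weights[i] for i in order]
    coverage = np.array(coverage)[order]

    noise = np.mean([res.model.noise_var for res in results], axis=0)
    nm = ns = None
    if all(res.norm_mean is not None for res in results):
        nm = np.mean([res.norm_mean for res in results], axis=0)
        ns = np.mean([res.norm_sd for res in results], axis=0)
    return PopulationPrior(
        basis,
        weights,
        noise,
        list(results[0].model.covariate_names),
        coverage,
        nm,
        ns,
    )
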