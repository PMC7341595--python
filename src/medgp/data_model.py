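"""Patient time-series containers and long-format table I/O.

A patient's record is a set of irregularly sampled covariate series
(vitals, labs) indexed by hours since admission.  Observation times are
unaligned across covariates and across patients.  The whole package
consumes the flattened layout: per-covariate blocks concatenated in a
fixed covariate order, so that entry ``t`` of the flattened vectors
belongs to covariate ``cov_index[t]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatientSeries",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "flatten",
    "unflatten",
]

REQUIRED_COLUMNS = ("patient_id", "covariate", "time_hours", "value")


@dataclass
class PatientSeries:
    """One patient's irregular observations across D covariates.

    Parameters
    ----------
    patient_id : str
        Unique identifier within a cohort.
    covariate_names : list of str
        Ordered covariate list; defines the covariate index d = 0..D-1
        used by the block-structured multi-output kernel.
    times : list of ndarray
        Per-covariate observation times in hours since admission,
        sorted non-decreasing, non-negative.
    values : list of ndarray
        Per-covariate observed values, same lengths as ``times``.
    """

    patient_id: str
    covariate_names: list[str]
    times: list[np.ndarray]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        D = len(self.covariate_names)
        if len(self.times) != D or len(self.values) != D:
            raise ValueError(
                f"times/values must have one entry per covariate (D={D})"
            )
        self.times = [np.asarray(t, dtype=float).ravel() for t in self.times]
        self.values = [np.asarray(v, dtype=float).ravel() for v in self.values]
        for d, (t, v) in enumerate(zip(self.times, self.values)):
            if t.shape != v.shape:
                raise ValueError(
                    f"covariate {self.covariate_names[d]!r}: "
                    f"{t.size} times but {v.size} values"
                )
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(
                    f"covariate {self.covariate_names[d]!r}: times not sorted"
                )
            if t.size and t.min() < 0:
                raise ValueError(
                    f"covariate {self.covariate_names[d]!r}: negative time"
                )

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_obs(self) -> int:
        """Total flattened length T_i = sum_d T_{i,d}."""
        return int(sum(t.size for t in self.times))

    def counts(self) -> np.ndarray:
        """Per-covariate observation counts T_{i,d}."""
        return np.array([t.size for t in self.times], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.covariate_names == other.covariate_names
            and all(np.array_equal(a, b) for a, b in zip(self.times, other.times))
            and all(np.array_equal(a, b) for a, b in zip(self.values, other.values))
        )


@dataclass
class Cohort:
    """A set of patients sharing one covariate ordering."""

    patients: list[PatientSeries] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        for p in self.patients:
            if p.covariate_names != self.covariate_names:
                raise ValueError(
                    f"patient {p.patient_id!r} covariate ordering differs "
                    "from the cohort's"
                )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.covariate_names == other.covariate_names
            and self.patients == other.patients
        )

    def __iter__(self):
        return iter(self.patients)


def flatten(patient: PatientSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate per-covariate blocks in covariate order.

    Returns
    -------
    x : ndarray, shape (T_i,)
        Flattened observation times.
    y : ndarray, shape (T_i,)
        Flattened observed values.
    cov_index : ndarray of int, shape (T_i,)
        Covariate index (0-based) of each flattened entry.
    """
    x = np.concatenate(patient.times) if patient.n_obs else np.empty(0)
    y = np.concatenate(patient.values) if patient.n_obs else np.empty(0)
    cov_index = np.repeat(np.arange(patient.n_covariates), patient.counts())
    return x, y, cov_index


def unflatten(
    x: np.ndarray,
    y: np.ndarray,
    cov_index: np.ndarray,
    covariate_names: list[str],
    patient_id: str = "",
) -> PatientSeries:
    """Inverse of :func:`flatten` for block-ordered inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov_index = np.asarray(cov_index, dtype=int)
    times = [x[cov_index == d] for d in range(len(covariate_names))]
    values = [y[cov_index == d] for d in range(len(covariate_names))]
    return PatientSeries(patient_id, list(covariate_names), times, values)


def read_cohort(
    path,
    covariates: list[str] | None = None,
    delimiter: str | None = None,
    value_ranges: dict[str, tuple[float, float]] | None = None,
) -> Cohort:
    """Read a long-format delimited table into a :class:`Cohort`.

    The table must have header columns ``patient_id``, ``covariate``,
    ``time_hours``, ``value``.  Rows are grouped by patient and
    covariate; times are sorted ascending within each covariate.

    Parameters
    ----------
    covariates : list of str, optional
        Restrict to (and order by) these covariate names.  A requested
        covariate absent for a patient yields an empty series.  When
        omitted, covariates are taken in order of first appearance.
    delimiter : str, optional
        Field delimiter; auto-detected (comma vs tab) when omitted.
    value_ranges : dict, optional
        Per-covariate plausible [min, max]; rows outside their
        covariate's range are dropped as artifacts.  Disabled by
        default.
    """
    if delimiter is None:
        # sniff comma vs tab from the header line, then parse with the
        # c engine so floats round-trip exactly
        if hasattr(path, "read"):
            head = path.readline()
            path.seek(0)
        else:
            with open(path) as fh:
                head = fh.readline()
        delimiter = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing required column(s): {missing}")

    for col in ("time_hours", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"non-numeric {col!r} at data row {row}")
        df[col] = coerced
    if df["time_hours"].lt(0).any():
        row = int(df["time_hours"].lt(0).idxmax())
        raise ValueError(f"negative time_hours at data row {row}")

    if value_ranges:
        keep = np.ones(len(df), dtype=bool)
        cov_col = df["covariate"].astype(str).to_numpy()
        vals = df["value"].to_numpy()
        for name, (lo, hi) in value_ranges.items():
            mask = cov_col == name
            keep &= ~mask | ((vals >= lo) & (vals <= hi))
        df = df[keep]

    if covariates is None:
        covariates = list(dict.fromkeys(df["covariate"].astype(str)))
    else:
        covariates = list(covariates)
        df = df[df["covariate"].astype(str).isin(covariates)]

    patients = []
    for pid, g in df.groupby("patient_id", sort=False):
        times, values = [], []
        for name in covariates:
            gc = g[g["covariate"].astype(str) == name]
            order = np.argsort(gc["time_hours"].to_numpy(), kind="stable")
            times.append(gc["time_hours"].to_numpy()[order])
            values.append(gc["value"].to_numpy()[order])
        patients.append(PatientSeries(str(pid), covariates, times, values))
    return Cohort(patients, covariates)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> str:
    """Write a cohort to the long format accepted by :func:`read_cohort`."""
    rows = []
    for p in cohort.patients:
        for name, t, v in zip(p.covariate_names, p.times, p.values):
            for ti, vi in zip(t, v):
                rows.append((p.patient_id, name, ti, vi))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False)
    return str(path)
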