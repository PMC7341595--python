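"""Metrics, baselines and paired comparisons."""

import numpy as np
import pandas as pd
import pytest

from medgp.data_model import PatientSeries
from medgp.evaluation import (
    compare,
    coverage95,
    crossvalidate,
    mae,
    naive_one_lag,
    univariate_gp_baseline,
)
from medgp.inference import FitConfig
from medgp.online import OnlineConfig, OnlineTrace
from medgp.synthetic import SimConfig, default_truth, simulate_cohort


def _trace(rows):
    return OnlineTrace(
        pd.DataFrame(
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
    )


class TestMetrics:
    def test_mae_perfect_and_hand_case(self):
        t = _trace(
            [("p", 1.0, "a", 1.0, 2.0, 1.0, True), ("p", 2.0, "a", 3.0, 2.0, 1.0, True)]
        )
        assert mae(t, "a") == pytest.approx(1.0)
        perfect = _trace([("p", 1.0, "a", 5.0, 5.0, 1.0, True)])
        assert mae(perfect, "a") == 0.0
        assert np.isnan(mae(perfect, "missing"))

    def test_mae_matches_recompute_oracle(self, rng):
        obs = rng.normal(size=30)
        pred = rng.normal(size=30)
        rows = [("p", float(i), "a", o, m, 1.0, True) for i, (o, m) in enumerate(zip(obs, pred))]
        assert mae(_trace(rows), "a") == pytest.approx(float(np.abs(obs - pred).mean()))

    def test_coverage_hand_cases(self):
        rows = [("p", float(i), "a", 0.0, 0.0, 1.0, True) for i in range(3)]
        rows.append(("p", 3.0, "a", 10.0, 0.0, 1.0, False))  # far outside
        t = _trace(rows)
        assert coverage95(t, "a") == pytest.approx(75.0)
        all_in = _trace(rows[:3])
        assert coverage95(all_in, "a") == pytest.approx(100.0)


class TestNaiveBaseline:
    def test_constant_series_has_zero_mae(self):
        p = PatientSeries("p", ["a"], [np.array([1.0, 2.0, 3.0])], [np.full(3, 7.0)])
        t = naive_one_lag(p, "a")
        assert mae(t, "a") == 0.0

    def test_hand_arithmetic(self):
        p = PatientSeries("p", ["a"], [np.array([1.0, 2.0, 3.0])], [np.array([1.0, 2.0, 4.0])])
        t = naive_one_lag(p, "a")
        assert t.records["pred_mean"].tolist() == [1.0, 2.0]
        assert mae(t, "a") == pytest.approx(1.5)

    def test_matches_shift_by_one_oracle(self, rng):
        v = rng.normal(size=20)
        p = PatientSeries("p", ["a"], [np.arange(20.0)], [v])
        t = naive_one_lag(p, "a")
        assert np.allclose(t.records["pred_mean"].to_numpy(), v[:-1])
        assert np.allclose(t.records["observed"].to_numpy(), v[1:])

    def test_short_series_gives_empty_trace(self):
        p = PatientSeries("p", ["a"], [np.array([1.0])], [np.array([5.0])])
        assert naive_one_lag(p, "a").records.empty


class TestCompare:
    def test_identical_traces_zero_improvement(self):
        rows = [("p", float(i), "a", float(i), float(i) + 0.5, 1.0, True) for i in range(10)]
        rep = compare({"m": _trace(rows), "b": _trace(rows)}, "m", ["b"])
        row = rep.table.iloc[0]
        assert row["improvement_pct"] == pytest.approx(0.0)
        assert row["p_value"] == 1.0
        assert not row["significant"]

    def test_planted_uniform_error_reduction(self, rng):
        obs = rng.normal(size=100)
        err = np.abs(rng.normal(size=100)) + 0.5
        base_rows = [
            ("p", float(i), "a", o, o + e, 1.0, True)
            for i, (o, e) in enumerate(zip(obs, err))
        ]
        med_rows = [
            ("p", float(i), "a", o, o + 0.5 * e, 1.0, True)
            for i, (o, e) in enumerate(zip(obs, err))
        ]
        rep = compare({"m": _trace(med_rows), "b": _trace(base_rows)}, "m", ["b"], n_covariates=1)
        row = rep.table.iloc[0]
        assert row["improvement_pct"] == pytest.approx(50.0, rel=1e-9)
        assert row["significant"]

    def test_bonferroni_thresholds_match_printed_values(self):
        """alpha/D reproduces the corrected thresholds: 4.17e-4 for the
        24-covariate panel and 0.005 for a two-covariate model."""
        rows = [("p", 0.0, "a", 1.0, 1.0, 1.0, True)]
        traces = {"m": _trace(rows), "b": _trace(rows)}
        rep24 = compare(traces, "m", ["b"], n_covariates=24)
        assert rep24.threshold == pytest.approx(4.17e-4, rel=1e-2)
        rep2 = compare(traces, "m", ["b"], n_covariates=2)
        assert rep2.threshold == pytest.approx(0.005, rel=1e-9)

    def test_mismatched_events_raise(self):
        rows = [("p", float(i), "a", 1.0, 1.0, 1.0, True) for i in range(4)]
        t1 = _trace(rows)
        t2 = _trace(rows[:-1])
        with pytest.raises(ValueError, match="event sets differ"):
            compare({"m": t1, "b": t2}, "m", ["b"])
        rep = compare({"m": t1, "b": t2}, "m", ["b"], allow_subset=True)
        assert rep.table.iloc[0]["n_events"] == 3


@pytest.fixture(scope="module")
def tiny_cohort():
    truth = default_truth(scenario="two_correlated")
    cfg = SimConfig(
        n_patients=6,
        truth=truth,
        stay_range_h=(100, 140),
        sampling_gap_h=np.array([8.0, 8.0]),
        seed=21,
    )
    cohort, _ = simulate_cohort(cfg)
    return cohort


class TestUnivariateBaseline:
    def test_deterministic_under_seed(self, tiny_cohort):
        p = tiny_cohort.patients[0]
        cfg = FitConfig(Q=1, R=1, n_init=10, max_iters=3, seed=5)
        t1 = univariate_gp_baseline(p, "PT", "SM", cfg)
        t2 = univariate_gp_baseline(p, "PT", "SM", cfg)
        assert np.allclose(
            t1.records["pred_mean"].to_numpy(), t2.records["pred_mean"].to_numpy()
        )

    def test_se_restriction_fixes_frequency_at_zero(self, tiny_cohort):
        p = tiny_cohort.patients[0]
        cfg = FitConfig(Q=1, R=1, n_init=10, max_iters=3, seed=5)
        t = univariate_gp_baseline(p, "PT", "SE", cfg, online_cfg=OnlineConfig(update=False))
        assert len(t.records) == p.times[0].size

    def test_rejects_unknown_kernel_type(self, tiny_cohort):
        with pytest.raises(ValueError):
            univariate_gp_baseline(tiny_cohort.patients[0], "PT", "RBF")


class TestCrossvalidate:
    def test_partition_and_determinism(self, tiny_cohort):
        cfg = FitConfig(Q=1, R=1, n_init=5, max_iters=2, inner_maxiter=5, seed=1,
                        use_sparse_prior=False)
        ocfg = OnlineConfig(update=False)
        rep1 = crossvalidate(tiny_cohort, cfg, k=2, seed=3, online_cfg=ocfg)
        rep2 = crossvalidate(tiny_cohort, cfg, k=2, seed=3, online_cfg=ocfg)
        # every patient's events appear exactly once in the method trace
        assert rep1.table["mae_method"].tolist() == rep2.table["mae_method"].tolist()
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(tiny_cohort, cfg, k=99, seed=0)


class TestUnivariateBaselineScience:
    def test_sm_beats_se_on_strongly_periodic_data(self):
        """Model mismatch: the squared-exponential restriction loses to
        the spectral-mixture kernel on circadian data in >= 9/10 seeds."""
        from medgp.kernels import (
            CoregWeights,
            MedGPModel,
            SMBasisKernel,
            lengthscale_to_v,
            period_to_mu,
        )

        truth = MedGPModel(
            [SMBasisKernel(period_to_mu(24.0), lengthscale_to_v(300.0))],
            [CoregWeights(np.array([[1.0]]), [0.0])],
            np.array([0.05]),
            ["x"],
        )
        wins = 0
        for seed in range(10):
            c, _ = simulate_cohort(
                SimConfig(
                    n_patients=1,
                    truth=truth,
                    stay_range_h=(150, 200),
                    sampling_gap_h=np.array([4.0]),
                    seed=seed,
                )
            )
            p = c.patients[0]
            cfg = FitConfig(
                Q=1, R=1, n_init=50, max_iters=8, inner_maxiter=20,
                seed=seed, use_sparse_prior=False, standardize=False,
            )
            t_se = univariate_gp_baseline(p, "x", "SE", cfg)
            t_sm = univariate_gp_baseline(p, "x", "SM", cfg)
            wins += mae(t_se, "x") > mae(t_sm, "x")
        assert wins >= 9

    def test_equivalence_with_joint_model_at_d1(self, tiny_cohort):
        """With a single covariate the univariate baseline and the joint
        model share the model class; their online MAE agrees within 5%."""
        from medgp.data_model import PatientSeries
        from medgp.inference import fit_patient
        from medgp.online import run_online
        from medgp.population import PopulationPrior

        p = tiny_cohort.patients[1]
        sub = PatientSeries(p.patient_id, ["PT"], [p.times[0]], [p.values[0]])
        cfg = FitConfig(Q=1, R=1, n_init=30, max_iters=6, seed=9)
        base = univariate_gp_baseline(p, "PT", "SM", cfg,
                                      online_cfg=OnlineConfig(update=False))
        res = fit_patient(sub, cfg)
        prior = PopulationPrior(
            res.model.basis, res.model.weights, res.model.noise_var,
            ["PT"], np.ones(1), res.norm_mean, res.norm_sd,
        )
        joint = run_online(sub, prior, OnlineConfig(update=False))
        m_b, m_j = mae(base, "PT"), mae(joint, "PT")
        assert abs(m_b - m_j) / m_j < 0.05
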