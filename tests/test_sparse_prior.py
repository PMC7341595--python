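"""Hierarchical gamma shrinkage prior: densities and MAP updates."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from medgp.kernels import CoregWeights, MedGPModel, SMBasisKernel
from medgp.sparse_prior import PriorConfig, PriorState, log_prior, map_update_scales


def _model_with(A_list, lam_list, names=None):
    Q = len(A_list)
    D = A_list[0].shape[0]
    basis = [SMBasisKernel(0.01 * (q + 1), 0.001) for q in range(Q)]
    weights = [CoregWeights(A_list[q], lam_list[q]) for q in range(Q)]
    names = names or [f"c{d}" for d in range(D)]
    return MedGPModel(basis, weights, np.full(D, 0.1), names)


def _random_instance(rng, Q=2, D=3, R=2):
    A = [rng.normal(scale=0.7, size=(D, R)) for _ in range(Q)]
    lam = [rng.uniform(0.01, 0.5, size=D) for _ in range(Q)]
    model = _model_with(A, lam)
    state = PriorState(
        rng.uniform(0.2, 2.0, (Q, D, R)),
        rng.uniform(0.2, 2.0, (Q, D, R)),
        rng.uniform(0.2, 2.0, (Q, R)),
        rng.uniform(0.2, 2.0, (Q, R)),
    )
    return model, state


# independent term-by-term density formulas (not the implementation path)
def _gamma_lpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def _oracle_log_prior(model, state, cfg):
    total = 0.0
    for q, w in enumerate(model.weights):
        D, R = w.A.shape
        for d in range(D):
            for r in range(R):
                psi = state.psi[q, d, r]
                total += -0.5 * np.log(2 * np.pi * psi) - w.A[d, r] ** 2 / (2 * psi)
                total += _gamma_lpdf(psi, cfg.alpha, state.delta[q, d, r])
                total += _gamma_lpdf(
                    state.delta[q, d, r], cfg.beta, state.phi[q, r]
                )
        for r in range(R):
            total += _gamma_lpdf(state.phi[q, r], cfg.gamma, state.tau[q, r])
            total += _gamma_lpdf(state.tau[q, r], cfg.xi, cfg.eta)
        for d in range(D):
            total += -np.log(cfg.beta_lambda) - w.lam[d] / cfg.beta_lambda
    return total


def test_log_prior_matches_term_by_term_oracle(rng):
    cfg = PriorConfig(eta=1.0)
    for _ in range(5):
        model, state = _random_instance(rng)
        assert log_prior(model, state, cfg) == pytest.approx(
            _oracle_log_prior(model, state, cfg), rel=1e-10
        )


def test_log_prior_decreases_when_weight_doubles(rng):
    cfg = PriorConfig()
    model, state = _random_instance(rng)
    lp0 = log_prior(model, state, cfg)
    model.weights[0].A[0, 0] *= 2.0
    assert log_prior(model, state, cfg) < lp0


def test_laplace_term_on_lambda():
    cfg = PriorConfig(beta_lambda=0.01)
    A = [np.zeros((2, 2))]
    m0 = _model_with(A, [np.array([0.0, 0.0])])
    m1 = _model_with(A, [np.array([0.5, 0.0])])
    state = PriorState.ones(1, 2, 2)
    assert log_prior(m0, state, cfg) - log_prior(m1, state, cfg) == pytest.approx(50.0)


class TestMapUpdates:
    def test_psi_update_matches_numeric_argmax(self, rng):
        """Each updated psi maximizes its 1-D conditional log-density."""
        cfg = PriorConfig(eta=0.5)
        for _ in range(20):
            model, state = _random_instance(rng)
            new = map_update_scales(model, state, cfg)
            q, d, r = (
                rng.integers(0, 2),
                rng.integers(0, 3),
                rng.integers(0, 2),
            )
            a = model.weights[q].A[d, r]
            delta = state.delta[q, d, r]  # psi is updated against current delta

            def neg_cond(log_psi):
                psi = np.exp(log_psi)
                return -(
                    (cfg.alpha - 1.5) * np.log(psi) - delta * psi - a**2 / (2 * psi)
                )

            res = minimize_scalar(neg_cond, bounds=(-30, 10), method="bounded",
                                  options={"xatol": 1e-12})
            assert new.psi[q, d, r] == pytest.approx(np.exp(res.x), rel=1e-6)

    def test_gamma_conditionals_match_numeric_argmax_when_mode_exists(self, rng):
        """With shapes > 1 every gamma conditional's update is its mode."""
        cfg = PriorConfig(alpha=2.0, beta=1.5, gamma=1.2, xi=0.8, eta=0.5)
        model, state = _random_instance(rng)
        new = map_update_scales(model, state, cfg)
        D = 3
        q, d, r = 1, 2, 0

        def argmax(neg):
            res = minimize_scalar(neg, bounds=(-30, 10), method="bounded",
                                  options={"xatol": 1e-12})
            return np.exp(res.x)

        # delta | psi_new, phi_old ~ Gamma(alpha+beta, psi+phi)
        rate = new.psi[q, d, r] + state.phi[q, r]
        got = argmax(lambda t: -((cfg.alpha + cfg.beta - 1) * t - rate * np.exp(t)))
        assert new.delta[q, d, r] == pytest.approx(got, rel=1e-6)
        # phi | delta_new (D of them), tau_old
        rate = new.delta[q, :, r].sum() + state.tau[q, r]
        shape = D * cfg.beta + cfg.gamma
        got = argmax(lambda t: -((shape - 1) * t - rate * np.exp(t)))
        assert new.phi[q, r] == pytest.approx(got, rel=1e-6)
        # tau | phi_new, eta
        rate = new.phi[q, r] + cfg.eta
        got = argmax(lambda t: -((cfg.gamma + cfg.xi - 1) * t - rate * np.exp(t)))
        assert new.tau[q, r] == pytest.approx(got, rel=1e-6)

    def test_mean_fallback_for_unit_shape_conditionals(self, rng):
        """alpha = beta = 0.5 puts the delta conditional at shape 1, whose
        mode sits on the boundary; the conditional mean is used instead."""
        cfg = PriorConfig()
        model, state = _random_instance(rng)
        new = map_update_scales(model, state, cfg)
        expected = 1.0 / (new.psi + state.phi[:, None, :])
        assert np.allclose(new.delta, expected, rtol=1e-12)

    def test_symmetric_columns_stay_symmetric(self):
        cfg = PriorConfig()
        A = np.array([[0.4, 0.4], [-0.2, -0.2], [0.7, 0.7]])
        model = _model_with([A], [np.full(3, 0.1)])
        state = PriorState.ones(1, 3, 2)
        new = map_update_scales(model, state, cfg)
        assert np.allclose(new.psi[0, :, 0], new.psi[0, :, 1])
        assert np.allclose(new.delta[0, :, 0], new.delta[0, :, 1])
        assert new.phi[0, 0] == pytest.approx(new.phi[0, 1])
        assert new.tau[0, 0] == pytest.approx(new.tau[0, 1])

    def test_repeated_sweeps_are_coordinate_ascent(self, rng):
        """Iterating the scale updates does not decrease the joint scale
        log-density once past the first sweep."""
        cfg = PriorConfig(alpha=2.0, beta=1.5, gamma=1.2, xi=0.8, eta=0.5)
        for _ in range(5):
            model, state = _random_instance(rng)
            prev = None
            for _ in range(6):
                state = map_update_scales(model, state, cfg)
                cur = log_prior(model, state, cfg)
                if prev is not None:
                    assert cur >= prev - 1e-9
                prev = cur

    def test_larger_eta_loosens_global_shrinkage(self, rng):
        """Raising the global rate eta lowers the updated tau, which
        chains into larger local variances psi (weaker shrinkage)."""
        model, state0 = _random_instance(rng)
        taus, psis = [], []
        for eta in (0.01, 0.1, 1.0):
            cfg = PriorConfig(eta=eta)
            new = map_update_scales(model, state0.copy(), cfg)
            taus.append(new.tau.mean())
            state = state0.copy()
            for _ in range(5):
                state = map_update_scales(model, state, cfg)
            psis.append(state.psi.mean())
        assert taus[0] >= taus[1] >= taus[2]
        assert psis[0] <= psis[1] <= psis[2]


def test_generative_chain_is_heavy_tailed_and_zero_peaked(rng):
    """Draws from the gamma-Gaussian chain (shapes 0.5) behave like a
    horseshoe: far heavier tails and more mass near zero than a
    Gaussian with the same sample scale."""
    n = 40000
    tau = rng.gamma(0.5, 1.0, size=n)
    phi = rng.gamma(0.5, 1.0 / tau)
    delta = rng.gamma(0.5, 1.0 / phi)
    psi = rng.gamma(0.5, 1.0 / delta)
    a = rng.normal(0.0, np.sqrt(psi))
    s = a.std()
    z = a / s
    excess_kurtosis = np.mean(z**4) - 3.0
    assert excess_kurtosis > 10.0
    near_zero = np.mean(np.abs(a) < 0.05 * s)
    gauss_near_zero = np.mean(np.abs(rng.normal(size=n)) < 0.05)
    assert near_zero > 3.0 * gauss_near_zero


def test_prior_state_validation():
    with pytest.raises(ValueError, match="positive"):
        PriorState(np.zeros((1, 2, 2)), np.ones((1, 2, 2)), np.ones((1, 2)), np.ones((1, 2)))
    with pytest.raises(ValueError):
        PriorConfig(eta=-1.0)
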