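"""X-learner algebra: stage-2 imputations, the propensity-weighted
combination, and exact agreement with a brute-force hand computation."""

import numpy as np
import pytest

from tests.conftest import statics_only_cohort
from txlearn.models import FunctionRiskModel, make_risk_model
from txlearn.xlearner import (
    ITEResult,
    XLearnerConfig,
    estimate_ate,
    estimate_ite,
    fit_xlearner,
    impute_effects,
)


class FrozenRegressor:
    """Effect surface / propensity returning a fixed function of statics."""

    def __init__(self, fn):
        self.fn = fn

    def fit(self, enc, target):
        return self

    def predict(self, enc):
        return np.array([self.fn(x) for x in enc.static_features], dtype=float)


class TestStageTwo:
    def test_treated_imputation(self):
        d1, _ = impute_effects(
            np.array([1]), np.array([1]), np.array([0.3]), np.array([])
        )
        assert d1[0] == pytest.approx(0.7)

    def test_control_imputation(self):
        _, d0 = impute_effects(
            np.array([0]), np.array([0]), np.array([]), np.array([0.45])
        )
        assert d0[0] == pytest.approx(0.45)

    def test_vectorised_imputations(self):
        y = np.array([1, 0, 0, 1, 0])
        t = np.array([1, 1, 0, 0, 0])
        mu0_on_treated = np.array([0.3, 0.2])
        mu1_on_controls = np.array([0.5, 0.6, 0.1])
        d1, d0 = impute_effects(y, t, mu0_on_treated, mu1_on_controls)
        np.testing.assert_allclose(d1, [0.7, -0.2])
        np.testing.assert_allclose(d0, [0.5, -0.4, 0.1])


class TestCombination:
    def _ite(self, g, tau0, tau1):
        return ITEResult(
            np.arange(len(g)), np.clip(np.asarray(g) * tau0 + (1 - np.asarray(g)) * tau1, -1, 1),
            np.asarray(g, float), np.asarray(tau0, float), np.asarray(tau1, float),
        )

    def test_convex_combination(self):
        assert 0.5 * 0.2 + 0.5 * 0.4 == pytest.approx(0.3)

    def test_endpoint_weights_and_constancy_through_estimator(self):
        statics = np.eye(3, dtype=np.float32)
        enc = statics_only_cohort(statics)
        xl_kwargs = dict(
            drug="X",
            mu0=None, mu1=None,
            config=XLearnerConfig(),
        )
        from txlearn.xlearner import XLearner

        # g=1 -> tau0; g=0 -> tau1
        xl = XLearner(
            tau0=FrozenRegressor(lambda x: 0.2),
            tau1=FrozenRegressor(lambda x: 0.4),
            propensity=FrozenRegressor(lambda x: float(x[0])),
            **xl_kwargs,
        )
        ite = estimate_ite(xl, enc)
        assert ite.tau_hat[0] == pytest.approx(0.2)  # g=1
        assert ite.tau_hat[1] == pytest.approx(0.4)  # g=0
        assert ite.tau_hat[2] == pytest.approx(0.4)  # g=0
        # clipping at epsilon keeps g inside (0, 1); with unclipped surfaces
        xl2 = XLearner(
            tau0=FrozenRegressor(lambda x: 0.7),
            tau1=FrozenRegressor(lambda x: 0.7),
            propensity=FrozenRegressor(lambda x: float(x[1]) * 0.5 + 0.25),
            **xl_kwargs,
        )
        np.testing.assert_allclose(estimate_ite(xl2, enc).tau_hat, 0.7)

    def test_ate_is_arithmetic_mean(self):
        ite = self._ite([0.5, 0.5, 0.5], np.array([0.1, -0.3, 0.2]),
                        np.array([0.1, -0.3, 0.2]))
        ate = estimate_ate(ite)
        assert ate.ate == pytest.approx(0.0)
        assert ate.n == 3

    def test_all_equal_ites_have_zero_sd(self):
        ite = self._ite([0.2] * 4, np.array([0.15] * 4), np.array([0.15] * 4))
        ate = estimate_ate(ite)
        assert ate.ate == pytest.approx(0.15)
        assert ate.sd == 0.0

    def test_empty_population_rejected(self):
        ite = self._ite([], np.array([]), np.array([]))
        with pytest.raises(ValueError):
            estimate_ate(ite)

    def test_unknown_weighting_rejected(self):
        ite = self._ite([0.5], np.array([0.1]), np.array([0.1]))
        with pytest.raises(ValueError):
            estimate_ate(ite, weighting="inverse")


def hand_xlearner(statics, t, y, mu0_fn, mu1_fn, tau_of_d, g_fn, clip=0.01):
    """Brute-force per-patient computation of the full X-learner algebra
    with frozen surfaces: the oracle the estimator must match exactly."""
    tau_hats = []
    d1 = [y[i] - mu0_fn(statics[i]) for i in range(len(t)) if t[i] == 1]
    d0 = [mu1_fn(statics[i]) - y[i] for i in range(len(t)) if t[i] == 0]
    for x in statics:
        g = min(max(g_fn(x), clip), 1 - clip)
        tau0 = tau_of_d(x, d0)
        tau1 = tau_of_d(x, d1)
        tau_hats.append(g * tau0 + (1 - g) * tau1)
    return np.array(tau_hats), np.array(d1), np.array(d0)


class TestOracleEquivalence:
    def test_frozen_surface_algebra_matches_hand_computation(self):
        statics = np.array(
            [[0.1, 1, 0], [0.9, 0, 1], [0.4, 1, 1],
             [0.6, 0, 0], [0.25, 1, 0], [0.75, 0, 1]],
            dtype=np.float32,
        )
        t = np.array([1, 1, 1, 0, 0, 0])
        y = np.array([1, 0, 1, 0, 1, 0])
        enc = statics_only_cohort(statics)

        mu0_fn = lambda x: 0.2 + 0.3 * float(x[0])
        mu1_fn = lambda x: 0.1 + 0.5 * float(x[0])
        g_fn = lambda x: float(x[0])

        def tau_of_d(x, d_values):
            # frozen "regressor": mean of imputed effects plus a tilt in x
            return float(np.mean(d_values)) + 0.1 * float(x[0])

        # fit through the real code path with frozen sub-models
        mu_factories = iter([
            FunctionRiskModel(lambda e: mu0_fn(e.static_features[0])),
            FunctionRiskModel(lambda e: mu1_fn(e.static_features[0])),
        ])

        class FrozenTau:
            def __init__(self):
                self.d = None

            def fit(self, enc_sub, d):
                self.d = np.asarray(d, float)
                return self

            def predict(self, enc_sub):
                return np.array(
                    [float(np.mean(self.d)) + 0.1 * float(x[0])
                     for x in enc_sub.static_features]
                )

        xl = fit_xlearner(
            enc, t, y,
            base_model_factory=lambda: next(mu_factories),
            config=XLearnerConfig(min_arm_size=1),
            drug="X",
            tau_regressor_factory=FrozenTau,
            propensity_factory=lambda: FrozenRegressor(g_fn),
        )
        expected_tau, expected_d1, expected_d0 = hand_xlearner(
            statics, t, y, mu0_fn, mu1_fn,
            lambda x, d: float(np.mean(d)) + 0.1 * float(x[0]), g_fn,
        )
        np.testing.assert_allclose(xl.imputed_d1, expected_d1, rtol=1e-6)
        np.testing.assert_allclose(xl.imputed_d0, expected_d0, rtol=1e-6)
        ite = estimate_ite(xl, enc)
        np.testing.assert_allclose(ite.tau_hat, expected_tau, rtol=1e-6)
        ate = estimate_ate(ite)
        assert ate.ate == pytest.approx(float(expected_tau.mean()))


class TestFitGuards:
    def test_small_arm_aborts(self):
        statics = np.random.default_rng(0).normal(size=(30, 3)).astype(np.float32)
        enc = statics_only_cohort(statics)
        t = np.zeros(30, dtype=int)
        t[:2] = 1
        y = np.random.default_rng(1).integers(0, 2, 30)
        with pytest.raises(ValueError, match="min_arm_size"):
            fit_xlearner(enc, t, y, lambda: make_risk_model("logistic"),
                         XLearnerConfig(min_arm_size=5))

    def test_single_class_arm_aborts(self):
        statics = np.random.default_rng(0).normal(size=(40, 3)).astype(np.float32)
        enc = statics_only_cohort(statics)
        t = np.array([1] * 20 + [0] * 20)
        y = np.array([1] * 20 + [0, 1] * 10)  # treated arm single-class
        with pytest.raises(ValueError, match="single class"):
            fit_xlearner(enc, t, y, lambda: make_risk_model("logistic"),
                         XLearnerConfig(min_arm_size=5))

    def test_tau_hat_is_bounded(self):
        rng = np.random.default_rng(5)
        statics = rng.normal(size=(200, 3)).astype(np.float32)
        enc = statics_only_cohort(statics)
        t = rng.integers(0, 2, 200)
        y = rng.integers(0, 2, 200)
        xl = fit_xlearner(enc, t, y, lambda: make_risk_model("logistic"),
                          XLearnerConfig(min_arm_size=5, seed=0))
        tau = estimate_ite(xl, enc).tau_hat
        assert np.all((tau >= -1) & (tau <= 1))
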