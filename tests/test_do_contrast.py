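import numpy as np
import pytest
from scipy.special import expit

from sleepdmpm.do_contrast import (
    AR1_BEST,
    OUTCOME_TARGETS,
    ar1_effect,
    category_effect,
    contrast_analysis,
    exact_ar1,
    exact_contrast,
    item_contrast,
    outcome_key,
)
from sleepdmpm.dmpm_core import CHANNELS
from sleepdmpm.panel_data import (
    COVARIATE_ORDER,
    attach_endpoints,
    default_covariate_specs,
)
from sleepdmpm.synthetic_data import GeneratorConfig, generate_panel, null_params

from conftest import single_draw_posterior


def _spec(name, low=None, high=None):
    spec = next(s for s in default_covariate_specs() if s.name == name)
    if low is not None:
        spec = spec.with_endpoints(low, high)
    return spec


def _params_with_beta(channel, cov, beta):
    params = null_params()
    params.channels[channel].beta_x[COVARIATE_ORDER.index(cov)] = beta
    return params


class TestStaticClosedForm:
    def test_logistic_one_step_difference(self, tiny_panel):
        """No lags, intercept 0, unit coefficient, endpoints (0,1): the
        contrast is |logistic(0) - logistic(1)| for every day."""
        panel, _ = tiny_panel
        params = _params_with_beta("y1", "ict", 1.0)
        item = _spec("ict", 0.0, 1.0)
        expected = abs(expit(0.0) - expit(1.0))  # 0.23105857...
        assert exact_contrast(params, panel, item, ("y1", 1)) == pytest.approx(
            expected, abs=1e-12
        )
        mc = item_contrast(single_draw_posterior(params), panel, item, ("y1", 1),
                           n_rep=4000, seed=3)
        se = np.sqrt(0.5 / (panel.n_subjects * 4000))
        assert abs(mc[0] - expected) < 3 * se


class TestExactOracle:
    def test_zero_coefficient_item_is_exactly_zero(self, tiny_panel):
        panel, params = tiny_panel
        item = _spec("sbp", 110.0, 140.0)
        assert all(params.channels[c].beta_x[COVARIATE_ORDER.index("sbp")] == 0
                   for c in CHANNELS)
        for out in OUTCOME_TARGETS:
            assert exact_contrast(params, panel, item, out) == 0.0

    def test_monte_carlo_agrees_with_enumeration(self, tiny_panel):
        panel, params = tiny_panel
        specs = attach_endpoints(panel, default_covariate_specs())
        draws = single_draw_posterior(params)
        n_rep = 5000
        se = np.sqrt(0.5 / (panel.n_subjects * n_rep))
        for name in ("bedtime_hr", "alcohol"):
            item = next(s for s in specs if s.name == name)
            for out in OUTCOME_TARGETS:
                ex = exact_contrast(params, panel, item, out)
                mc = item_contrast(draws, panel, item, out, n_rep=n_rep, seed=13)[0]
                assert abs(mc - ex) < 3 * se, (name, out, mc, ex)

    def test_t2_reduces_to_one_step_difference(self):
        """With T=2 the exact contrast is a hand-computable single-step
        difference of channel probabilities (no propagation)."""
        panel, _ = generate_panel(GeneratorConfig(n_subjects=1, n_days=2, seed=9))
        params = _params_with_beta("y1", "bmi", 0.1)
        item = _spec("bmi", 20.0, 25.0)
        got = exact_contrast(params, panel, item, ("y1", 1))
        assert got == pytest.approx(abs(expit(0.1 * 20) - expit(0.1 * 25)), abs=1e-12)

    def test_monotone_in_coefficient_magnitude(self, tiny_panel):
        """Single-channel case with 0/1 endpoints: a larger coefficient
        magnitude never shrinks the exact contrast (the low endpoint pins
        one probability at 1/2, so saturation cannot reverse the order)."""
        panel, _ = tiny_panel
        item = _spec("ict", 0.0, 1.0)
        vals = [
            exact_contrast(_params_with_beta("y1", "ict", b), panel, item, ("y1", 1))
            for b in (0.0, 0.05, 0.2, 1.0, 3.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_instance_size_guard(self):
        panel, params = generate_panel(GeneratorConfig(n_subjects=8, n_days=3, seed=1))
        item = _spec("bmi", 21.0, 25.0)
        with pytest.raises(ValueError, match="enumeration"):
            exact_contrast(params, panel, item, ("y1", 1))


class TestItemContrast:
    def test_degenerate_endpoints_give_zero_with_warning(self, tiny_panel):
        panel, params = tiny_panel
        item = _spec("sunshine_hr", 5.0, 5.0)
        with pytest.warns(UserWarning, match="degenerate"):
            s = item_contrast(single_draw_posterior(params), panel, item,
                              ("y1", 1), n_rep=10, seed=0)
        assert (s == 0).all()

    def test_unknown_item_is_key_error(self, tiny_panel):
        panel, params = tiny_panel
        from sleepdmpm.panel_data import CovariateSpec

        ghost = CovariateSpec("ghost", "dietary", False,
                              shift_low=0.0, shift_high=1.0)
        with pytest.raises(KeyError):
            item_contrast(single_draw_posterior(params), panel, ghost, ("y1", 1),
                          n_rep=5, seed=0)

    def test_bad_outcome_rejected(self, tiny_panel):
        panel, params = tiny_panel
        with pytest.raises(ValueError):
            item_contrast(single_draw_posterior(params), panel,
                          _spec("bmi", 20.0, 25.0), ("y2", 2), n_rep=5, seed=0)

    def test_seed_invariance_of_estimates(self, tiny_panel):
        panel, params = tiny_panel
        item = _spec("bedtime_hr", -1.0, 1.0)
        draws = single_draw_posterior(params)
        n_rep = 3000
        a = item_contrast(draws, panel, item, ("y1", 1), n_rep=n_rep, seed=1)[0]
        b = item_contrast(draws, panel, item, ("y1", 1), n_rep=n_rep, seed=2)[0]
        se = np.sqrt(0.5 / (panel.n_subjects * n_rep))
        assert abs(a - b) < 3 * np.sqrt(2) * se


class TestCategoryEffect:
    def test_single_item_identity(self):
        s = np.array([0.1, 0.2, 0.3])
        samples, summary = category_effect({"only": s})
        np.testing.assert_array_equal(samples, s)
        assert summary["posterior_mean"] == pytest.approx(0.2)

    def test_constant_additivity(self):
        samples, _ = category_effect({"a": np.full(5, 0.02), "b": np.full(5, 0.03)})
        np.testing.assert_allclose(samples, 0.05)

    def test_interval_is_5th_95th_percentile(self):
        rng = np.random.default_rng(0)
        s = {"a": rng.random(500), "b": rng.random(500)}
        samples, summary = category_effect(s)
        assert summary["ci_low"] == pytest.approx(np.quantile(samples, 0.05))
        assert summary["ci_high"] == pytest.approx(np.quantile(samples, 0.95))

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError):
            category_effect({})


class TestAR1:
    def test_zero_lag_coefficients_give_zero(self, tiny_panel):
        panel, _ = tiny_panel
        params = null_params()
        for out in (("y1", 1), ("y2", 3)):
            assert exact_ar1(params, panel, out) == 0.0
        s = ar1_effect(single_draw_posterior(params), panel, ("y1", 1),
                       n_rep=500, seed=1)
        assert abs(s[0]) < 3 * np.sqrt(0.5 / (panel.n_subjects * 500))

    def test_positive_persistence_gives_positive_effect(self, tiny_panel):
        panel, params = tiny_panel
        for out in OUTCOME_TARGETS:
            assert exact_ar1(params, panel, out) > 0

    def test_identical_clamps_cancel(self, tiny_panel):
        panel, params = tiny_panel
        from sleepdmpm.dmpm_core import simulate_forward
        from sleepdmpm.do_contrast import _panel_sim_inputs

        initial, cov_path = _panel_sim_inputs(panel)
        a = simulate_forward(params, initial, cov_path, n_rep=50, seed=4,
                             lag_outcome_clamp=AR1_BEST)
        b = simulate_forward(params, initial, cov_path, n_rep=50, seed=4,
                             lag_outcome_clamp=dict(AR1_BEST))
        for c in CHANNELS:
            np.testing.assert_array_equal(a[c], b[c])


class TestFullAnalysis:
    @pytest.fixture(scope="class")
    def result(self, small_panel, small_fit):
        panel, _ = small_panel
        return contrast_analysis(small_fit, panel, n_rep=20, seed=2, thin_to=40)

    def test_drawwise_additivity(self, result):
        for okey, cats in result.per_category.items():
            for cat, samples in cats.items():
                items = [s for name, s in result.per_item[okey].items()
                         if result.item_category[name] == cat]
                np.testing.assert_array_equal(samples, np.sum(items, axis=0))

    def test_bounds(self, result):
        for okey in result.per_item:
            for s in result.per_item[okey].values():
                assert (s >= 0).all() and (s <= 1).all()
            for s in result.ar1.values():
                assert (s >= 0).all() and (s <= 1).all()

    def test_caffeine_override_endpoints(self, small_panel):
        panel, _ = small_panel
        specs = attach_endpoints(panel, default_covariate_specs())
        caffeine = next(s for s in specs if s.name == "caffeine")
        assert (caffeine.shift_low, caffeine.shift_high) == (0.0, 1.0)

    def test_summary_frame_layout(self, result):
        df = result.summary_frame()
        assert set(df["outcome"]) == {outcome_key(*o) for o in OUTCOME_TARGETS}
        # 35 item rows + 6 category rows + 1 ar1 row per outcome
        assert len(df) == 5 * (35 + 6 + 1)
        assert (df["ci_low"] <= df["posterior_mean"] + 1e-12).all()
        assert (df["posterior_mean"] <= df["ci_high"] + 1e-12).all()
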