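"""Parameter estimation: recovery, goodness of fit, model comparison."""

import numpy as np
import pytest

from instabean.fitting import (
    RehydrationCurve,
    compare_models,
    estimate_rehydration_time,
    fit_global_arrhenius,
    fit_single_curve,
    fit_two_step_arrhenius,
    goodness_of_fit,
)
from instabean.models import BoundaryMoistures, DegenerateRangeError, InvalidInputError
from instabean.simulate import RehydrationSimSpec, gen_rehydration_dataset

M_O, M_E = 11.0, 150.0


def _one_curve(model_name, params, e_a=0.0, noise=0.0, seed=0, **kw):
    spec = RehydrationSimSpec(
        model_name=model_name, true_params=params, e_a=e_a,
        temperatures=(353.15,), m_o=M_O, m_e=M_E, noise_sd=noise, seed=seed, **kw
    )
    return gen_rehydration_dataset(spec)[0]


class TestSingleCurve:
    @pytest.mark.parametrize(
        "model,gen_model,params,expected",
        [
            ("weibull", "weibull", {"alpha_ref": 4.52, "beta": 0.6},
             {"alpha": 4.52, "beta": 0.6}),
            ("peleg", "peleg", {"k1_ref": 0.02, "k2": 1.0 / (M_E - M_O)},
             {"k1": 0.02, "k2": 1.0 / (M_E - M_O)}),
            ("first_order", "first_order", {"h_ref": 0.15}, {"h": 0.15}),
            ("exponential", "exponential", {"k_ref": 0.25, "n": 0.7},
             {"k": 0.25, "n": 0.7}),
        ],
    )
    def test_exact_recovery_on_noiseless_data(self, model, gen_model, params, expected,
                                              true_bounds):
        curve = _one_curve(gen_model, params)
        fit = fit_single_curve(curve, model, bounds=true_bounds)
        for name, value in expected.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_fick_recovery_of_geometric_factor(self, true_bounds):
        curve = _one_curve(
            "fick_slab", {"d_ref": 6.53e-8, "g": 6.53, "half_thickness": 0.005}
        )
        fit = fit_single_curve(curve, "fick", bounds=true_bounds, half_thickness=0.005)
        assert fit.params["g"] == pytest.approx(6.53, rel=1e-5)
        assert fit.params["d_eff"] == pytest.approx(6.53e-8, rel=1e-5)

    def test_refit_on_own_predictions_is_fixed_point(self, true_bounds):
        curve = _one_curve("weibull", {"alpha_ref": 4.52, "beta": 0.6})
        fit = fit_single_curve(curve, "weibull", bounds=true_bounds)
        moistures = M_O + fit.predicted * (M_E - M_O)
        refit_curve = RehydrationCurve(
            sample_id="refit", drying_method="VD", temperature=353.15,
            times=curve.times, dry_mass=curve.dry_mass, moistures=moistures,
        )
        refit = fit_single_curve(refit_curve, "weibull", bounds=true_bounds)
        assert refit.params["alpha"] == pytest.approx(fit.params["alpha"], rel=1e-6)
        assert refit.params["beta"] == pytest.approx(fit.params["beta"], rel=1e-6)

    def test_small_noise_gives_small_alpha_bias(self, true_bounds):
        errs = []
        for s in range(100):
            curve = _one_curve("weibull", {"alpha_ref": 4.52, "beta": 0.6},
                               noise=0.01 * (M_E - M_O), seed=1000 + s)
            fit = fit_single_curve(curve, "weibull", bounds=true_bounds)
            errs.append(fit.params["alpha"] / 4.52 - 1.0)
        assert abs(np.mean(errs)) < 0.02

    def test_bias_vanishes_as_noise_shrinks(self, true_bounds):
        mean_abs = []
        for noise_rr in (0.05, 0.01, 0.001):
            errs = []
            for s in range(20):
                curve = _one_curve("weibull", {"alpha_ref": 4.52, "beta": 0.6},
                                   noise=noise_rr * (M_E - M_O), seed=500 + s)
                fit = fit_single_curve(curve, "weibull", bounds=true_bounds)
                errs.append(fit.params["alpha"] / 4.52 - 1.0)
            mean_abs.append(abs(np.mean(errs)))
        assert mean_abs[2] < mean_abs[0]
        assert mean_abs[2] < 0.005

    def test_degenerate_constant_curve_rejected(self):
        curve = RehydrationCurve(
            sample_id="flat", drying_method="AD", temperature=353.15,
            times=np.array([0.0, 10.0, 20.0, 30.0]), dry_mass=9.0,
            moistures=np.full(4, 50.0),
        )
        with pytest.raises(DegenerateRangeError):
            fit_single_curve(curve, "weibull")

    def test_unknown_model_and_missing_thickness(self, weibull_curves):
        with pytest.raises(InvalidInputError):
            fit_single_curve(weibull_curves[0], "parabolic")
        with pytest.raises(InvalidInputError):
            fit_single_curve(weibull_curves[0], "fick")

    def test_time_unit_rescaling_rescales_rate(self, true_bounds):
        curve = _one_curve("first_order", {"h_ref": 0.15})
        fit_min = fit_single_curve(curve, "first_order", bounds=true_bounds)
        curve_h = RehydrationCurve(
            sample_id="hours", drying_method="VD", temperature=353.15,
            times=curve.times / 60.0, dry_mass=curve.dry_mass,
            moistures=curve.moistures,
        )
        fit_h = fit_single_curve(curve_h, "first_order", bounds=true_bounds)
        assert fit_h.params["h"] == pytest.approx(60.0 * fit_min.params["h"], rel=1e-5)


class TestGlobalArrhenius:
    def test_exact_ea_recovery_noiseless(self, weibull_curves, true_bounds):
        g = fit_global_arrhenius(weibull_curves, "weibull", bounds=true_bounds)
        assert g.e_a == pytest.approx(14.0, rel=1e-4)
        assert g.k_ref == pytest.approx(4.52, rel=1e-4)
        assert g.extras["beta"] == pytest.approx(0.6, rel=1e-4)

    def test_rate_at_reference_equals_k_ref(self, weibull_curves, true_bounds):
        g = fit_global_arrhenius(weibull_curves, "weibull", bounds=true_bounds)
        assert g.rate_at(g.t_ref) == pytest.approx(g.k_ref)

    def test_single_step_matches_two_step_noiseless(self, weibull_curves, true_bounds):
        g = fit_global_arrhenius(weibull_curves, "weibull", bounds=true_bounds)
        two = fit_two_step_arrhenius(weibull_curves, "weibull")
        assert g.e_a == pytest.approx(two.e_a, rel=1e-4)
        assert g.k_ref == pytest.approx(two.k_ref, rel=1e-3)

    def test_zero_activation_energy_gives_equal_rates(self, true_bounds):
        spec = RehydrationSimSpec(
            model_name="weibull", true_params={"alpha_ref": 4.52, "beta": 0.6},
            e_a=0.0, m_o=M_O, m_e=M_E, noise_sd=0.0, seed=3,
        )
        curves = gen_rehydration_dataset(spec)
        two = fit_two_step_arrhenius(curves, "weibull")
        rates = np.array(list(two.rates.values()))
        assert np.ptp(rates) / rates.mean() < 1e-6
        g = fit_global_arrhenius(curves, "weibull", bounds=true_bounds)
        assert abs(g.e_a) < 1e-4

    def test_fick_global_recovery(self, true_bounds):
        spec = RehydrationSimSpec(
            model_name="fick_slab",
            true_params={"d_ref": 6.53e-8, "g": 6.53, "half_thickness": 0.005},
            e_a=14.70, m_o=M_O, m_e=M_E, noise_sd=0.0, seed=4,
        )
        curves = gen_rehydration_dataset(spec)
        g = fit_global_arrhenius(curves, "fick", half_thickness=0.005, bounds=true_bounds)
        assert g.k_ref == pytest.approx(6.53e-8, rel=1e-4)
        assert g.e_a == pytest.approx(14.70, rel=1e-4)
        assert g.extras["g"] == pytest.approx(6.53, rel=1e-4)

    def test_confidence_interval_coverage(self, true_bounds):
        true_ea = 14.0
        hits = 0
        for s in range(50):
            spec = RehydrationSimSpec(
                model_name="weibull", true_params={"alpha_ref": 4.52, "beta": 0.6},
                e_a=true_ea, m_o=M_O, m_e=M_E, noise_sd=0.01 * (M_E - M_O), seed=s,
            )
            g = fit_global_arrhenius(gen_rehydration_dataset(spec), "weibull",
                                     bounds=true_bounds)
            hits += abs(g.e_a - true_ea) <= 1.96 * g.e_a_se
        assert 0.88 <= hits / 50 <= 0.99

    def test_single_temperature_rejected(self, weibull_curves):
        with pytest.raises(InvalidInputError, match="fit_single_curve"):
            fit_global_arrhenius([weibull_curves[0]], "weibull")

    def test_mixed_methods_rejected(self, weibull_curves):
        other = RehydrationCurve(
            sample_id="x", drying_method="FD",
            temperature=weibull_curves[1].temperature,
            times=weibull_curves[1].times, dry_mass=9.0,
            moistures=weibull_curves[1].moistures,
        )
        with pytest.raises(InvalidInputError, match="mix"):
            fit_global_arrhenius([weibull_curves[0], other], "weibull")


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        obs = np.array([0.0, 0.5, 1.0])
        r2, rmse, chi2 = goodness_of_fit(obs, obs, 1)
        assert (r2, rmse, chi2) == (1.0, 0.0, 0.0)

    def test_zero_r_squared_when_sse_equals_sst(self):
        r2, _, _ = goodness_of_fit([0.0, 1.0], [0.5, 0.5], 0)
        assert r2 == pytest.approx(0.0)

    def test_constant_shift_gives_rmse_of_shift(self):
        obs = np.linspace(0, 1, 10)
        _, rmse, _ = goodness_of_fit(obs, obs + 0.07, 1)
        assert rmse == pytest.approx(0.07)

    def test_chi2_uses_residual_dof(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        pred = obs + 1.0
        _, _, chi2 = goodness_of_fit(obs, pred, 2)
        assert chi2 == pytest.approx(4.0 / 2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateRangeError):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 1.1, 0.9], 1)


class TestRehydrationTime:
    def test_rule_on_worked_sequence(self):
        curve = RehydrationCurve(
            sample_id="s", drying_method="AD", temperature=353.15,
            times=np.array([0.0, 60.0, 120.0, 180.0]), dry_mass=9.0,
            weights=np.array([10.0, 12.0, 12.04, 12.06]),
        )
        rt = estimate_rehydration_time(curve)
        assert rt.time_min == 120.0 and rt.saturated

    def test_constant_weights_saturated_from_start(self):
        curve = RehydrationCurve(
            sample_id="s", drying_method="AD", temperature=353.15,
            times=np.array([0.0, 60.0, 120.0]), dry_mass=9.0,
            weights=np.array([12.0, 12.0, 12.0]),
        )
        rt = estimate_rehydration_time(curve)
        assert rt.time_min == 0.0 and rt.saturated

    def test_fast_growing_curve_flagged_not_saturated(self):
        curve = RehydrationCurve(
            sample_id="s", drying_method="AD", temperature=353.15,
            times=np.array([0.0, 60.0, 120.0]), dry_mass=9.0,
            weights=np.array([10.0, 12.0, 14.0]),
        )
        rt = estimate_rehydration_time(curve)
        assert rt.time_min == 120.0 and not rt.saturated


class TestCompareModels:
    def test_best_fit_ranks_first(self, weibull_curves, true_bounds):
        curve = weibull_curves[0]
        fits = [
            fit_single_curve(curve, m, bounds=true_bounds)
            for m in ("weibull", "first_order")
        ]
        table = compare_models(fits)
        assert table.iloc[0]["model"] == "weibull"
        assert table.iloc[0]["r_squared"] > table.iloc[1]["r_squared"]

    def test_weibull_and_exponential_reparameterization_tie(self, weibull_curves,
                                                            true_bounds):
        curve = weibull_curves[0]
        fits = [
            fit_single_curve(curve, m, bounds=true_bounds)
            for m in ("weibull", "exponential")
        ]
        table = compare_models(fits).set_index("model")
        assert table.loc["weibull", "r_squared"] == pytest.approx(
            table.loc["exponential", "r_squared"], abs=1e-9
        )
        assert table.loc["weibull", "rmse"] == pytest.approx(
            table.loc["exponential", "rmse"], abs=1e-9
        )

    def test_mismatched_data_rejected(self, weibull_curves, true_bounds):
        f1 = fit_single_curve(weibull_curves[0], "weibull", bounds=true_bounds)
        f2 = fit_single_curve(weibull_curves[1], "weibull", bounds=true_bounds)
        with pytest.raises(InvalidInputError):
            compare_models([f1, f2])
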