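"""Tests of the dichotomous dose-response models and BMD machinery."""

import numpy as np
import pytest

from fiprisk.doseresponse import (
    FIPRONIL_CONVULSION,
    MODELS,
    DoseResponseData,
    bmd_from_params,
    bmd_numeric,
    compute_model_weights,
    fit_dichotomous_model,
    make_models,
    model_average_bmd,
    model_probability,
)
from fiprisk.mcmc import McmcSettings


class TestData:
    def test_validation(self):
        with pytest.raises(ValueError):
            DoseResponseData(np.array([0.1, 1.0]), np.array([50, 50]), np.array([0, 1]))
        with pytest.raises(ValueError):
            DoseResponseData(np.array([0.0, 1.0]), np.array([50, 50]), np.array([0, 51]))
        with pytest.raises(ValueError):
            DoseResponseData(np.array([0.0, 1.0, 1.0]), np.array([50] * 3), np.array([0, 1, 2]))


class TestModelProbability:
    def test_zero_slope_quantal_linear_is_background(self):
        assert model_probability("QuantalLinear", [0.1, 0.0], 3.0) == pytest.approx(0.1)

    def test_logistic_at_origin_is_half(self):
        assert model_probability("Logistic", [0.0, 0.0], 5.0) == pytest.approx(0.5)

    def test_multistage_closed_form(self):
        # g=0, b1=1, b2=0 gives p(d) = 1 - exp(-d); at d = ln 2 that is 1/2
        assert model_probability("Multistage2", [0.0, 1.0, 0.0], np.log(2)) == pytest.approx(0.5)

    def test_background_at_zero_dose(self):
        assert model_probability("LogLogistic", [0.07, -2.0, 1.5], 0.0) == pytest.approx(0.07)
        assert model_probability("DichotomousHill", [0.2, 0.5, -1.0, 1.5], 0.0) == pytest.approx(0.1)

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError):
            model_probability("QuantalLinear", [1.5, 1.0], 1.0)


class TestBmdClosedForms:
    def test_quantal_linear_independent_of_background(self):
        assert bmd_from_params("QuantalLinear", [0.0, 1.0]) == pytest.approx(-np.log(0.9))
        assert bmd_from_params("QuantalLinear", [0.3, 1.0]) == pytest.approx(0.10536, abs=1e-5)

    def test_quantal_linear_scales_with_slope(self):
        assert bmd_from_params("QuantalLinear", [0.2, 2.0]) == pytest.approx(0.05268, abs=1e-5)

    def test_weibull_square_root_form(self):
        assert bmd_from_params("Weibull", [0.0, 1.0, 2.0]) == pytest.approx(
            np.sqrt(-np.log(0.9)), rel=1e-10
        )

    def test_flat_curve_raises(self):
        with pytest.raises(ValueError):
            bmd_from_params("QuantalLinear", [0.1, 0.0])

    @pytest.mark.parametrize("name", list(MODELS))
    def test_inversion_recovers_bmr(self, name, rng):
        """Plugging the BMD back into the extra-risk formula returns 10%."""
        model = MODELS[name]
        for _ in range(20):
            params = _random_params(model, rng)
            try:
                bmd = bmd_from_params(model, params)
            except ValueError:
                continue
            p0 = model_probability(model, params, 0.0)
            pd_ = model_probability(model, params, bmd)
            assert (pd_ - p0) / (1 - p0) == pytest.approx(0.10, abs=1e-8)

    @pytest.mark.parametrize("name", list(MODELS))
    def test_closed_form_matches_root_finder(self, name, rng):
        model = MODELS[name]
        checked = 0
        while checked < 50:
            params = _random_params(model, rng)
            try:
                closed = bmd_from_params(model, params)
            except ValueError:
                continue
            if closed > 1e7:
                continue
            numeric = bmd_numeric(model, params)
            assert closed == pytest.approx(numeric, rel=1e-8)
            checked += 1


def _random_params(model, rng):
    """Draw a parameter vector from a well-behaved region of the box."""
    out = []
    for name, (lo, hi) in zip(model.param_names, model.bounds):
        if name == "g":
            out.append(rng.uniform(0.0, 0.5))
        elif name == "v":
            out.append(rng.uniform(0.3, 1.0))
        elif name == "a":
            out.append(rng.uniform(-5.0, 1.0))
        elif name == "k":
            out.append(rng.uniform(max(lo, 0.5), 4.0))
        else:
            out.append(rng.uniform(max(lo, 0.05), min(hi, 3.0)))
    return np.array(out)


class TestFits:
    def test_quantal_linear_parameter_recovery(self):
        from fiprisk.synthetic import generate_dose_response

        model = MODELS["QuantalLinear"]
        data = generate_dose_response(
            model, [0.0, 0.5], np.array([0.0, 0.5, 1.0, 2.0, 4.0]), 1000, seed=4
        )
        fit = fit_dichotomous_model(data, model, McmcSettings(n_chains=3, n_iter=8_000, seed=5))
        assert fit.converged
        assert np.median(fit.param_draws[:, 1]) == pytest.approx(0.5, rel=0.10)

    def test_control_rate_covered(self):
        data = DoseResponseData(
            np.array([0.0, 1.0, 2.0]), np.array([100, 100, 100]), np.array([10, 10, 10])
        )
        fit = fit_dichotomous_model(
            data, MODELS["QuantalLinear"], McmcSettings(n_chains=3, n_iter=8_000, seed=6)
        )
        g = fit.param_draws[:, 0]
        lo, hi = np.percentile(g, [2.5, 97.5])
        assert lo < 0.10 < hi

    def test_convulsion_bmd_in_plausible_decade(self, convulsion_fits_small):
        """The fipronil data put the quantal-linear BMD in 1-100 mg/kg/day."""
        med = convulsion_fits_small["QuantalLinear"].bmd_median
        assert 1.0 < med < 100.0

    def test_fitted_curves_nondecreasing(self, convulsion_fits_small):
        grid = np.linspace(0, 12.68, 40)
        for name, fit in convulsion_fits_small.items():
            p = fit.model.prob(fit.param_draws[::500], grid)
            assert np.all(np.diff(p, axis=1) >= -1e-9), name


class TestWeights:
    def test_single_model_gets_unit_weight(self, convulsion_fits_small):
        one = {"Logistic": convulsion_fits_small["Logistic"]}
        assert compute_model_weights(one)["Logistic"] == pytest.approx(1.0)

    def test_identical_models_split_evenly(self, convulsion_fits_small):
        fit = convulsion_fits_small["Probit"]
        w = compute_model_weights({"first": fit, "second": fit})
        assert w["first"] == pytest.approx(0.5, abs=1e-12)

    def test_permutation_invariance(self, convulsion_fits_small):
        w1 = compute_model_weights(convulsion_fits_small)
        reordered = dict(reversed(list(convulsion_fits_small.items())))
        w2 = compute_model_weights(reordered)
        for name in w1:
            assert w1[name] == pytest.approx(w2[name], rel=1e-9)

    def test_simplex(self, convulsion_fits_small):
        for scheme in ("bic", "pseudo_bma"):
            w = compute_model_weights(convulsion_fits_small, scheme)
            assert min(w.values()) >= 0
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_scheme(self, convulsion_fits_small):
        with pytest.raises(ValueError):
            compute_model_weights(convulsion_fits_small, "magic")


class TestModelAverage:
    def test_degenerate_weights_reproduce_single_model(self, convulsion_fits_small):
        names = list(convulsion_fits_small)
        weights = {n: (1.0 if n == "Probit" else 0.0) for n in names}
        avg = model_average_bmd(convulsion_fits_small, weights, n_draws=20_000, seed=3)
        probit = convulsion_fits_small["Probit"].bmd_draws
        probit = probit[np.isfinite(probit) & (probit > 0)]
        assert np.median(avg.averaged_draws) == pytest.approx(np.median(probit), rel=0.02)

    def test_mixture_proportions(self, convulsion_fits_small):
        """With disjoint supports the mixture mass follows the weights."""
        import copy

        lo = copy.copy(convulsion_fits_small["Probit"])
        hi = copy.copy(convulsion_fits_small["Probit"])
        lo.bmd_draws = np.full(1000, 1.0)
        hi.bmd_draws = np.full(1000, 100.0)
        avg = model_average_bmd({"lo": lo, "hi": hi}, {"lo": 0.3, "hi": 0.7}, n_draws=50_000, seed=8)
        assert (avg.averaged_draws < 10).mean() == pytest.approx(0.3, abs=0.01)

    def test_weights_must_be_simplex(self, convulsion_fits_small):
        weights = {n: 1.0 for n in convulsion_fits_small}
        with pytest.raises(ValueError):
            model_average_bmd(convulsion_fits_small, weights)

    def test_protective_percentiles_monotone(self, convulsion_fits_small):
        avg = model_average_bmd(convulsion_fits_small, n_draws=50_000, seed=4)
        t = avg.percentile_table()
        assert t["p99_protective"] <= t["p95_protective"] <= t["p90_protective"] <= t["median"]


class TestRestriction:
    def test_unrestricted_bounds_widen(self):
        restricted = make_models(True)
        free = make_models(False)
        assert restricted["Weibull"].bounds[2][0] == 1.0
        assert free["Weibull"].bounds[2][0] == 0.0
        assert free["LogLogistic"].bounds[2][0] == 0.0
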