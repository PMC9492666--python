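"""Median-effect fitting, dose inversion, CI, IC50 metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synscreen import (DoseResponseSeries, FitError, MedianEffectParams,
                       ModelViolationError, UndefinedDoseError,
                       combination_index, dose_for_fa, fit_median_effect,
                       ic50, ic50_fold_shift, resistance_factor,
                       simulate_combo_matrix, simulate_dose_response)

from oracles import grid_fit_median_effect, loewe_additive_fa, transformed_sse


def _noiseless_series(Dm, m, doses=(0.5, 1, 2, 4, 8)):
    return simulate_dose_response(MedianEffectParams(Dm, m), doses)


class TestFitMedianEffect:
    def test_exact_linearization_recovers_parameters(self):
        fit = fit_median_effect(_noiseless_series(2.0, 1.5))
        assert fit.Dm == pytest.approx(2.0, rel=1e-10)
        assert fit.m == pytest.approx(1.5, rel=1e-10)
        assert fit.r == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("Dm", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("m", [0.5, 1.0, 2.0, 4.0])
    def test_round_trip_grid(self, Dm, m):
        doses = Dm * 2.0 ** np.arange(-2.0, 3.0)
        fit = fit_median_effect(
            DoseResponseSeries("d", doses, MedianEffectParams(Dm, m).fa(doses))
        )
        assert fit.Dm == pytest.approx(Dm, rel=1e-10)
        assert fit.m == pytest.approx(m, rel=1e-10)
        assert fit.r == pytest.approx(1.0, abs=1e-10)

    def test_extreme_fa_points_excluded(self):
        series = DoseResponseSeries(
            "d", [0.01, 0.5, 1, 2, 4, 8, 1000],
            [0.0, 0.2, 1 / 3, 0.5, 2 / 3, 0.8, 1.0],
        )
        fit = fit_median_effect(series)
        assert fit.n_used == 5
        assert fit.n_excluded == 2
        assert fit.Dm == pytest.approx(2.0, rel=1e-9)

    def test_too_few_usable_points(self):
        with pytest.raises(FitError):
            fit_median_effect(DoseResponseSeries("d", [1, 2, 3], [0, 0.5, 1]))

    def test_inverted_dose_response_rejected(self):
        with pytest.raises(ModelViolationError):
            fit_median_effect(
                DoseResponseSeries("d", [1, 2, 4, 8], [0.8, 0.6, 0.4, 0.2])
            )

    def test_noisy_fit_matches_grid_search_oracle(self):
        """OLS fit ties the brute-force grid oracle in transformed SSE."""
        for seed in range(20):
            series = simulate_dose_response(
                MedianEffectParams(2.0, 1.5),
                np.geomspace(0.25, 16, 9),
                noise_sd=0.03,
                seed=seed,
            )
            fit = fit_median_effect(series)
            mask = (series.fa > 0.005) & (series.fa < 0.995)
            d, fa = series.doses[mask], series.fa[mask]
            _, _, oracle_sse = grid_fit_median_effect(d, fa)
            fit_sse = transformed_sse(
                d, fa, fit.m, -fit.m * np.log10(fit.Dm)
            )
            assert fit_sse <= oracle_sse + 1e-6


class TestDoseForFa:
    @pytest.mark.parametrize(
        "Dm,m,fa,expected",
        [(5.0, 1.7, 0.5, 5.0), (2.0, 1.0, 0.8, 8.0), (1.0, 2.0, 0.9, 3.0)],
    )
    def test_closed_form_inversion(self, Dm, m, fa, expected):
        fit = fit_median_effect(_noiseless_series(Dm, m, Dm * 2.0 ** np.arange(-2.0, 3.0)))
        assert dose_for_fa(fit, fa) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("fa", [0.0, 1.0, -0.1, 1.5])
    def test_unreachable_effect_rejected(self, fa):
        fit = fit_median_effect(_noiseless_series(2.0, 1.0))
        with pytest.raises(UndefinedDoseError):
            dose_for_fa(fit, fa)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6))
    def test_strictly_increasing_in_fa(self, fas):
        fit = fit_median_effect(_noiseless_series(2.0, 1.5))
        fas = sorted(set(fas))
        doses = [dose_for_fa(fit, f) for f in fas]
        assert all(a < b for a, b in zip(doses, doses[1:]))


def _fits_from_design(design):
    return (
        fit_median_effect(design.drug_a),
        fit_median_effect(design.drug_b),
        fit_median_effect(design.combo),
    )


class TestCombinationIndex:
    def test_sham_self_combination_is_additive(self):
        p = MedianEffectParams(2.0, 1.5)
        fa_levels = (0.25, 0.5, 0.75)
        fits = _fits_from_design(simulate_combo_matrix(p, p))
        for res in combination_index(*fits, fa_levels=fa_levels):
            assert res.ci == pytest.approx(1.0, abs=1e-10)
            assert res.classification == "additivity"

    @given(p=st.floats(0.05, 0.95))
    def test_sham_identity_at_any_ratio(self, p):
        params = MedianEffectParams(3.0, 2.0)
        fit = fit_median_effect(
            _noiseless_series(3.0, 2.0, 3.0 * 2.0 ** np.arange(-2.0, 3.0))
        )
        for res in combination_index(fit, fit, fit, ratio=(p, 1 - p),
                                     fa_levels=(0.3, 0.5, 0.8)):
            assert res.ci == pytest.approx(1.0, abs=1e-10)

    def test_potency_shift_becomes_ci(self):
        p = MedianEffectParams(2.0, 1.5)
        fits = _fits_from_design(simulate_combo_matrix(p, p, potency_shift=0.5))
        for res in combination_index(*fits, fa_levels=(0.25, 0.5, 0.75)):
            assert res.ci == pytest.approx(0.5, abs=1e-9)
            assert res.classification == "synergism"

    def test_loewe_additive_unequal_potency_gives_ci_one(self):
        """Combo built point-by-point from the Loewe bisection oracle."""
        a, b = (2.0, 1.5), (8.0, 1.5)
        doses = np.geomspace(0.4, 40, 9)
        fa = [loewe_additive_fa(d, (0.5, 0.5), a, b) for d in doses]
        fit_a = fit_median_effect(
            _noiseless_series(*a, 2.0 * 2.0 ** np.arange(-2.0, 3.0))
        )
        fit_b = fit_median_effect(
            _noiseless_series(*b, 8.0 * 2.0 ** np.arange(-2.0, 3.0))
        )
        fit_c = fit_median_effect(DoseResponseSeries("combo", doses, fa))
        for res in combination_index(fit_a, fit_b, fit_c,
                                     fa_levels=(0.25, 0.5, 0.75)):
            assert res.ci == pytest.approx(1.0, abs=1e-6)

    def test_more_potent_combo_lowers_ci(self):
        p = MedianEffectParams(2.0, 1.5)
        cis = []
        for s in (1.0, 0.8, 0.6, 0.4):
            fits = _fits_from_design(simulate_combo_matrix(p, p, potency_shift=s))
            cis.append(combination_index(*fits, fa_levels=(0.5,))[0].ci)
        assert all(a > b for a, b in zip(cis, cis[1:]))

    def test_invalid_ratio_rejected(self):
        fit = fit_median_effect(_noiseless_series(2.0, 1.5))
        with pytest.raises(ValueError):
            combination_index(fit, fit, fit, ratio=(0.6, 0.6))

    def test_antagonism_classified(self):
        p = MedianEffectParams(2.0, 1.5)
        fits = _fits_from_design(simulate_combo_matrix(p, p, potency_shift=2.0))
        res = combination_index(*fits, fa_levels=(0.5,))[0]
        assert res.ci == pytest.approx(2.0, abs=1e-9)
        assert res.classification == "antagonism"


class TestIC50Metrics:
    def test_ic50_is_dm(self):
        fit = fit_median_effect(_noiseless_series(5.0, 2.0, [1, 2.5, 5, 10, 20]))
        assert ic50(fit) == pytest.approx(5.0, rel=1e-10)
        assert ic50(fit) == pytest.approx(dose_for_fa(fit, 0.5), rel=1e-12)

    def test_fold_shift_identity_and_ratio(self):
        f10 = fit_median_effect(_noiseless_series(10.0, 1.5, [2.5, 5, 10, 20, 40]))
        f2 = fit_median_effect(_noiseless_series(2.0, 1.5))
        assert ic50_fold_shift(f10, f10) == pytest.approx(1.0)
        assert ic50_fold_shift(f10, f2) == pytest.approx(5.0, rel=1e-9)

    def test_simulated_sensitization_halving_dm(self):
        """A sensitizer halving Dm is recovered as a ~2x fold shift."""
        ratios = []
        for seed in range(50):
            alone = simulate_dose_response(
                MedianEffectParams(4.0, 1.5), np.geomspace(0.5, 32, 8),
                noise_sd=0.02, seed=seed,
            )
            with_sens = simulate_dose_response(
                MedianEffectParams(2.0, 1.5), np.geomspace(0.25, 16, 8),
                noise_sd=0.02, seed=1000 + seed,
            )
            ratios.append(
                ic50_fold_shift(fit_median_effect(alone),
                                fit_median_effect(with_sens))
            )
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    @pytest.mark.parametrize(
        "ic_tol,ic_par,expected_ratio,expected_flag",
        [(5.0, 5.0, 1.0, False), (50.0, 5.0, 10.0, True),
         (49.95, 5.0, 9.99, False)],
    )
    def test_resistance_factor_threshold(self, ic_tol, ic_par,
                                         expected_ratio, expected_flag):
        from synscreen import MedianEffectFit

        tol = MedianEffectFit("tolerant", Dm=ic_tol, m=1.5, r=1.0, n_used=5)
        par = MedianEffectFit("parental", Dm=ic_par, m=1.5, r=1.0, n_used=5)
        ratio, flag = resistance_factor(tol, par)
        assert ratio == pytest.approx(expected_ratio, rel=1e-9)
        assert flag is expected_flag
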