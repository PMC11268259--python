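"""Release bookkeeping, dissolution, activity ratios and 4PL viability fits."""

import numpy as np
import pytest

from aerosilica import kinetics as kin
from aerosilica import synthetic_data as sd
from aerosilica.kinetics import KineticsError, ReleaseSeries


def series_from(conc, withdrawn=2.0, omega=0.078, sample=10.0, vessel=5.0):
    t = np.arange(1.0, len(conc) + 1)
    w = np.full(len(conc), withdrawn)
    return ReleaseSeries(sample_mass=sample, protein_weight_fraction=omega,
                         vessel_mass=vessel, times=t,
                         concentrations=np.asarray(conc, float),
                         withdrawn=w, replaced=w)


class TestIntervalRelease:
    def test_single_interval_literal_formula(self):
        """ω = C·m/(ω_lys·m_sample) for one sampling point."""
        s = series_from([0.0546])
        res = kin.interval_release(s, mode="as_printed")
        assert res.interval_fractions[0] == pytest.approx(0.0546 * 5 / (0.078 * 10))
        assert res.interval_fractions[0] == pytest.approx(0.35)

    def test_zero_concentrations_zero_fractions(self):
        s = series_from([0.0, 0.0, 0.0])
        for mode in ("as_printed", "carryover_corrected"):
            res = kin.interval_release(s, mode=mode)
            assert np.all(res.interval_fractions == 0.0)
            assert np.all(res.cumulative_fractions == 0.0)

    def test_modes_agree_for_single_interval(self):
        s = series_from([0.2])
        a = kin.interval_release(s, "as_printed").cumulative_fractions[-1]
        b = kin.interval_release(s, "carryover_corrected").cumulative_fractions[-1]
        assert a == pytest.approx(b)

    def test_modes_agree_without_withdrawal_in_increments(self):
        """With zero withdrawal the carryover-corrected increments are the
        increments of the literal total-concentration formula."""
        s = series_from([0.1, 0.25, 0.30], withdrawn=0.0)
        lit = kin.interval_release(s, "as_printed").interval_fractions
        cor = kin.interval_release(s, "carryover_corrected").interval_fractions
        assert cor[0] == pytest.approx(lit[0])
        assert np.allclose(np.cumsum(cor), lit)

    def test_carryover_converges_to_generator_plateau(self):
        """Noiseless first-order release with withdrawal/replacement:
        corrected cumulative release ends on the generator plateau."""
        s, truth = sd.gen_release_series(plateau_frac=0.703, rate_per_h=0.25)
        res = kin.interval_release(s, "carryover_corrected")
        assert res.cumulative_fractions[-1] == pytest.approx(
            truth["released_frac_at"][72.0], rel=1e-9)
        assert res.cumulative_fractions[-1] == pytest.approx(0.703, rel=1e-3)

    def test_cumulative_release_at_24h_near_plateau(self):
        s, truth = sd.gen_release_series(plateau_frac=0.703, rate_per_h=0.3)
        res = kin.interval_release(s, "carryover_corrected")
        i24 = list(s.times).index(24.0)
        assert res.cumulative_fractions[i24] == pytest.approx(0.703, abs=0.001)

    def test_cumulative_is_running_sum(self):
        cum = kin.cumulative_release([0.1, 0.2, 0.05])
        assert np.allclose(cum, [0.1, 0.3, 0.35])

    def test_cumulative_nondecreasing_on_noisy_data(self):
        s, _ = sd.gen_release_series(noise=0.05, seed=8)
        res = kin.interval_release(s, "carryover_corrected")
        assert np.all(np.diff(res.cumulative_fractions) >= 0.0)


class TestDissolution:
    def test_full_dissolution_is_100_percent(self):
        d = kin.DissolutionSeries(dose_mg_L=30.0, times=[24.0],
                                  si_mg_L=[30.0 * 0.4674])
        assert kin.si_percent_dissolved(d)[0] == pytest.approx(100.0, rel=1e-4)

    def test_linear_in_concentration(self):
        d1 = kin.DissolutionSeries(30.0, [1.0], [5.0])
        d2 = kin.DissolutionSeries(30.0, [1.0], [10.0])
        assert kin.si_percent_dissolved(d2)[0] == pytest.approx(
            2.0 * kin.si_percent_dissolved(d1)[0])

    def test_generator_reaches_93pct_at_24h(self):
        """The first-order dissolution fixture approaches complete Si
        dissolution (~93%) by 24 h."""
        series, _ = sd.gen_dissolution_series()
        pct = kin.si_percent_dissolved(series)
        i24 = list(series.times).index(24.0)
        assert pct[i24] == pytest.approx(93.0, abs=1.0)

    def test_t50_midpoint_of_line(self):
        assert kin.t50_interpolate([0.0, 8.0], [0.0, 100.0]) == pytest.approx(4.0)

    def test_t50_from_constant_rate(self):
        """A dissolution rate of 8.065 %/h crosses 50% at 6.2 h."""
        t = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        assert kin.t50_interpolate(t, 8.065 * t) == pytest.approx(50 / 8.065, rel=1e-9)
        assert kin.t50_interpolate(t, 8.065 * t) == pytest.approx(6.2, abs=0.01)

    def test_t50_time_unit_invariance(self):
        t_h = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        p = 8.065 * t_h
        t50_h = kin.t50_interpolate(t_h, p)
        t50_min = kin.t50_interpolate(t_h * 60.0, p, window=(0.0, 480.0))
        assert t50_min / 60.0 == pytest.approx(t50_h, rel=1e-9)

    def test_flat_series_errors(self):
        with pytest.raises(KineticsError, match="trend"):
            kin.t50_interpolate([1.0, 4.0, 8.0], [10.0, 10.0, 10.0])


class TestActivity:
    def test_ratios(self):
        assert kin.activity_ratio(1.0, 1.0) == pytest.approx(100.0)
        assert kin.activity_ratio(0.92, 1.0) == pytest.approx(92.0)
        assert kin.activity_ratio(0.70, 1.0) == pytest.approx(70.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(KineticsError):
            kin.activity_ratio(1.0, 0.0)


class TestViability:
    def test_normalization_anchors(self):
        assert kin.normalize_viability(0.8, 0.8, 0.1) == pytest.approx(100.0)
        assert kin.normalize_viability(0.1, 0.8, 0.1) == pytest.approx(0.0)
        assert kin.normalize_viability(0.45, 0.8, 0.1) == pytest.approx(50.0)

    def test_untreated_below_blank_rejected(self):
        with pytest.raises(KineticsError):
            kin.normalize_viability(0.5, 0.1, 0.2)

    def test_noiseless_4pl_exact(self):
        x, y, _ = sd.gen_dose_response(upper=100.0, lower=0.0, inflection=0.5,
                                       hill=2.0)
        fit = kin.fit_4pl(x, y)
        assert fit.upper_asymptote == pytest.approx(100.0, rel=1e-6)
        assert fit.lower_asymptote == pytest.approx(0.0, abs=1e-5)
        assert fit.inflection_concentration == pytest.approx(0.5, rel=1e-6)
        assert fit.hill_slope == pytest.approx(2.0, rel=1e-6)

    def test_noisy_4pl_within_two_stderr(self):
        x, y, _ = sd.gen_dose_response(inflection=0.5, hill=2.0,
                                       noise=0.05, seed=3)
        fit = kin.fit_4pl(x, y)
        assert abs(fit.inflection_concentration - 0.5) <= 2.0 * fit.stderr["c"]

    def test_flat_viability_flags_ic50_beyond_range(self):
        """Viability held near 100% across 0.0078-1.0 mg/mL: no IC50 in range."""
        x, y, _ = sd.gen_dose_response(inflection=50.0, noise=0.02, seed=3)
        fit = kin.fit_4pl(x, y)
        assert fit.ic50_beyond_range
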