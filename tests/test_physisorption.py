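"""BET, BJH and pore-metric operations against closed-form and forward-model oracles."""

import numpy as np
import pytest

from aerosilica import physisorption as ph
from aerosilica import synthetic_data as sd
from aerosilica.physisorption import PhysisorptionError, PoreMetrics


class TestBET:
    def test_exact_recovery_from_bet_equation(self):
        """An isotherm generated from the multilayer equation returns the
        generating monolayer capacity and C to machine precision."""
        iso = sd.gen_bet_isotherm(monolayer_capacity=71.68, c_constant=100.0)
        res = ph.bet_surface_area(iso, fit_range=(0.05, 0.30))
        assert res.surface_area == pytest.approx(71.68 * 4.3525, rel=1e-10)
        assert res.surface_area == pytest.approx(312.0, abs=0.05)
        assert res.monolayer_capacity == pytest.approx(71.68, rel=1e-9)
        assert res.bet_constant_C == pytest.approx(100.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("qm,c", [(50.0, 30.0), (120.0, 250.0)])
    def test_roundtrip_across_parameters(self, qm, c):
        iso = sd.gen_bet_isotherm(qm, c)
        res = ph.bet_surface_area(iso)
        assert res.monolayer_capacity == pytest.approx(qm, rel=1e-6)
        assert res.bet_constant_C == pytest.approx(c, rel=1e-6)

    def test_linearity_in_uptake(self):
        """Doubling every uptake doubles the surface area exactly."""
        iso = sd.gen_bet_isotherm(71.68, 100.0)
        double = ph.SorptionIsotherm(iso.p_rel, 2.0 * iso.q_ads, iso.branch)
        r1 = ph.bet_surface_area(iso)
        r2 = ph.bet_surface_area(double)
        assert r2.surface_area == pytest.approx(2.0 * r1.surface_area, rel=1e-12)

    def test_zero_uptake_rejected(self):
        p = np.linspace(0.05, 0.3, 10)
        iso = ph.SorptionIsotherm(p, np.zeros_like(p),
                                  np.array(["ads"] * 10, dtype=object))
        with pytest.raises(PhysisorptionError):
            ph.bet_surface_area(iso)

    def test_too_few_points_in_range(self):
        iso = sd.gen_bet_isotherm(70.0, 100.0, p_grid=np.array([0.01, 0.02, 0.10, 0.34]))
        with pytest.raises(PhysisorptionError, match="insufficient"):
            ph.bet_surface_area(iso, fit_range=(0.05, 0.30))


class TestTotalPoreVolume:
    def test_plateau_conversion(self):
        """452.5 cm³ STP/g of gas at the plateau is 0.70 cm³/g of liquid."""
        p = np.array([0.1, 0.5, 0.9, 0.99])
        q = np.array([100.0, 300.0, 440.0, 452.5])
        iso = ph.SorptionIsotherm(p, q, np.array(["ads"] * 4, dtype=object))
        assert ph.total_pore_volume(iso) == pytest.approx(0.6999, abs=5e-4)

    def test_truncated_isotherm_errors(self):
        p = np.array([0.1, 0.5, 0.95])
        iso = ph.SorptionIsotherm(p, np.array([1.0, 2.0, 3.0]),
                                  np.array(["ads"] * 3, dtype=object))
        with pytest.raises(PhysisorptionError, match="threshold"):
            ph.total_pore_volume(iso)

    def test_zero_uptake_gives_zero_volume(self):
        p = np.array([0.1, 0.5, 0.99])
        iso = ph.SorptionIsotherm(p, np.zeros(3), np.array(["ads"] * 3, dtype=object))
        assert ph.total_pore_volume(iso) == 0.0


class TestBJH:
    @pytest.mark.parametrize("median", [40.0, 60.0, 80.0, 100.0, 120.0])
    def test_forward_model_roundtrip(self, median):
        """BJH on a Kelvin+film forward isotherm recovers the generating
        distribution: mode within 10%, total volume within 5%."""
        iso, truth = sd.gen_isotherm(median_diameter_A=median, seed=1)
        psd = ph.bjh_distribution(iso)
        assert psd.modal_diameter == pytest.approx(truth["modal_diameter_A"], rel=0.10)
        assert psd.total_volume == pytest.approx(truth["total_volume"], rel=0.05)

    def test_recovered_mode_monotone_in_generator_mode(self):
        modes = []
        for median in (40.0, 60.0, 80.0, 100.0, 120.0):
            iso, _ = sd.gen_isotherm(median_diameter_A=median, seed=1)
            modes.append(ph.bjh_distribution(iso).modal_diameter)
        assert np.all(np.diff(modes) > 0)

    def test_total_pore_volume_bounds_bjh_volume(self):
        iso, _ = sd.gen_isotherm(median_diameter_A=80.0)
        assert ph.total_pore_volume(iso) >= ph.bjh_distribution(iso).total_volume

    def test_film_only_isotherm_has_negligible_pore_volume(self):
        """A nonporous (film-only) surface shows < 2% of the pore volume of
        an equal-surface porous sample once its known external area is
        accounted for."""
        area = 355.0
        iso0, _ = sd.gen_isotherm(total_volume=1e-9, external_area=area)
        iso1, _ = sd.gen_isotherm(median_diameter_A=80.0, total_volume=0.70,
                                  external_area=5.0)
        v0 = ph.bjh_distribution(iso0, external_area=area).total_volume
        v1 = ph.bjh_distribution(iso1, external_area=5.0).total_volume
        assert v0 < 0.02 * v1

    def test_carrier_like_fixture_average_diameter(self):
        """A distribution spanning the 30-125 Å carrier range yields a BJH
        average pore diameter near 80.5 Å."""
        iso, _ = sd.gen_isotherm(median_diameter_A=80.5, geometric_sigma=1.25,
                                 total_volume=0.70, external_area=5.0)
        psd = ph.bjh_distribution(iso, external_area=5.0)
        avg = ph.average_pore_diameter(psd)
        assert avg == pytest.approx(80.5, rel=0.05)

    def test_missing_branch_errors(self):
        iso = sd.gen_bet_isotherm(70.0, 100.0)  # adsorption only
        with pytest.raises(PhysisorptionError, match="branch"):
            ph.bjh_distribution(iso, branch="des")


class TestAveragePoreDiameter:
    def test_two_bin_volume_weighted_mean(self):
        psd = ph.PoreSizeDistribution(np.array([60.0, 100.0]),
                                      np.array([0.25, 0.75]),
                                      np.array([10.0, 10.0]))
        assert ph.average_pore_diameter(psd) == pytest.approx(90.0)

    def test_single_bin_any_method(self):
        psd = ph.PoreSizeDistribution(np.array([80.0]), np.array([0.5]),
                                      np.array([10.0]))
        assert ph.average_pore_diameter(psd, "volume_weighted") == pytest.approx(80.0)
        assert ph.average_pore_diameter(psd, "four_v_over_a") == pytest.approx(80.0)

    def test_symmetric_distribution_centered(self):
        d = np.array([60.0, 80.0, 100.0])
        v = np.array([0.2, 0.6, 0.2])
        psd = ph.PoreSizeDistribution(d, v, np.full(3, 20.0))
        assert ph.average_pore_diameter(psd) == pytest.approx(80.0)

    def test_empty_distribution_errors(self):
        psd = ph.PoreSizeDistribution(np.array([80.0]), np.array([0.0]),
                                      np.array([10.0]))
        with pytest.raises(PhysisorptionError, match="empty"):
            ph.average_pore_diameter(psd)


class TestPoreMetricsDelta:
    def test_loading_reduces_area_65pct(self):
        ref = PoreMetrics(312.0, 0.70, 80.5)
        loaded = PoreMetrics(108.0, 0.25, 73.5)
        delta = ph.pore_metrics_delta(ref, loaded)
        assert delta.surface_area_reduction_pct == pytest.approx(65.4, abs=0.05)

    def test_washed_sample_reductions(self):
        ref = PoreMetrics(312.0, 0.70, 80.5)
        washed = PoreMetrics(171.0, 0.40, 78.5)
        delta = ph.pore_metrics_delta(ref, washed)
        assert delta.surface_area_reduction_pct == pytest.approx(45.2, abs=0.05)
        assert delta.pore_volume_reduction_pct == pytest.approx(42.9, abs=0.05)

    def test_identical_metrics_zero_and_increase_flagged(self):
        m = PoreMetrics(100.0, 0.5, 80.0)
        assert ph.pore_metrics_delta(m, m).surface_area_reduction_pct == 0.0
        bigger = PoreMetrics(150.0, 0.6, 80.0)
        assert ph.pore_metrics_delta(m, bigger).increased

    def test_swap_antisymmetry(self):
        """100(1 − s/r) under swap maps x to −x/(1−x/100): check via ratios."""
        a = PoreMetrics(312.0, 0.70, 80.5)
        b = PoreMetrics(171.0, 0.40, 78.5)
        fwd = ph.pore_metrics_delta(a, b).surface_area_reduction_pct
        rev = ph.pore_metrics_delta(b, a).surface_area_reduction_pct
        assert (1 - fwd / 100.0) * (1 - rev / 100.0) == pytest.approx(1.0, rel=1e-12)


class TestIsothermValidation:
    def test_pressure_out_of_bounds(self):
        with pytest.raises(PhysisorptionError):
            ph.SorptionIsotherm(np.array([0.0, 0.5]), np.array([1.0, 2.0]),
                                np.array(["ads", "ads"], dtype=object))

    def test_inverted_hysteresis_rejected(self):
        p = np.array([0.2, 0.5, 0.8, 0.8, 0.5, 0.2])
        q = np.array([10.0, 20.0, 30.0, 30.0, 15.0, 5.0])  # des below ads
        b = np.array(["ads"] * 3 + ["des"] * 3, dtype=object)
        with pytest.raises(PhysisorptionError, match="hysteresis"):
            ph.SorptionIsotherm(p, q, b)

    def test_consistency_factor_near_one_for_cylinders(self):
        m = PoreMetrics(312.0, 0.70, 80.5)
        assert m.consistency_factor() == pytest.approx(4e4 * 0.70 / 312.0 / 80.5)
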