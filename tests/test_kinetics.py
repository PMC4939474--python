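"""Rate-constant regression, titration fit, antenna geometry and area arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protonfcs import (
    SAMPLES,
    AntennaGeometry,
    CurveMeta,
    FCSModelParams,
    TitrationParams,
    annulus_area,
    antenna_radius,
    disc_area,
    dwell_time,
    fit_protonation,
    fit_titration,
    fold_change,
    kprot_points,
    mean_sd,
    titration_value,
)
from protonfcs.fitting import FitResult


def _fit_result(tau_prot: float, meta=None) -> FitResult:
    params = FCSModelParams(N=4.0, tau_D=3e-4, P=0.3, tau_prot=tau_prot)
    return FitResult(params=params, stderr={}, residuals=np.zeros(1), cost=0.0,
                     converged=True, n_iter=1, meta=meta)


class TestKprotPoints:
    def test_reciprocal_and_ph_conversion(self):
        pts = kprot_points([(_fit_result(7.9e-6), CurveMeta(pH=8.0))])
        h, k = pts[0]
        assert h == pytest.approx(1e-8, rel=1e-12)
        assert k == pytest.approx(1 / 7.9e-6, rel=1e-12)
        assert k == pytest.approx(1.266e5, rel=1e-3)

    def test_empty_input(self):
        assert kprot_points([]) == []

    def test_missing_ph_metadata_names_curve(self):
        with pytest.raises(ValueError, match="sample-x"):
            kprot_points([(_fit_result(1e-5), CurveMeta(sample_id="sample-x"))])

    def test_nd12_rates_from_measured_constants(self):
        """k_prot at pH 9 and 8 from the bundled 12-nm-disc rate constants."""
        spec = SAMPLES["ND12-flu"]
        for ph, expected in ((9.0, 6.015e4), (8.0, 1.263e5)):
            k = spec.k_off + spec.kappa_on * 10 ** (-ph)
            assert k == pytest.approx(expected, rel=1e-3)
            pts = kprot_points([(_fit_result(1.0 / k), CurveMeta(pH=ph))])
            assert pts[0][1] == pytest.approx(expected, rel=1e-3)


class TestFitProtonation:
    def test_exact_line_recovery(self):
        kappa, koff = 7.54e12, 6.72e4  # 9-nm-disc sample constants
        pts = [(h, koff + kappa * h) for h in (1e-9, 2e-9, 5e-9, 1e-8)]
        kin = fit_protonation(pts, h_max=1e-8)
        assert kin.kappa_on == pytest.approx(kappa, rel=1e-9)
        assert kin.k_off == pytest.approx(koff, rel=1e-9)
        assert kin.n_points == 4

    def test_two_points_interpolate_exactly(self):
        pts = [(1e-9, 5e4), (1e-8, 1.4e5)]
        kin = fit_protonation(pts)
        assert kin.kappa_on == pytest.approx(1e13, rel=1e-12)
        assert kin.k_off == pytest.approx(4e4, rel=1e-9)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(11)
        kappa, koff = 7.35e12, 5.28e4
        h = np.geomspace(1e-9, 1e-8, 8)
        k = (koff + kappa * h) * (1 + rng.normal(0, 0.05, size=8))
        kin = fit_protonation(list(zip(h, k)), h_max=1e-8)
        assert kin.kappa_on == pytest.approx(kappa, rel=0.15)

    def test_h_max_filter_and_count(self):
        pts = [(1e-9, 6e4), (1e-8, 1.3e5), (1e-6, 7e6)]
        kin = fit_protonation(pts, h_max=1e-8)
        assert kin.n_points == 2
        assert kin.h_range == (1e-9, 1e-8)

    def test_too_few_admissible_points(self):
        with pytest.raises(ValueError):
            fit_protonation([(1e-9, 6e4), (1e-6, 7e6)], h_max=1e-8)

    def test_negative_intercept_flagged_not_clamped(self):
        pts = [(1e-9, 1e4), (5e-9, 6e4), (1e-8, 1.2e5)]
        kin = fit_protonation(pts)
        assert kin.k_off < 0
        assert kin.warn_negative_koff


class TestFitTitration:
    def test_noiseless_recovery(self):
        truth = TitrationParams(a=0.41, pKa1=6.8, pKa2=8.7, c=0.0)
        grid = np.arange(5.0, 10.25, 0.25)
        pts = [(ph, float(titration_value(truth, ph))) for ph in grid]
        fit = fit_titration(pts)
        assert fit.converged
        assert fit.params.a == pytest.approx(truth.a, abs=1e-3)
        assert fit.params.pKa1 == pytest.approx(truth.pKa1, abs=1e-3)
        assert fit.params.pKa2 == pytest.approx(truth.pKa2, abs=1e-3)

    def test_flat_data_flagged(self):
        pts = [(ph, 0.2) for ph in (5.0, 6.0, 7.0, 8.0)]
        fit = fit_titration(pts)
        assert not fit.converged

    def test_single_site_data(self):
        """Data with one transition are reproduced by the reduced model; the
        site split (a, pKa1) is degenerate, so recovery is asserted at the
        function level plus the identifiable upper pKa."""
        truth = TitrationParams(a=0.0, pKa1=7.0, pKa2=7.4, c=0.0)
        grid = np.arange(5.0, 10.0, 0.25)
        pts = [(ph, float(titration_value(truth, ph))) for ph in grid]
        fit = fit_titration(pts)
        recon = np.asarray(titration_value(fit.params, grid))
        np.testing.assert_allclose(recon, [p[1] for p in pts], atol=1e-4)
        assert fit.params.pKa2 == pytest.approx(7.4, abs=0.02)

    def test_needs_span_and_points(self):
        with pytest.raises(ValueError):
            fit_titration([(7.0, 0.1), (7.2, 0.2), (7.4, 0.3)])
        with pytest.raises(ValueError):
            fit_titration([(7.0, 0.1), (7.2, 0.2), (7.4, 0.3), (7.6, 0.4)])

    def test_ordering_convention_after_fit(self):
        truth = TitrationParams(a=0.3, pKa1=6.5, pKa2=8.5)
        pts = [(ph, float(titration_value(truth, ph))) for ph in np.arange(4.5, 10.5, 0.25)]
        # initialize with the sites crossed
        fit = fit_titration(pts, init=TitrationParams(a=0.7, pKa1=5.0, pKa2=9.5))
        assert fit.params.pKa1 <= fit.params.pKa2


class TestAntennaGeometry:
    def test_radius_from_surface_diffusion(self):
        # D_s = 2e-7 cm^2/s = 2e7 nm^2/s, dwell 1 us
        assert antenna_radius(2e7, 1e-6) == pytest.approx(3.568, abs=2e-3)

    def test_dwell_from_radius(self):
        assert dwell_time(5.0, 2e7) == pytest.approx(1.963e-6, rel=1e-3)

    def test_sqrt_scaling(self):
        assert antenna_radius(2e7, 4e-6) == pytest.approx(2 * antenna_radius(2e7, 1e-6), rel=1e-12)

    @given(d=st.floats(1e4, 1e10), tau=st.floats(1e-9, 1e-3))
    @settings(max_examples=100, deadline=None)
    def test_mutually_inverse(self, d, tau):
        assert dwell_time(antenna_radius(d, tau), d) == pytest.approx(tau, rel=1e-12)

    def test_consistency_enforced(self):
        with pytest.raises(ValueError):
            AntennaGeometry(R_PCA=10.0, D_s=2e7, tau_s=1e-6)
        AntennaGeometry(R_PCA=antenna_radius(2e7, 1e-6), D_s=2e7, tau_s=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            antenna_radius(0.0, 1e-6)
        with pytest.raises(ValueError):
            dwell_time(5.0, -1.0)


class TestMembraneAreas:
    def test_disc_areas_match_printed_values(self):
        assert disc_area(9.0) == pytest.approx(63.6, abs=0.05)   # printed as 64 / ~60
        assert disc_area(12.0) == pytest.approx(113.1, abs=0.05)  # printed as ~110

    def test_annulus_areas_match_printed_values(self):
        # 6.5-nm protein footprint inside 12- and 9-nm discs: ~80 and ~30 nm^2
        assert annulus_area(12.0, 6.5) == pytest.approx(79.9, abs=0.05)
        assert annulus_area(9.0, 6.5) == pytest.approx(30.4, abs=0.05)

    def test_protein_must_fit(self):
        with pytest.raises(ValueError):
            annulus_area(6.0, 6.5)


class TestFoldChanges:
    def test_vesicle_vs_disc_factor_four(self):
        assert fold_change(3.1e13, 7.71e12) == pytest.approx(4.02, abs=0.01)

    def test_small_to_large_disc_factor_fifty(self):
        assert fold_change(7.71e12, 1.44e11) == pytest.approx(53.5, abs=0.1)

    def test_identity(self):
        assert fold_change(3.3, 3.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)

    def test_antenna_exceeds_free_dye_hundredfold(self):
        """Each disc-anchored-dye on-rate constant exceeds free fluorescein's
        by more than two orders of magnitude."""
        free = SAMPLES["flu"].kappa_on
        for sid in ("ND9-flu", "ND12-flu", "ND12-CytcO-flu"):
            assert fold_change(SAMPLES[sid].kappa_on, free) > 100


def test_mean_sd_helper():
    m, s = mean_sd([7.2e12, 7.5e12, 7.4e12])
    assert m == pytest.approx(7.3666e12, rel=1e-4)
    assert s == pytest.approx(np.std([7.2e12, 7.5e12, 7.4e12], ddof=1), rel=1e-12)
    assert mean_sd([5.0]) == (5.0, 0.0)
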