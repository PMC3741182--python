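"""WLC force model, inversion and parameter fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptdna
from ptdna.wlc import WLC_ALPHA, KB_PN_NM_PER_K, _bracket


class TestForceModel:
    def test_zero_extension_gives_zero_force(self, untreated_params):
        assert ptdna.wlc_force(0.0, untreated_params) == pytest.approx(0.0)

    def test_force_at_half_extension_matches_term_by_term_evaluation(self):
        """Independent oracle: literal term-by-term sum at z = 0.5."""
        params = ptdna.WLCParameters(50.0, 16.5, 298.0)
        z = 0.5
        kBT = 1.380649e-2 * 298.0
        terms = [
            1.0 / (4.0 * (1.0 - z) ** 2),
            -0.25,
            z,
            -0.5164228 * z**2,
            -2.737418 * z**3,
            16.07497 * z**4,
            -38.87607 * z**5,
            39.49944 * z**6,
            -14.17718 * z**7,
        ]
        expected = (kBT / 50.0) * math.fsum(terms)
        assert ptdna.wlc_force(z, params) == pytest.approx(expected, rel=1e-14)

    def test_standard_interpolation_coefficients(self):
        """The seventh-order correction uses the standard coefficient set."""
        assert WLC_ALPHA == (-0.5164228, -2.737418, 16.07497, -38.87607,
                             39.49944, -14.17718)
        assert KB_PN_NM_PER_K * 298.0 == pytest.approx(4.11, abs=0.01)

    def test_domain_errors(self, untreated_params):
        for z in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                ptdna.wlc_force(z, untreated_params)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(z1=st.floats(0.0, 0.995), dz=st.floats(1e-6, 0.004))
    def test_force_strictly_increasing(self, z1, dz):
        params = ptdna.WLCParameters(44.0, 16.5)
        assert ptdna.wlc_force(z1 + dz, params) > ptdna.wlc_force(z1, params)

    def test_force_diverges_near_full_extension(self, untreated_params):
        assert ptdna.wlc_force(1 - 1e-6, untreated_params) > 1e6


class TestInversion:
    @pytest.mark.parametrize("z", [0.1, 0.5, 0.9])
    def test_round_trip(self, z, untreated_params):
        f = ptdna.wlc_force(z, untreated_params)
        ext = ptdna.wlc_extension_at_force(f, untreated_params)
        z_back = ext / untreated_params.contour_length_um
        assert z_back == pytest.approx(z, abs=1e-8)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(z=st.floats(1e-4, 0.99))
    def test_round_trip_across_domain(self, z):
        params = ptdna.WLCParameters(44.0, 16.5)
        f = ptdna.wlc_force(z, params)
        z_back = ptdna.wlc_extension_at_force(f, params) / 16.5
        assert abs(z_back - z) < 1e-8

    def test_small_force_limit(self, untreated_params):
        ext = ptdna.wlc_extension_at_force(1e-6, untreated_params)
        assert ext / untreated_params.contour_length_um < 1e-3

    def test_monotone_in_force(self, untreated_params):
        exts = [ptdna.wlc_extension_at_force(f, untreated_params)
                for f in (0.1, 0.5, 2.0, 6.0)]
        assert np.all(np.diff(exts) > 0)

    def test_nonpositive_force_rejected(self, untreated_params):
        with pytest.raises(ValueError):
            ptdna.wlc_extension_at_force(0.0, untreated_params)


class TestFit:
    def test_noiseless_recovery(self, untreated_params):
        curve = ptdna.gen_force_extension(untreated_params, seed=0)
        fit = ptdna.fit_wlc(curve)
        assert fit.converged
        assert fit.params.persistence_length_nm == pytest.approx(44.0,
                                                                 rel=1e-6)
        assert fit.params.contour_length_um == pytest.approx(16.5, rel=1e-6)

    def test_noisy_recovery_within_printed_ci(self, untreated_params):
        """5% force noise, 40 points: P recovered within +/- 2.1 nm."""
        curve = ptdna.gen_force_extension(
            untreated_params, n_points=40,
            noise=ptdna.NoiseModel("multiplicative-gaussian", 0.05), seed=11)
        fit = ptdna.fit_wlc(curve)
        assert abs(fit.params.persistence_length_nm - 44.0) < 2.1

    def test_matches_grid_search_oracle(self):
        """Exhaustive (P, L0) grid at 0.1% resolution on a tiny curve."""
        truth = ptdna.WLCParameters(44.0, 16.5)
        forces = np.array([0.1, 0.4, 1.0, 2.5, 4.0, 6.0])
        ext = np.array([ptdna.wlc_extension_at_force(f, truth)
                        for f in forces])
        rng = np.random.default_rng(5)
        forces_obs = forces * (1 + 0.03 * rng.standard_normal(6))
        curve = ptdna.ForceExtensionCurve(ext, forces_obs)
        fit = ptdna.fit_wlc(curve)

        # 2-D grid: the optimizer's optimum dominates every grid point, and
        # the grid's best rss is within its resolution of the optimizer's
        # (P and L0 are strongly correlated, so coordinates are compared on
        # the 1-D profile below rather than on the 2-D ridge)
        P_grid = np.arange(40.0, 48.0, 0.044)
        L_grid = np.arange(16.0, 17.0, 0.0165)
        kBT = truth.kBT_pN_nm
        best = (np.inf, None, None)
        for P in P_grid:
            for L0 in L_grid:
                pred = (kBT / P) * _bracket(ext / L0)
                rss = float(np.sum((pred - forces_obs) ** 2))
                if rss < best[0]:
                    best = (rss, P, L0)
        assert fit.residual_rss <= best[0] + 1e-12
        # the grid's optimum is at least as good as the grid point nearest
        # the optimizer's solution (no better basin elsewhere)
        P_near = P_grid[np.argmin(np.abs(P_grid
                                         - fit.params.persistence_length_nm))]
        L_near = L_grid[np.argmin(np.abs(L_grid
                                         - fit.params.contour_length_um))]
        pred = (kBT / P_near) * _bracket(ext / L_near)
        assert best[0] <= float(np.sum((pred - forces_obs) ** 2)) + 1e-12

        # 1-D profile at fixed contour: coordinates match within a grid step
        fit1d = ptdna.fit_wlc(curve, fix_contour_um=16.5)
        best1d = (np.inf, None)
        for P in np.arange(40.0, 48.0, 0.044):
            pred = (kBT / P) * _bracket(ext / 16.5)
            rss = float(np.sum((pred - forces_obs) ** 2))
            if rss < best1d[0]:
                best1d = (rss, P)
        assert fit1d.params.persistence_length_nm == pytest.approx(
            best1d[1], abs=0.044)

    def test_scale_consistency(self, untreated_params):
        """Scaling forces and kB*T by the same factor leaves (P, L0) fixed."""
        curve = ptdna.gen_force_extension(
            untreated_params,
            noise=ptdna.NoiseModel("multiplicative-gaussian", 0.03), seed=2)
        fit1 = ptdna.fit_wlc(curve)
        c = 2.5
        scaled = ptdna.ForceExtensionCurve(curve.extensions_um,
                                           c * curve.forces_pN)
        fit2 = ptdna.fit_wlc(scaled, temperature_K=c * 298.0)
        assert fit2.params.persistence_length_nm == pytest.approx(
            fit1.params.persistence_length_nm, rel=1e-6)
        assert fit2.params.contour_length_um == pytest.approx(
            fit1.params.contour_length_um, rel=1e-6)

    def test_median_recovery_over_replicates(self, untreated_params):
        """Median fitted P over 100 noisy replicates within 2% of truth."""
        noise = ptdna.NoiseModel("multiplicative-gaussian", 0.05)
        P_hat = []
        for seed in range(100):
            curve = ptdna.gen_force_extension(untreated_params, noise=noise,
                                              seed=seed)
            P_hat.append(ptdna.fit_wlc(curve).params.persistence_length_nm)
        assert np.median(P_hat) == pytest.approx(44.0, rel=0.02)

    def test_fix_contour_option(self, untreated_params):
        curve = ptdna.gen_force_extension(untreated_params, seed=0)
        fit = ptdna.fit_wlc(curve, fix_contour_um=16.5)
        assert fit.params.contour_length_um == 16.5
        assert fit.params.persistence_length_nm == pytest.approx(44.0,
                                                                 rel=1e-6)
        assert fit.ci95_contour_um == 0.0

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            curve = ptdna.ForceExtensionCurve(
                np.full(8, 5.0), np.linspace(0.1, 2.0, 8))
            ptdna.fit_wlc(curve)

    def test_report_serialization(self, untreated_params):
        curve = ptdna.gen_force_extension(untreated_params, seed=0)
        fit = ptdna.fit_wlc(curve)
        d = fit.to_dict()
        assert set(d) == {"params", "ci95", "rss", "converged", "n_points"}
        assert d["n_points"] == 40


class TestTypes:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            ptdna.WLCParameters(-1.0, 16.5)
        with pytest.raises(ValueError):
            ptdna.WLCParameters(44.0, 0.0)

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            ptdna.ForceExtensionCurve(np.arange(5.0), np.arange(1.0, 6.0))
        with pytest.raises(ValueError):
            ptdna.ForceExtensionCurve(np.arange(8.0),
                                      np.r_[np.arange(1.0, 8.0), -1.0])
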