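"""Exponential-decay fitting, condensation rates, changepoints, split fits."""

import warnings

import numpy as np
import pytest

import ptdna
from ptdna.kinetics import IdentifiabilityError
from tests.conftest import make_decay_series


class TestSingleExponential:
    def test_noiseless_recovery(self):
        ts = make_decay_series(5.0, [12.0], [97.13], duration=400.0)
        fit = ptdna.fit_single_exponential(ts)
        assert fit.converged
        assert fit.time_constants_min[0] == pytest.approx(97.13, rel=1e-3)
        assert fit.plateau_um == pytest.approx(5.0, rel=1e-3)

    def test_zero_amplitude_is_unidentifiable(self):
        ts = make_decay_series(5.0, [0.0], [50.0])
        with pytest.raises(IdentifiabilityError):
            ptdna.fit_single_exponential(ts)

    def test_matches_profiled_grid_oracle(self):
        """Grid over T with (plateau, amplitude) solved linearly at each T."""
        t = np.arange(10, dtype=float) * 5.0
        rng = np.random.default_rng(3)
        y = 4.0 + 6.0 * np.exp(-t / 12.0) + 0.05 * rng.standard_normal(10)
        ts = ptdna.ExtensionTimeSeries(t, y)
        fit = ptdna.fit_single_exponential(ts)

        best = (np.inf, None)
        for T in np.linspace(1.0, 60.0, 2000):
            X = np.column_stack([np.ones_like(t), np.exp(-t / T)])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ coef) ** 2))
            if rss < best[0]:
                best = (rss, T)
        assert fit.rss <= best[0] + 1e-10
        assert fit.time_constants_min[0] == pytest.approx(best[1], rel=0.02)

    def test_rss_self_consistency(self):
        ts = make_decay_series(5.0, [8.0], [60.0], sigma=0.1, seed=1,
                               duration=300.0)
        fit = ptdna.fit_single_exponential(ts)
        rss = float(np.sum((fit.predict(ts.times_min)
                            - ts.extensions_um) ** 2))
        assert rss == pytest.approx(fit.rss, abs=1e-10)


class TestDoubleExponential:
    def test_noiseless_recovery_of_printed_constants(self):
        ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                               duration=600.0)
        fit = ptdna.fit_double_exponential(ts)
        T1, T2 = fit.time_constants_min
        assert T1 == pytest.approx(23.89, rel=5e-3)
        assert T2 == pytest.approx(473.27, rel=5e-3)
        assert T1 < T2

    def test_equal_constants_merge_amplitudes(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ts = make_decay_series(5.0, [2.0, 3.0], [50.0, 50.0],
                                   duration=300.0)
            fit = ptdna.fit_double_exponential(ts)
        assert sum(fit.amplitudes_um) == pytest.approx(5.0, rel=1e-3)

    def test_collapse_warning(self):
        ts = make_decay_series(5.0, [2.0, 3.0], [50.0, 50.0], duration=300.0)
        with pytest.warns(RuntimeWarning):
            ptdna.fit_double_exponential(ts)

    def test_ordering_invariant(self):
        """T1 < T2 after every fit, regardless of noise realization."""
        for seed in range(5):
            ts = make_decay_series(4.0, [3.2, 6.5], [14.74, 1130.61],
                                   duration=600.0, sigma=0.27, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = ptdna.fit_double_exponential(ts)
            assert fit.time_constants_min[0] < fit.time_constants_min[1]
            assert all(T > 0 for T in fit.time_constants_min)


class TestModelSelection:
    def test_true_model_preferred(self):
        # asymptotic (noiseless) case: the simpler true model must win
        single = make_decay_series(5.0, [8.7], [97.13], duration=400.0)
        assert ptdna.select_decay_model(single).model == "single"
        double = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                                   duration=600.0, sigma=0.27, seed=0)
        assert ptdna.select_decay_model(double).model == "double"

    def test_agrees_with_f_test_oracle(self):
        """AICc choice matches a residual F test on 20 clear-cut datasets."""
        agree = 0
        for seed in range(20):
            if seed < 10:
                ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                                       duration=600.0, sigma=0.27, seed=seed)
            else:
                ts = make_decay_series(5.0, [8.7], [97.13], duration=400.0,
                                       sigma=0.17, seed=seed)
            chosen = ptdna.select_decay_model(ts).model
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s = ptdna.fit_single_exponential(ts)
                d = ptdna.fit_double_exponential(ts)
            n = len(ts)
            from scipy.stats import f as fdist
            fstat = ((s.rss - d.rss) / 2) / (d.rss / (n - 5))
            oracle = "double" if fdist.sf(fstat, 2, n - 5) < 0.05 else "single"
            agree += chosen == oracle
        assert agree == 20


class TestRates:
    def test_average_rate_closed_form(self):
        ts = make_decay_series(5.0, [8.7], [97.13], duration=400.0)
        ra = ptdna.average_rate(ts)
        closed = 8.7 * (1 - np.exp(-ra.times_min / 97.13)) / ra.times_min
        assert np.max(np.abs(ra.values - closed)) < 1e-10

    def test_average_rate_identity(self):
        """t * nu_a(t) + L(t) = L(0) exactly with the sample origin."""
        ts = make_decay_series(5.0, [8.7], [97.13], duration=200.0,
                               sigma=0.1, seed=7)
        ra = ptdna.average_rate(ts, origin="sample")
        recon = ra.times_min * ra.values + ts.extensions_um[1:]
        assert np.allclose(recon, ts.extensions_um[0], atol=1e-12)

    def test_average_rate_constant_series_is_zero(self):
        t = np.arange(10, dtype=float)
        ts = ptdna.ExtensionTimeSeries(t, np.full(10, 7.0))
        ra = ptdna.average_rate(ts)
        assert np.allclose(ra.values, 0.0)

    def test_average_rate_nonnegative_for_decay(self):
        ts = make_decay_series(5.0, [8.7], [97.13], duration=400.0)
        assert np.all(ptdna.average_rate(ts).values >= 0)

    def test_instantaneous_rate_exact_on_linear_decay(self):
        t = np.arange(0.0, 50.0)
        ts = ptdna.ExtensionTimeSeries(t, 10.0 - 0.05 * t)
        ri = ptdna.instantaneous_rate(ts)
        assert np.allclose(ri.values, 0.05, atol=1e-12)

    def test_instantaneous_rate_closed_form(self):
        ts = make_decay_series(5.0, [8.7], [97.13], duration=400.0)
        ri = ptdna.instantaneous_rate(ts, window=11, poly_order=2)
        closed = (8.7 / 97.13) * np.exp(-ri.times_min / 97.13)
        interior = slice(10, -10)
        rel = np.abs(ri.values - closed)[interior] / closed[interior]
        assert rel.max() < 0.02

    def test_instantaneous_rate_unbiased_on_white_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 400.0)
        ts = ptdna.ExtensionTimeSeries(t, 5.0 + 0.1 * rng.standard_normal(400))
        ri = ptdna.instantaneous_rate(ts)
        assert abs(ri.values.mean()) < 1e-3

    def test_window_validation(self):
        ts = make_decay_series(5.0, [8.0], [60.0], duration=20.0)
        with pytest.raises(ValueError):
            ptdna.instantaneous_rate(ts, window=10)
        with pytest.raises(ValueError):
            ptdna.instantaneous_rate(ts, window=3, poly_order=2)


class TestChangepoint:
    @staticmethod
    def _piecewise(seed=0, tb=40.0, noise=0.005):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 100.0, 60)
        y = np.where(t < tb, 1 - 0.01 * t, 1 - 0.01 * tb - 0.04 * (t - tb))
        return ptdna.RateSeries(t, y + rng.normal(0, noise, t.size),
                                "instantaneous")

    def test_straight_line_not_significant(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0.0, 100.0, 60)
        rs = ptdna.RateSeries(t, 1 - 0.01 * t + rng.normal(0, 0.02, 60),
                              "instantaneous")
        assert not ptdna.detect_slope_discontinuity(rs).significant

    def test_breakpoint_located_within_one_grid_step(self):
        rs = self._piecewise()
        cp = ptdna.detect_slope_discontinuity(rs)
        step = rs.times_min[1] - rs.times_min[0]
        assert abs(cp.breakpoint_time_min - 40.0) <= step + 1e-9
        assert cp.significant
        assert cp.right_slope < cp.left_slope

    def test_sse_equals_brute_force_oracle(self):
        """Independent exhaustive hinge regression over all breakpoints."""
        rs = self._piecewise(seed=3)
        cp = ptdna.detect_slope_discontinuity(rs)
        t, y = rs.times_min, rs.values
        best = np.inf
        for i in range(2, t.size - 3):
            X = np.column_stack([np.ones_like(t), t,
                                 np.clip(t - t[i], 0, None)])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            best = min(best, float(np.sum((y - X @ beta) ** 2)))
        coef_sse = best
        # reconstruct the detector's SSE from its F statistic
        X1 = np.column_stack([np.ones_like(t), t])
        b1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
        sse1 = float(np.sum((y - X1 @ b1) ** 2))
        df2 = t.size - 4
        sse2 = sse1 / (1 + 2 * cp.improvement_stat / df2)
        assert sse2 == pytest.approx(coef_sse, rel=1e-9)


class TestSplitFit:
    @staticmethod
    def _two_regime(seed=None, sigma=0.0):
        spec = {"head": {"plateau": 3.5, "amplitudes": [3.4, 6.8],
                         "time_constants": [6.07, 76.23]},
                "tail": {"plateau": 2.0, "time_constant": 146.98},
                "breakpoint_min": 120.0}
        return ptdna.gen_extension_timeseries(
            spec, duration_min=600.0,
            noise=ptdna.NoiseModel("additive-gaussian", sigma), seed=seed)

    def test_tail_constant_recovered(self):
        ts = self._two_regime(seed=5, sigma=0.27)
        sp = ptdna.split_exponential_fit(ts)
        assert sp.regime_change
        assert sp.tail_fit.time_constants_min[0] == pytest.approx(146.98,
                                                                  rel=0.10)

    def test_pure_double_exponential_flags_no_regime_change(self):
        ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                               duration=600.0, sigma=0.27, seed=9)
        sp = ptdna.split_exponential_fit(ts)
        assert not sp.regime_change

    def test_breakpoint_matches_finer_exhaustive_search(self):
        """Refinement oracle: dense grid at double the coarse resolution."""
        ts = self._two_regime(seed=2, sigma=0.15)
        sp = ptdna.split_exponential_fit(ts, n_coarse=24)
        t, span = ts.times_min, ts.span_min
        lo, hi = t[0] + 0.2 * span, t[0] + 0.8 * span
        step = (hi - lo) / 23
        best = (np.inf, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for tb in np.linspace(lo, hi, 47):
                head = t < tb
                if head.sum() < 12 or (~head).sum() < 8:
                    continue
                h = ptdna.fit_double_exponential(
                    ptdna.ExtensionTimeSeries(t[head],
                                              ts.extensions_um[head]))
                s = ptdna.fit_single_exponential(
                    ptdna.ExtensionTimeSeries(t[~head],
                                              ts.extensions_um[~head]))
                if h.rss + s.rss < best[0]:
                    best = (h.rss + s.rss, tb)
        assert abs(sp.breakpoint_time_min - best[1]) <= step + 1e-9


class TestComponentRates:
    def test_initial_rates_and_labels(self):
        ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                               duration=600.0)
        fit = ptdna.fit_double_exponential(ts)
        rates = ptdna.component_rates(fit, 0.0)
        assert set(rates) == {"fast_diadduct", "slow_microloop"}
        A1, A2 = fit.amplitudes_um
        T1, T2 = fit.time_constants_min
        assert float(rates["fast_diadduct"]) == pytest.approx(A1 / T1)
        assert float(rates["slow_microloop"]) == pytest.approx(A2 / T2)

    def test_matches_finite_difference_of_component(self):
        ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                               duration=600.0)
        fit = ptdna.fit_double_exponential(ts)
        t = np.linspace(5.0, 300.0, 50)
        h = 1e-5
        for i, label in enumerate(["fast_diadduct", "slow_microloop"]):
            A = fit.amplitudes_um[i]
            T = fit.time_constants_min[i]
            comp = lambda x: A * np.exp(-x / T)
            fd = -(comp(t + h) - comp(t - h)) / (2 * h)
            assert np.allclose(ptdna.component_rates(fit, t)[label], fd,
                               atol=1e-8)

    def test_rates_decay_and_fast_declines_faster(self):
        ts = make_decay_series(6.0, [3.0, 4.7], [23.89, 473.27],
                               duration=600.0)
        fit = ptdna.fit_double_exponential(ts)
        t = np.linspace(0.0, 400.0, 100)
        r = ptdna.component_rates(fit, t)
        for v in r.values():
            assert np.all(np.diff(v) < 0)
        rel_fast = r["fast_diadduct"] / r["fast_diadduct"][0]
        rel_slow = r["slow_microloop"] / r["slow_microloop"][0]
        assert np.all(rel_fast[1:] < rel_slow[1:])


class TestTypes:
    def test_series_invariants(self):
        with pytest.raises(ValueError):
            ptdna.ExtensionTimeSeries(np.arange(5.0), np.ones(5))  # too short
        with pytest.raises(ValueError):
            ptdna.ExtensionTimeSeries(np.zeros(10), np.ones(10))  # not increasing
        with pytest.raises(ValueError):
            ptdna.ExtensionTimeSeries(np.arange(10.0),
                                      np.r_[np.ones(9), np.nan])
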