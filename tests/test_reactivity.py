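"""Reactivity measures: GMFA, z-scored local response, trapezoidal AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tepkit.io import ROIDefinition
from tepkit.reactivity import (
    DegenerateBaselineError,
    MissingDataError,
    ResponseSeries,
    auc,
    baseline_activity,
    gmfa,
    local_response,
    score_subject,
)
from tepkit.simulate import LatentProfile, SimulationConfig, make_roi, simulate_subject_tep

from conftest import coarse_tep, make_tep


def const_series(value, n=1501, fs=1000.0, t0=-1000.0, kind="global_gmfa"):
    return ResponseSeries(kind=kind, values=np.full(n, float(value)),
                          t0_ms=t0, fs_hz=fs)


class TestGMFA:
    def test_identical_channels_give_zero(self):
        tep = coarse_tep(np.tile(np.arange(16.0)[:, None], (1, 4)))
        assert np.all(gmfa(tep).values == 0)

    def test_two_channel_hand_case(self):
        data = np.zeros((16, 2))
        data[5] = [1.0, -1.0]
        tep = coarse_tep(data)
        g = gmfa(tep).values
        assert g[5] == pytest.approx(1.0)
        assert g[0] == 0

    def test_matches_population_sd_oracle(self, rng):
        data = rng.normal(size=(10, 5))
        tep = coarse_tep(data)
        g = gmfa(tep).values
        # brute-force loop over samples: sqrt(mean squared deviation)
        for t in range(10):
            mean_t = sum(data[t]) / 5
            expect = (sum((v - mean_t) ** 2 for v in data[t]) / 5) ** 0.5
            assert g[t] == pytest.approx(expect, abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            gmfa(coarse_tep(np.zeros((16, 1))))

    def test_channel_order_invariance(self, rng):
        data = rng.normal(size=(10, 6))
        perm = rng.permutation(6)
        a = gmfa(coarse_tep(data)).values
        b = gmfa(coarse_tep(data[:, perm])).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestLocalResponse:
    def _tep_and_roi(self, data):
        ids = [f"v{i}" for i in range(data.shape[1])]
        tep = make_tep(data, space="source_roi", series_ids=ids,
                       t0_ms=-1000.0, fs_hz=1000.0)
        return tep, ROIDefinition(target="DLPFC", vertex_ids=ids)

    def test_constant_equal_to_baseline_gives_error(self):
        # s(t) constant over the whole epoch -> sigma = 0: degenerate
        tep, roi = self._tep_and_roi(np.ones((1501, 3)))
        with pytest.raises(DegenerateBaselineError):
            local_response(tep, roi)

    def test_hand_computed_z(self):
        data = np.ones((1501, 1))
        t = -1000.0 + np.arange(1501)
        c = 0.25
        base = (t >= -500) & (t <= -3)
        # alternate baseline samples at 1 +/- c -> mu = 1, sigma = c
        signs = np.where(np.arange(base.sum()) % 2 == 0, 1.0, -1.0)
        data[base, 0] = 1.0 + c * signs
        data[t == 100.0, 0] = 1.0 + 2 * c
        tep, roi = self._tep_and_roi(data)
        z = local_response(tep, roi)
        assert z.baseline_mu == pytest.approx(1.0)
        assert z.baseline_sigma == pytest.approx(c)
        assert z.values[np.nonzero(t == 100.0)[0][0]] == pytest.approx(2.0)

    def test_baseline_window_standardized(self, rng):
        cfg = SimulationConfig(n_subjects=4, n_roi_vertices=8, n_sensors=4,
                               epoch_ms=(-1000.0, 500.0))
        src, _ = simulate_subject_tep(LatentProfile("s", 0.3), "DLPFC", cfg, rng)
        z = local_response(src, make_roi("DLPFC", cfg))
        idx = src.window_indices(-500, -3)
        assert z.values[idx].mean() == pytest.approx(0.0, abs=1e-10)
        assert z.values[idx].std(ddof=0) == pytest.approx(1.0, rel=1e-10)

    def test_vertex_order_invariance(self, rng):
        data = np.abs(rng.normal(size=(1501, 5))) + 0.1
        ids = [f"v{i}" for i in range(5)]
        tep = make_tep(data, space="source_roi", series_ids=ids)
        a = local_response(tep, ROIDefinition("DLPFC", ids)).values
        b = local_response(tep, ROIDefinition("DLPFC", ids[::-1])).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rectification_precedes_averaging(self):
        # +v and -v vertices: averaging first would cancel, rectifying first must not
        data = np.zeros((1501, 2))
        t = -1000.0 + np.arange(1501)
        base = (t >= -500) & (t <= -3)
        signs = np.where(np.arange(base.sum()) % 2 == 0, 1.0, -1.0)
        data[base, 0] = 0.5 + 0.1 * signs
        data[base, 1] = -(0.5 + 0.1 * signs)
        data[t == 50.0] = [2.0, -2.0]
        tep, roi = self._tep_and_roi(data)
        z = local_response(tep, roi)
        i50 = np.nonzero(t == 50.0)[0][0]
        assert z.values[i50] == pytest.approx((2.0 - 0.5) / 0.1)


class TestAUC:
    def test_unit_series_over_response_window(self):
        assert auc(const_series(1.0)) == pytest.approx(385.0)

    def test_linear_series_matches_analytic_integral(self):
        t = -1000.0 + np.arange(1501)
        s = ResponseSeries(kind="global_gmfa", values=t / 100.0,
                           t0_ms=-1000.0, fs_hz=1000.0)
        expect = (400.0**2 - 15.0**2) / 200.0  # integral of t/100 on [15, 400]
        assert auc(s) == pytest.approx(expect, rel=1e-9)

    def test_trapezoid_exact_for_linear_at_half_rate(self):
        t_fast = -1000.0 + np.arange(1501)
        t_slow = -1000.0 + 2.0 * np.arange(751)
        for t, fs in ((t_fast, 1000.0), (t_slow, 500.0)):
            s = ResponseSeries(kind="global_gmfa", values=3.0 * t + 7.0,
                               t0_ms=-1000.0, fs_hz=fs)
            # closed window endpoints 15 and 400 ms present at 1 kHz only;
            # use an even-ms window shared by both rates
            assert auc(s, (16.0, 400.0)) == pytest.approx(
                1.5 * (400.0**2 - 16.0**2) + 7.0 * 384.0, rel=1e-9)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            auc(const_series(1.0, n=1451, t0=-1000.0), (15.0, 500.0))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 1000))
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 1501))
        mk = lambda v: ResponseSeries(kind="global_gmfa", values=v,
                                      t0_ms=-1000.0, fs_hz=1000.0)
        lhs = auc(mk(a * x + b * y))
        rhs = a * auc(mk(x)) + b * auc(mk(y))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestBaselineActivity:
    def test_zero_signal_gives_zero(self):
        ids = ["v0", "v1"]
        tep = make_tep(np.zeros((1501, 2)), space="source_roi", series_ids=ids)
        assert baseline_activity(tep, ROIDefinition("DLPFC", ids)) == 0.0

    def test_constant_rectified_amplitude(self):
        ids = ["v0"]
        c = 0.7
        tep = make_tep(np.full((1501, 1), -c), space="source_roi", series_ids=ids)
        # |s| = c over the 497 ms baseline window
        assert baseline_activity(tep, ROIDefinition("DLPFC", ids)) == pytest.approx(c * 497.0)

    def test_matches_brute_force_trapezoid(self, rng):
        cfg = SimulationConfig(n_subjects=4, n_roi_vertices=6, n_sensors=4,
                               epoch_ms=(-1000.0, 500.0))
        src, _ = simulate_subject_tep(LatentProfile("s", 0.0), "DLPFC", cfg, rng)
        roi = make_roi("DLPFC", cfg)
        got = baseline_activity(src, roi)
        cols = [src.series_index(v) for v in roi.vertex_ids]
        s = np.abs(src.data[:, cols]).mean(axis=1)
        t = src.times
        idx = src.window_indices(-500, -3)
        expect = sum(
            0.5 * (s[i] + s[i + 1]) * (t[i + 1] - t[i])
            for i in idx[:-1]
        )
        assert got == pytest.approx(expect, rel=1e-10)


class TestScoreSubject:
    def test_bundles_components_and_is_deterministic(self, fast_cfg, rng):
        src, sen = simulate_subject_tep(LatentProfile("s", 0.2), "DLPFC", fast_cfg, rng)
        roi = make_roi("DLPFC", fast_cfg)
        a = score_subject(sen, src, roi)
        b = score_subject(sen, src, roi)
        assert a == b
        assert a.local_auc == pytest.approx(auc(local_response(src, roi)))
        assert a.global_auc == pytest.approx(auc(gmfa(sen)))
        assert a.baseline_activity == pytest.approx(baseline_activity(src, roi))

    def test_missing_space_is_explicit(self, fast_cfg, rng):
        src, _ = simulate_subject_tep(LatentProfile("s", 0.0), "DLPFC", fast_cfg, rng,
                                      spaces=("source_roi",))
        with pytest.raises(MissingDataError, match="sensor"):
            score_subject(None, src, make_roi("DLPFC", fast_cfg))
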