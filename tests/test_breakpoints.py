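"""Tests of bending-point detection and replicate alignment."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from golgikin import (align_and_average, detect_breakpoint_intersection,
                      detect_breakpoint_r2scan)
from golgikin.breakpoints import NoIntersectionError
from golgikin.correction import NormalizedTrace
from golgikin.families import evaluate_family


def oracle_split(t, y, min_seg=3):
    """Independent exhaustive two-segment oracle: for every admissible split
    fit a line to the head and the better of an exponential and a line to the
    tail, and return the split minimizing total SSE."""
    best = None
    for s in range(min_seg - 1, len(t) - min_seg):
        ph = np.polyfit(t[:s + 1], y[:s + 1], 1)
        sse_h = float(np.sum((np.polyval(ph, t[:s + 1]) - y[:s + 1]) ** 2))
        tt, yy = t[s:] - t[s], y[s:]
        pl = np.polyfit(tt, yy, 1)
        sse_tail = float(np.sum((np.polyval(pl, tt) - yy) ** 2))
        c0 = max(min(yy.min(), yy[-1]), 0.0)
        try:
            sl, ic = np.polyfit(tt, np.log(np.clip(yy - c0, 1e-9, None)), 1)
            popt, _ = curve_fit(lambda x, a, k, c: a * np.exp(-k * x) + c,
                                tt, yy, p0=[np.exp(ic), max(-sl, 1e-6), c0],
                                maxfev=5000)
            sse_exp = float(np.sum((popt[0] * np.exp(-popt[1] * tt)
                                    + popt[2] - yy) ** 2))
            sse_tail = min(sse_tail, sse_exp)
        except Exception:
            pass
        tot = sse_h + sse_tail
        if best is None or tot < best[1]:
            best = (s, tot)
    return best[0]


def _trace(t, y):
    return NormalizedTrace(time_s=np.asarray(t, float),
                           value_pct=np.asarray(y, float), imax=100.0)


NOISELESS_CASES = [
    (3, {"y0": 100.0, "t_b": 60.0, "k": 0.01, "c": 0.0}),
    (3, {"y0": 100.0, "t_b": 36.0, "k": 0.008, "c": 5.0}),
    (3, {"y0": 100.0, "t_b": 120.0, "k": 0.02, "c": 0.0}),
    (4, {"y0": 100.0, "b": 0.15, "t_b": 60.0, "k": 0.01, "c": 0.0}),
    (5, {"y0": 100.0, "t_b": 60.0, "b": 0.25}),
    (5, {"y0": 100.0, "t_b": 90.0, "b": 0.3}),
]


class TestR2Scan:
    def test_pure_exponential_has_no_negative_peak(self, time_grid):
        """A noiseless exponential-decay trace yields no breakpoint."""
        y = evaluate_family(2, {"a": 100.0, "k": 0.008, "c": 0.0}, time_grid)
        bp = detect_breakpoint_r2scan(_trace(time_grid, y))
        assert not bp.found
        assert bp.index is None

    def test_plateau_then_exponential_breaks_at_plateau_end(self, time_grid):
        """Plateau through frame 10 (t_b = 60 s): the detector reports 10."""
        y = evaluate_family(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01, "c": 0.0},
                            time_grid)
        bp = detect_breakpoint_r2scan(_trace(time_grid, y))
        assert bp.index == 10
        assert bp.time_s == pytest.approx(60.0)

    @pytest.mark.parametrize("fid,params", NOISELESS_CASES)
    def test_agrees_with_exhaustive_oracle_noiseless(self, fid, params,
                                                     time_grid):
        y = evaluate_family(fid, params, time_grid)
        bp = detect_breakpoint_r2scan(_trace(time_grid, y))
        assert bp.found
        assert abs(bp.index - oracle_split(time_grid, y)) <= 1

    def test_profile_reported_with_scan(self, time_grid):
        y = evaluate_family(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01, "c": 0.0},
                            time_grid)
        bp = detect_breakpoint_r2scan(_trace(time_grid, y))
        assert bp.r2_profile.size > 0
        assert np.all(bp.r2_profile <= 1.0 + 1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_breakpoint_r2scan(_trace(np.arange(5.0), np.ones(5)))


class TestIntersection:
    def test_flat_plateau_exact_geometry(self, time_grid):
        """Horizontal plateau then exponential decay: the intersection is the
        breakpoint time to within half a frame."""
        y = evaluate_family(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01, "c": 0.0},
                            time_grid)
        bp = detect_breakpoint_intersection(_trace(time_grid, y))
        assert bp.time_s == pytest.approx(60.0, abs=3.0)

    def test_led_shape_matches_sse_optimal_split(self, time_grid):
        """Linear decay into a steeper exponential: intersection within one
        frame of the exhaustive-oracle split."""
        y = evaluate_family(4, {"y0": 100.0, "b": 0.15, "t_b": 60.0,
                                "k": 0.01, "c": 0.0}, time_grid)
        bp = detect_breakpoint_intersection(_trace(time_grid, y))
        assert abs(bp.index - oracle_split(time_grid, y)) <= 1

    @pytest.mark.parametrize("fid,params", NOISELESS_CASES)
    def test_agrees_with_exhaustive_oracle_noiseless(self, fid, params,
                                                     time_grid):
        y = evaluate_family(fid, params, time_grid)
        bp = detect_breakpoint_intersection(_trace(time_grid, y))
        assert abs(bp.index - oracle_split(time_grid, y)) <= 1

    def test_parallel_segments_raise(self, time_grid):
        """Two flat non-intersecting pieces have no crossing."""
        y = np.full(60, 100.0)
        with pytest.raises(NoIntersectionError):
            detect_breakpoint_intersection(_trace(time_grid, y))

    def test_localizes_under_noise(self, time_grid):
        """2% noise: the intersection lands within one frame of the bend in
        the vast majority of replicates."""
        rng = np.random.default_rng(123)
        clean = evaluate_family(3, {"y0": 100.0, "t_b": 60.0, "k": 0.01,
                                    "c": 0.0}, time_grid)
        hits = 0
        for _ in range(50):
            y = clean + rng.normal(0, 2.0, len(time_grid))
            bp = detect_breakpoint_intersection(_trace(time_grid, y))
            hits += abs(bp.index - 10) <= 1
        assert hits >= 45


class TestAlignAndAverage:
    def _staggered_replicates(self, plateaus, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(60) * 6.0
        traces, bps = [], []
        for p in plateaus:
            y = evaluate_family(3, {"y0": 100.0, "t_b": p, "k": 0.01,
                                    "c": 0.0}, t)
            if noise_sd:
                y = y + rng.normal(0, noise_sd, len(t))
            tr = _trace(t, y)
            traces.append(tr)
            bps.append(detect_breakpoint_r2scan(tr))
        return traces, bps

    def test_staggered_plateaus_collapse_onto_one_curve(self):
        """Six noiseless replicates with different plateau lengths align to a
        single common curve: pointwise SD is (near) zero."""
        traces, bps = self._staggered_replicates([36.0, 48.0, 60.0, 72.0,
                                                  84.0, 96.0])
        aligned = align_and_average(traces, bps)
        assert aligned.n_replicates == 6
        assert np.max(aligned.sd) < 1e-9

    def test_alignment_sd_reflects_noise_only(self):
        """With 2% noise the post-alignment SD is on the order of the noise."""
        traces, bps = self._staggered_replicates([48.0, 60.0, 72.0, 84.0,
                                                  60.0, 48.0], noise_sd=2.0,
                                                 seed=9)
        aligned = align_and_average(traces, bps)
        assert np.median(aligned.sd) < 3 * 2.0

    def test_zero_shift_mean_is_pointwise_mean(self, time_grid):
        y1 = evaluate_family(2, {"a": 100.0, "k": 0.01, "c": 0.0}, time_grid)
        y2 = 0.8 * y1
        traces = [_trace(time_grid, y1), _trace(time_grid, y2)]
        bps = [detect_breakpoint_r2scan(tr) for tr in traces]
        assert all(not bp.found for bp in bps)   # pure decay, no shift
        aligned = align_and_average(traces, bps)
        np.testing.assert_allclose(aligned.mean, (y1 + y2) / 2, rtol=1e-12)

    def test_permutation_invariance(self):
        traces, bps = self._staggered_replicates([48.0, 60.0, 72.0, 84.0],
                                                 noise_sd=1.0, seed=2)
        a = align_and_average(traces, bps)
        b = align_and_average(traces[::-1], bps[::-1])
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.sd, b.sd)

    def test_ci_band_shrinks_with_replicates(self):
        traces, bps = self._staggered_replicates([60.0] * 8, noise_sd=2.0,
                                                 seed=4)
        small = align_and_average(traces[:3], bps[:3])
        large = align_and_average(traces, bps)
        width_small = np.mean(small.ci95_high - small.ci95_low)
        width_large = np.mean(large.ci95_high - large.ci95_low)
        assert width_large < width_small

    def test_single_trace_rejected(self):
        traces, bps = self._staggered_replicates([60.0])
        with pytest.raises(ValueError):
            align_and_average(traces, bps)
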