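"""Bending-point detection and replicate alignment.

A normalized exit trace is typically flat (or gently sloped) until cargo
begins to leave the Golgi zone, then decays.  Two detectors locate that
bending point:

* ``detect_breakpoint_r2scan`` — the stepwise coefficient-of-determination
  scan: fit a straight trend line to a growing initial window, record
  R0^2, R1^2, ..., Rn^2, and report the frame after which the profile shows
  its maximal single-step decrease.  A pure-decay trace produces no negative
  peak in the profile and is reported as having no breakpoint.
* ``detect_breakpoint_intersection`` — fit a line to the initial segment and
  an exponential decay to the tail (segments from the SSE-optimal two-segment
  split) and return the time where the two fitted curves intersect.

Replicates are then aligned by shifting each trace so its bending point sits
at a shared origin, and averaged pointwise with SD and 95% confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import NormalizedTrace
from .families import _fit_exponential, _fit_linear_decay, MIN_SEGMENT_FRAMES

__all__ = [
    "BreakpointResult",
    "AlignedSet",
    "detect_breakpoint_r2scan",
    "detect_breakpoint_intersection",
    "align_and_average",
    "two_segment_split",
]


class NoIntersectionError(RuntimeError):
    """The head and tail fits never cross inside the observation window."""


@dataclass
class BreakpointResult:
    index: int | None            # frame index of the bending point (None: pure decay)
    time_s: float | None
    r2_profile: np.ndarray       # Rn^2 scan profile (r2scan) or empty
    method: str
    detail: dict = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.index is not None


@dataclass
class AlignedSet:
    common_time_s: np.ndarray    # grid with the breakpoint at t = 0
    values: np.ndarray           # (n_replicates, n_grid)
    mean: np.ndarray
    sd: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


def _line_r2(t, y):
    """R^2 of a straight trend line; a (near-)perfectly fit flat window is 1."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    sst = float(yc @ yc)
    slope = float(tc @ yc) / sxx if sxx > 0 else 0.0
    sse = sst - slope * slope * sxx
    scale = max(float(np.mean(y * y)), 1.0)
    if sst <= 1e-18 * scale:
        return 1.0 if sse <= 1e-18 * scale else 0.0
    return 1.0 - sse / sst


def _best_tail_fit(t, y):
    """Best decay fit for a tail segment: exponential or straight line.

    The decay part of a trace may itself be exponential or linear (the two
    tail shapes among the five candidate families), so the segment is fit by
    whichever of the two explains it better.
    Returns (kind, params, sse) with kind in {"exp", "line"}.
    """
    line, sse_line = _fit_linear_decay(t - t[0], y)
    try:
        exp, sse_exp = _fit_exponential(t - t[0], y)
    except Exception:
        return "line", line, sse_line
    if sse_exp < sse_line:
        return "exp", exp, sse_exp
    return "line", line, sse_line


def two_segment_split(t, y, min_seg=MIN_SEGMENT_FRAMES):
    """SSE-optimal split into a linear head and a decaying tail.

    The tail is fit by the better of an exponential decay and a straight
    line.  Returns (split_index s, head_sse + tail_sse) minimizing the total
    SSE over all admissible splits; the head covers frames [0..s] and the
    tail [s..end] (the bending frame belongs to both segments).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    if n < 2 * min_seg + 1:
        raise ValueError("trace too short for a two-segment split")
    best = None
    for s in range(min_seg - 1, n - min_seg):
        _, sse_head = _fit_linear_decay(t[:s + 1], y[:s + 1])
        try:
            _, _, sse_tail = _best_tail_fit(t[s:], y[s:])
        except Exception:
            continue
        total = sse_head + sse_tail
        if best is None or total < best[1]:
            best = (s, total)
    if best is None:
        raise RuntimeError("no admissible split could be fit")
    return best


def detect_breakpoint_r2scan(trace: NormalizedTrace, flat_tol=0.02,
                             min_window=4) -> BreakpointResult:
    """Stepwise R^2-scan bending-point detector.

    The scan starts from the first two-thirds of the initial (pre-decay)
    segment — located by the SSE-optimal two-segment split — fits a straight
    line, and extends the window one frame at a time, recording Rn^2.  The
    frame after which the profile drops the most is the bending point.  If no
    single-step decrease exceeds ``flat_tol`` the trace is reported as pure
    decay (no breakpoint), mirroring the absence of a negative peak in the
    profile of an exponential-decay trace.
    """
    t = np.asarray(trace.time_s, float)
    y = np.asarray(trace.value_pct, float)
    n = len(t)
    if n < 9:
        raise ValueError("need at least 9 frames for the R^2 scan")

    split, _ = two_segment_split(t, y)
    m0 = max(min_window, int(np.floor(2.0 / 3.0 * (split + 1))))
    m0 = min(m0, n - 2)

    profile = np.array([_line_r2(t[:m], y[:m]) for m in range(m0, n + 1)])
    drops = profile[:-1] - profile[1:]
    if drops.size == 0 or np.max(drops) < flat_tol:
        return BreakpointResult(index=None, time_s=None, r2_profile=profile,
                                method="r2scan",
                                detail={"max_drop": float(np.max(drops, initial=0.0)),
                                        "start_window": m0, "split_hint": split})
    step = int(np.argmax(drops))
    # window length m0+step covers frames [0 .. m0+step-1]; adding the next
    # frame caused the maximal decrease, so the bending point is the last
    # frame of that window.
    idx = m0 + step - 1
    return BreakpointResult(index=idx, time_s=float(t[idx]), r2_profile=profile,
                            method="r2scan",
                            detail={"max_drop": float(drops[step]),
                                    "start_window": m0, "split_hint": split})


def detect_breakpoint_intersection(trace: NormalizedTrace,
                                   split=None) -> BreakpointResult:
    """Bending point as the intersection of the head and tail fits.

    The two segments come from the SSE-optimal two-segment split (or a caller
    supplied split index); a straight line is fit to the head, the better of
    an exponential decay and a line to the tail, and the two fitted curves
    are intersected numerically inside the observation window.  Raises
    :class:`NoIntersectionError` when the fits never cross (e.g. parallel
    flat segments).
    """
    t = np.asarray(trace.time_s, float)
    y = np.asarray(trace.value_pct, float)
    n = len(t)
    if n < 9:
        raise ValueError("need at least 9 frames for the intersection method")
    if split is None:
        split, _ = two_segment_split(t, y)

    line, _ = _fit_linear_decay(t[:split + 1], y[:split + 1])
    tail_kind, tail, _ = _best_tail_fit(t[split:], y[split:])

    def gap(tt):
        head_val = line["y0"] - line["b"] * tt
        if tail_kind == "exp":
            tail_val = tail["a"] * np.exp(-tail["k"] * (tt - t[split])) + tail["c"]
        else:
            tail_val = tail["y0"] - tail["b"] * (tt - t[split])
        return head_val - tail_val

    # dense sign scan across the window, then bisection on the bracketing pair
    grid = np.linspace(t[0], t[-1], max(40 * n, 400))
    g = gap(grid)
    sign = np.sign(g)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise NoIntersectionError("head and tail fits do not intersect "
                                  "within the observation window")
    # pick the crossing closest to the split frame
    c = crossings[np.argmin(np.abs(grid[crossings] - t[split]))]
    lo, hi = grid[c], grid[c + 1]
    from scipy.optimize import brentq
    if gap(lo) == 0.0:
        t_cross = float(lo)
    elif gap(hi) == 0.0:
        t_cross = float(hi)
    else:
        t_cross = float(brentq(gap, lo, hi, xtol=1e-10))
    idx = int(np.argmin(np.abs(t - t_cross)))
    return BreakpointResult(index=idx, time_s=t_cross, r2_profile=np.array([]),
                            method="intersection",
                            detail={"split": int(split), "head": line,
                                    "tail_kind": tail_kind, "tail": tail})


def align_and_average(traces, breakpoints) -> AlignedSet:
    """Shift each replicate so its bending point is at t = 0, then average.

    The common grid is the overlap of the shifted supports; traces are
    interpolated linearly onto it when their grids are incommensurate.  The
    95% band is ``mean +/- 1.96 * SD / sqrt(n)``.  Replicates whose detector
    reported no breakpoint are anchored at their first frame (pure-decay
    traces need no shift).
    """
    traces = list(traces)
    breakpoints = list(breakpoints)
    if len(traces) < 2:
        raise ValueError("need at least 2 replicates to align and average")
    if len(traces) != len(breakpoints):
        raise ValueError("one breakpoint per trace required")

    rel_times, values = [], []
    for tr, bp in zip(traces, breakpoints):
        t = np.asarray(tr.time_s, float)
        idx = bp.index if (bp is not None and bp.index is not None) else 0
        t0 = bp.time_s if (bp is not None and bp.time_s is not None) else t[idx]
        rel_times.append(t - t0)
        values.append(np.asarray(tr.value_pct, float))

    lo = max(rt[0] for rt in rel_times)
    hi = min(rt[-1] for rt in rel_times)
    if hi <= lo:
        raise ValueError("aligned replicates have empty overlap")
    dt = float(np.median(np.diff(rel_times[0])))
    # grid anchored at the shared origin t=0
    grid = np.concatenate([-np.arange(0.0, -lo + 1e-9, dt)[::-1],
                           np.arange(dt, hi + 1e-9, dt)])
    mat = np.vstack([np.interp(grid, rt, v) for rt, v in zip(rel_times, values)])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    half = 1.96 * sd / np.sqrt(mat.shape[0])
    return AlignedSet(common_time_s=grid, values=mat, mean=mean, sd=sd,
                      ci95_low=mean - half, ci95_high=mean + half)
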