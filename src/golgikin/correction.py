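"""Reference-based trace correction, percent normalization and FRAP half-time.

The raw FRAP-region intensity ``Ifr`` is corrected in three steps:

1. The reference region is compensated for the bleach step: before the bleach
   ``Icrr(t) = Irr(t)``; from the bleach on, the pre/post-bleach difference is
   added back, ``Icrr(t) = Irr(t) + (Irr_pre - Irr_after)``, so ``Icrr``
   tracks only the fluorophore fading envelope.
2. Background is subtracted and fading divided out:
   ``Ifr_corr(t) = (Ifr(t) - Ibr(t)) * Irr_pre / Icrr(t)``.
3. The corrected trace is rescaled so its maximum is exactly 100 percent.

Negative corrected values (possible under noise) are retained: clipping would
bias the downstream least-squares fits.  A FRAP recovery is summarized by the
one-phase association ``F(t) = Fm*(1 - exp(-k*t))`` with half-time
``ln(2)/k``, time measured from the first post-bleach frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import RawTraceSet

__all__ = [
    "CorrectedTrace",
    "NormalizedTrace",
    "FrapFitResult",
    "correct_reference",
    "correct_trace",
    "normalize",
    "estimate_half_time",
]


class DegenerateReferenceError(ValueError):
    """The corrected reference is non-positive somewhere, so Eq.-style division fails."""


@dataclass
class CorrectedTrace:
    time_s: np.ndarray
    ifr_corr: np.ndarray
    icrr: np.ndarray
    bleach_frame: int = 0


@dataclass
class NormalizedTrace:
    time_s: np.ndarray
    value_pct: np.ndarray
    imax: float
    bleach_frame: int = 0

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class FrapFitResult:
    fm: float
    k: float
    half_time_s: float
    residual_sse: float


def correct_reference(raw: RawTraceSet) -> np.ndarray:
    """Bleach-step-compensated reference channel ``Icrr``.

    Frames before ``bleach_frame`` pass through unchanged; frames at/after it
    get the scalar difference ``Irr_pre - Irr_after`` added back.
    """
    irr = np.asarray(raw.irr, dtype=float)
    icrr = irr.copy()
    if raw.bleach_frame < len(irr):
        if raw.irr_pre is None or raw.irr_after is None:
            raise ValueError("irr_pre/irr_after required when post-bleach frames exist")
        icrr[raw.bleach_frame:] += raw.irr_pre - raw.irr_after
    return icrr


def correct_trace(raw: RawTraceSet, icrr=None) -> CorrectedTrace:
    """Background-subtracted, fading-corrected FRAP-region trace."""
    if icrr is None:
        icrr = correct_reference(raw)
    icrr = np.asarray(icrr, dtype=float)
    if np.any(icrr <= 0):
        raise DegenerateReferenceError("corrected reference non-positive")
    ifr_corr = (np.asarray(raw.ifr, float) - np.asarray(raw.ibr, float)) \
        * raw.irr_pre / icrr
    return CorrectedTrace(time_s=np.asarray(raw.time_s, float),
                          ifr_corr=ifr_corr, icrr=icrr,
                          bleach_frame=raw.bleach_frame)


def normalize(trace: CorrectedTrace, window=None) -> NormalizedTrace:
    """Percent normalization: the trace maximum is equated to 100.

    ``window`` optionally restricts the frames over which the maximum ``Imax``
    is taken (e.g. the post-synchronization part); default is the whole trace.
    """
    y = np.asarray(trace.ifr_corr, dtype=float)
    sel = y if window is None else y[slice(*window)]
    if sel.size == 0 or np.max(sel) <= 0:
        raise ValueError("trace has no positive value to normalize against")
    imax = float(np.max(sel))
    return NormalizedTrace(time_s=np.asarray(trace.time_s, float),
                           value_pct=100.0 * y / imax, imax=imax,
                           bleach_frame=trace.bleach_frame)


def estimate_half_time(trace: NormalizedTrace, bleach_frame=None) -> FrapFitResult:
    """Fit ``Fm*(1 - exp(-k*t))`` to the post-bleach recovery.

    ``t`` is measured from the first post-bleach frame.  Returns the plateau
    ``Fm``, the rate ``k`` (per second) and the half-time ``ln(2)/k``.
    """
    j = trace.bleach_frame if bleach_frame is None else bleach_frame
    t = np.asarray(trace.time_s, float)[j:]
    y = np.asarray(trace.value_pct, float)[j:]
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach frames")
    t = t - t[0]

    fm0 = max(float(np.max(y)), 1e-9)
    half = fm0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half0 = t[above[0]] if above.size and above[0] > 0 else (t[-1] / 4 or 1.0)
    k0 = np.log(2.0) / max(t_half0, t[1] if len(t) > 1 else 1.0)

    popt, _ = curve_fit(lambda tt, fm, k: fm * (1.0 - np.exp(-k * tt)),
                        t, y, p0=[fm0, k0],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10000)
    fm, k = float(popt[0]), float(popt[1])
    if not k > 0:
        raise RuntimeError("recovery fit returned a non-positive rate")
    resid = y - fm * (1.0 - np.exp(-k * t))
    return FrapFitResult(fm=fm, k=k, half_time_s=np.log(2.0) / k,
                         residual_sse=float(resid @ resid))
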