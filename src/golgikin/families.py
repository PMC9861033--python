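"""The five theoretical decay-curve families and the model competition.

A normalized fluorescence trace (percent of its own maximum versus time) is
compared against five candidate kinetic laws:

1. ``LD``  linear decay                      y(t) = y0 - b*t
2. ``ED``  exponential decay                 y(t) = a*exp(-k*t) + c
3. ``PED`` plateau -> exponential decay      y0 until t_b, then decay to c
4. ``LED`` linear -> exponential decay       y0 - b*t until t_b, then decay to c
5. ``PLD`` plateau -> linear decay           y0 until t_b, then y0 - b*(t-t_b)

Piecewise families are continuous at the breakpoint t_b.  Every family is fit
by least squares; the winner of a competition is the family with the highest
coefficient of determination R^2 (equivalently the lowest absolute sum of
squares on the same points), with a parsimony correction: a family with fewer
parameters replaces the raw winner when the extra-sum-of-squares F-test finds
the raw winner's improvement insignificant.  The exponential offset ``c``
models a fluorescence floor and may be fixed to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import f as f_dist

__all__ = [
    "FamilyFit",
    "CompetitionResult",
    "FAMILY_LABELS",
    "FAMILY_NPARAMS",
    "FAMILY_NAMES",
    "evaluate_family",
    "fit_family",
    "compete",
    "decide_from_stats",
    "classify_trace",
]

FAMILY_LABELS = {1: "LD", 2: "ED", 3: "PED", 4: "LED", 5: "PLD"}
FAMILY_NAMES = {
    1: "linear decay",
    2: "exponential decay",
    3: "plateau then exponential decay",
    4: "linear then exponential decay",
    5: "plateau then linear decay",
}
FAMILY_NPARAMS = {1: 2, 2: 3, 3: 4, 4: 5, 5: 3}

#: minimum number of frames required on each side of a piecewise breakpoint,
#: so that every segment fit is determined.  This also breaks the nesting of
#: family 2 inside family 3 (a pure exponential cannot be won by family 3 by
#: shrinking the plateau to nothing).
MIN_SEGMENT_FRAMES = 3


class FitError(ValueError):
    """Raised when a fit cannot be attempted on the given data."""


@dataclass
class FamilyFit:
    """Least-squares fit of one curve family to one trace."""

    family_id: int
    params: dict
    r2: float
    sse: float
    n_points: int
    converged: bool

    @property
    def label(self) -> str:
        return FAMILY_LABELS[self.family_id]

    @property
    def n_params(self) -> int:
        return FAMILY_NPARAMS[self.family_id]

    def predict(self, times):
        return evaluate_family(self.family_id, self.params, times)


@dataclass
class CompetitionResult:
    """All candidate fits plus the winning family and the decision trail."""

    fits: dict
    winner_id: int
    decision_trace: list = field(default_factory=list)

    @property
    def winner(self) -> FamilyFit:
        return self.fits[self.winner_id]

    @property
    def label(self) -> str:
        return FAMILY_LABELS[self.winner_id]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_family(family_id, params, times):
    """Evaluate family ``family_id`` with parameter dict ``params`` at ``times``.

    Piecewise families are continuous at ``t_b``; ``t_b`` must lie inside the
    sampled window when one is supplied.
    """
    t = np.asarray(times, dtype=float)
    p = params
    if family_id == 1:
        return p["y0"] - p["b"] * t
    if family_id == 2:
        return p["a"] * np.exp(-p["k"] * t) + p["c"]
    if family_id in (3, 4, 5):
        t_b = p["t_b"]
        if t.size and not (t.min() <= t_b <= t.max()):
            raise FitError(f"breakpoint t_b={t_b} outside the sampled window")
        tail = np.clip(t - t_b, 0.0, None)
        if family_id == 3:
            head_val = p["y0"]
            y = np.where(t <= t_b, p["y0"],
                         (head_val - p["c"]) * np.exp(-p["k"] * tail) + p["c"])
            return y
        if family_id == 4:
            head = p["y0"] - p["b"] * t
            head_val = p["y0"] - p["b"] * t_b
            y = np.where(t <= t_b, head,
                         (head_val - p["c"]) * np.exp(-p["k"] * tail) + p["c"])
            return y
        # family 5
        return np.where(t <= t_b, p["y0"], p["y0"] - p["b"] * tail)
    raise FitError(f"unknown family id {family_id}")


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _r2_sse(y, yhat):
    y = np.asarray(y, float)
    resid = y - yhat
    sse = float(resid @ resid)
    dev = y - y.mean()
    sst = float(dev @ dev)
    if sst <= 1e-300:
        return (1.0 if sse <= 1e-12 else -np.inf), sse
    return 1.0 - sse / sst, sse


def _k_grid(t, n=25):
    """Candidate decay rates spanning half-lives from ~one frame to ~10 windows."""
    span = t.max() - t.min() if t.size > 1 else 1.0
    dt = span / max(len(t) - 1, 1)
    lo = np.log(2.0) / (20.0 * span)
    hi = np.log(2.0) / max(0.25 * dt, 1e-9)
    return np.geomspace(lo, hi, n)


def _fit_exponential(t, y, fix_c=None):
    """Fit a*exp(-k*t)+c with a>=0, k>0, c>=0 by variable projection over k."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)

    def solve_linear(k):
        e = np.exp(-k * (t - t[0]))
        if fix_c is not None:
            denom = float(e @ e)
            a = float(e @ (y - fix_c)) / denom if denom > 0 else 0.0
            a = max(a, 0.0)
            yhat = a * e + fix_c
            c = fix_c
        else:
            X = np.column_stack([e, np.ones_like(e)])
            (a, c), *_ = np.linalg.lstsq(X, y, rcond=None)
            if c < 0.0 or a < 0.0:
                c = max(min(float(np.min(y)), float(c)), 0.0) if a >= 0 else 0.0
                denom = float(e @ e)
                a = max(float(e @ (y - c)) / denom, 0.0) if denom > 0 else 0.0
            yhat = a * e + c
        resid = y - yhat
        return float(resid @ resid), float(a), float(c)

    best = None
    for k in _k_grid(t):
        sse, a, c = solve_linear(k)
        if best is None or sse < best[0]:
            best = (sse, k, a, c)
    _, k0, _, _ = best
    res = minimize_scalar(lambda lk: solve_linear(np.exp(lk))[0],
                          bracket=(np.log(k0 / 2.0), np.log(k0), np.log(k0 * 2.0))
                          if k0 > 0 else None,
                          method="brent", options={"xtol": 1e-10})
    k = float(np.exp(res.x)) if np.isfinite(res.x) else k0
    sse, a, c = solve_linear(k)
    if sse > best[0]:
        sse, k, a, c = best
    # parameters are reported in the absolute time origin
    a_abs = a * np.exp(k * t[0])
    return {"a": float(a_abs), "k": float(k), "c": float(c)}, sse


def _fit_linear_decay(t, y):
    """y0 - b*t with b >= 0."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(t), -t])
    (y0, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    if b < 0.0:
        b = 0.0
        y0 = float(y.mean())
    yhat = y0 - b * t
    resid = y - yhat
    return {"y0": float(y0), "b": float(b)}, float(resid @ resid)


def _piecewise_sse(t, y, family_id, t_b, fix_c=None, polish=True):
    """Best SSE for family 3 or 4 at a fixed breakpoint t_b.

    Given (t_b, k) both families are linear in the remaining parameters:
    family 3 in (y0, c) and family 4 in (y0, b, c), so the rate k is profiled
    on a grid, plus a local refinement when ``polish`` is set (the unpolished
    profile is used while scanning breakpoint candidates).
    Returns (sse, params).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    head = t <= t_b
    tau = np.clip(t - t_b, 0.0, None)

    def design(k):
        e = np.exp(-k * tau)
        if family_id == 3:
            cols = [np.where(head, 1.0, e)]
        else:
            cols = [np.where(head, 1.0, e), np.where(head, -t, -t_b * e)]
        if fix_c is None:
            cols.append(np.where(head, 0.0, 1.0 - e))
        return np.column_stack(cols), e

    def solve(k):
        X, e = design(k)
        target = y if fix_c is None else y - np.where(head, 0.0, fix_c * (1.0 - e))
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        yhat = X @ beta + (0.0 if fix_c is None else np.where(head, 0.0, fix_c * (1.0 - e)))
        resid = y - yhat
        return float(resid @ resid), beta

    best = None
    for k in _k_grid(t, n=25 if polish else 15):
        sse, beta = solve(k)
        if best is None or sse < best[0]:
            best = (sse, k, beta)
    sse, k, beta = best
    if polish:
        k0 = k
        try:
            res = minimize_scalar(lambda lk: solve(np.exp(lk))[0],
                                  bracket=(np.log(k0 / 2.0), np.log(k0),
                                           np.log(k0 * 2.0)),
                                  method="brent", options={"xtol": 1e-12})
            k = float(np.exp(res.x))
            sse, beta = solve(k)
            if sse > best[0]:
                sse, k, beta = best
        except Exception:
            sse, k, beta = best

    if family_id == 3:
        y0 = float(beta[0])
        b = None
        c = float(beta[1]) if fix_c is None else float(fix_c)
    else:
        y0 = float(beta[0])
        b = float(beta[1])
        c = float(beta[2]) if fix_c is None else float(fix_c)

    # enforce sign constraints by constrained refits on violation
    if c < 0.0 or (b is not None and b < 0.0):
        if b is not None and b < 0.0:
            # degenerate toward a flat head: refit as family 3 shape
            sse3, p3 = _piecewise_sse(t, y, 3, t_b, fix_c=fix_c, polish=polish)
            params = {"y0": p3["y0"], "b": 0.0, "t_b": float(t_b),
                      "k": p3["k"], "c": p3["c"]}
            return sse3, params
        return _piecewise_sse(t, y, family_id, t_b, fix_c=0.0, polish=polish)

    params = {"y0": y0, "t_b": float(t_b), "k": float(k), "c": c}
    if family_id == 4:
        params = {"y0": y0, "b": b, "t_b": float(t_b), "k": float(k), "c": c}
    return sse, params


def _plateau_linear_sse(t, y, t_b):
    """Family 5 at fixed t_b: linear in (y0, b), b >= 0."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tau = np.clip(t - t_b, 0.0, None)
    X = np.column_stack([np.ones_like(t), -tau])
    (y0, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    if b < 0.0:
        b = 0.0
        y0 = float(y.mean())
    yhat = y0 - b * tau
    resid = y - yhat
    return float(resid @ resid), {"y0": float(y0), "t_b": float(t_b), "b": float(b)}


def _fit_piecewise(t, y, family_id, fix_c=None):
    """Breakpoint by grid search over admissible frames + continuous refinement.

    The breakpoint t_b sits on a frame during the grid stage; each segment
    must keep at least MIN_SEGMENT_FRAMES frames.  The best grid solution is
    then polished continuously — family 5 by a bounded scalar search over
    t_b (its inner fit is exact), families 3-4 by a joint bounded
    least-squares over all parameters with t_b confined to one frame either
    side of the grid optimum (the SSE is only piecewise-smooth in t_b, so the
    local polish stays inside the bracket the grid identified).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    lo = MIN_SEGMENT_FRAMES - 1
    hi = n - 1 - MIN_SEGMENT_FRAMES
    if hi < lo:
        raise FitError("trace too short for a piecewise fit")
    dt = (t[-1] - t[0]) / (n - 1)

    if family_id == 5:
        best = None
        for i in range(lo, hi + 1):
            sse, params = _plateau_linear_sse(t, y, t[i])
            if best is None or sse < best[0]:
                best = (sse, params, i)
        sse, params, i = best
        a, b_ = max(t[lo], t[i] - dt), min(t[hi], t[i] + dt)
        if b_ > a:
            res = minimize_scalar(lambda tb: _plateau_linear_sse(t, y, tb)[0],
                                  bounds=(a, b_), method="bounded",
                                  options={"xatol": dt * 1e-9})
            sse_r, params_r = _plateau_linear_sse(t, y, float(res.x))
            if sse_r < sse:
                sse, params = sse_r, params_r
        return params, sse

    # coarse ranking of breakpoint frames with the unpolished profile, then
    # polished fits for the leading candidates (the coarse rate grid can
    # mis-rank nearby frames)
    coarse = []
    for i in range(lo, hi + 1):
        sse_i, _ = _piecewise_sse(t, y, family_id, t[i], fix_c=fix_c,
                                  polish=False)
        coarse.append((sse_i, i))
    coarse.sort()
    best = None
    for _, i in coarse[:5]:
        sse_i, params_i = _piecewise_sse(t, y, family_id, t[i], fix_c=fix_c,
                                         polish=True)
        if best is None or sse_i < best[0]:
            best = (sse_i, params_i, i)
    sse, params, i = best

    tb_lo, tb_hi = max(t[lo], t[i] - dt), min(t[hi], t[i] + dt)
    names = ["y0", "t_b", "k"] if family_id == 3 else ["y0", "b", "t_b", "k"]
    free_c = fix_c is None
    if free_c:
        names = names + ["c"]

    def unpack(x):
        p = dict(zip(names, x))
        if not free_c:
            p["c"] = float(fix_c)
        return p

    lb = {"y0": -np.inf, "b": 0.0, "t_b": tb_lo, "k": 1e-12, "c": 0.0}
    ub = {"y0": np.inf, "b": np.inf, "t_b": tb_hi, "k": np.inf, "c": np.inf}
    lo_vec = [lb[nm] for nm in names]
    hi_vec = [ub[nm] for nm in names]
    x0 = np.clip([params[nm] for nm in names], lo_vec, hi_vec)
    try:
        res = least_squares(lambda x: evaluate_family(family_id, unpack(x), t) - y,
                            x0, bounds=(lo_vec, hi_vec),
                            xtol=1e-14, ftol=1e-14, gtol=None, max_nfev=200)
        sse_r = float(2.0 * res.cost)
        if sse_r < sse:
            sse, params = sse_r, unpack(res.x)
    except Exception:
        pass
    return params, sse


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_family(time_s, values, family_id, fix_c=None):
    """Least-squares fit of one family; never raises on non-convergence.

    Parameters
    ----------
    time_s, values : arrays of equal length
    family_id : 1..5
    fix_c : float or None
        Fix the exponential floor ``c`` (families 2-4) instead of estimating it.
    """
    t = np.asarray(time_s, float)
    y = np.asarray(values, float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitError("time and values must be equal-length 1-D arrays")
    if len(t) < FAMILY_NPARAMS[family_id] + 2:
        raise FitError(f"need at least {FAMILY_NPARAMS[family_id] + 2} points "
                       f"for family {family_id}")
    try:
        if family_id == 1:
            params, sse = _fit_linear_decay(t, y)
        elif family_id == 2:
            params, sse = _fit_exponential(t, y, fix_c=fix_c)
        elif family_id in (3, 4, 5):
            params, sse = _fit_piecewise(t, y, family_id,
                                         fix_c=fix_c if family_id != 5 else None)
        else:
            raise FitError(f"unknown family id {family_id}")
        yhat = evaluate_family(family_id, params, t)
        r2, sse = _r2_sse(y, yhat)
        return FamilyFit(family_id, params, r2, sse, len(t), converged=True)
    except FitError:
        raise
    except Exception:
        return FamilyFit(family_id, {}, -np.inf, np.inf, len(t), converged=False)


def compete(time_s, values, candidate_ids=(1, 2, 3, 4, 5), fix_c=None,
            alpha=0.05, r2_tie_tol=1e-6):
    """Fit every candidate family and pick the winner.

    The raw winner is the converged fit with the highest R^2 (identical to the
    lowest SSE on the same points).  A simpler candidate then replaces it when
    the raw winner's SSE advantage is insignificant under the
    extra-sum-of-squares F-test at level ``alpha`` — without this correction a
    more flexible family always absorbs a little noise and beats the true,
    simpler law by a vanishing margin.  Exact R^2 ties (within ``r2_tie_tol``)
    also resolve toward fewer parameters.
    """
    candidate_ids = list(candidate_ids)
    if len(candidate_ids) < 2:
        raise FitError("competition needs at least 2 candidate families")
    t = np.asarray(time_s, float)
    fits = {fid: fit_family(t, values, fid, fix_c=fix_c) for fid in candidate_ids}
    ok = {fid: f for fid, f in fits.items() if f.converged}
    if not ok:
        raise FitError("all candidate fits failed")

    trace = []
    raw = max(ok.values(), key=lambda f: (f.r2, -f.n_params))
    trace.append({"step": "raw_winner", "family": raw.family_id, "r2": raw.r2,
                  "sse": raw.sse,
                  "note": "highest R^2; SSE ordering is identical by construction"})

    winner = raw
    n = raw.n_points
    noise_var = raw.sse / max(n - raw.n_params, 1)
    simpler = sorted((f for f in ok.values()
                      if f.n_params < raw.n_params and f.family_id != raw.family_id),
                     key=lambda f: (f.n_params, -f.r2))
    for cand in simpler:
        dp = raw.n_params - cand.n_params
        if abs(raw.r2 - cand.r2) <= r2_tie_tol:
            adequate = True
            fstat, fcrit = 0.0, np.inf
        elif noise_var <= 1e-300:
            adequate = cand.sse <= raw.sse + 1e-12 * max(raw.sse, 1.0)
            fstat, fcrit = np.inf, np.nan
        else:
            fstat = max(cand.sse - raw.sse, 0.0) / dp / noise_var
            fcrit = float(f_dist.ppf(1.0 - alpha, dp, n - raw.n_params))
            adequate = fstat < fcrit
        trace.append({"step": "parsimony_check", "family": cand.family_id,
                      "F": float(fstat), "F_crit": float(fcrit),
                      "adequate": bool(adequate)})
        if adequate:
            winner = cand
            trace.append({"step": "winner_replaced", "family": cand.family_id,
                          "note": "simpler family fits insignificantly worse"})
            break

    return CompetitionResult(fits=fits, winner_id=winner.family_id,
                             decision_trace=trace)


def decide_from_stats(stats):
    """Competition decision from already-printed fit statistics.

    ``stats`` maps family id -> (r2, sse).  The winner is the family with the
    highest R^2; the decision trace records whether the SSE ordering agrees
    (on fits to the same points the two orderings cannot disagree, so any
    discordance flags inconsistent reported statistics rather than a second
    criterion).
    """
    if len(stats) < 2:
        raise FitError("need at least 2 families of statistics")
    winner = max(stats, key=lambda fid: stats[fid][0])
    sse_winner = min(stats, key=lambda fid: stats[fid][1])
    trace = [{"step": "stats_winner", "family": winner,
              "r2": stats[winner][0], "sse": stats[winner][1],
              "sse_concordant": bool(sse_winner == winner)}]
    fits = {fid: FamilyFit(fid, {}, float(r2), float(sse), 0, converged=True)
            for fid, (r2, sse) in stats.items()}
    return CompetitionResult(fits=fits, winner_id=winner, decision_trace=trace)


def classify_trace(time_s, values, fix_c=None, alpha=0.05):
    """Compete all five families and return the result with its kinetic label."""
    return compete(time_s, values, candidate_ids=(1, 2, 3, 4, 5),
                   fix_c=fix_c, alpha=alpha)
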