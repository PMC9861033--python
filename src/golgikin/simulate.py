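"""Monte-Carlo simulation of post-Golgi carrier (GPC) departure.

Two planar geometries reproduce the proposal that random hit events, not
cargo diffusion, empty the Golgi zone:

* **Central Golgi** — N carriers occupy non-overlapping arcs of angular width
  w on a ring of radius R around the centrosome.  Microtubules grow one at a
  time in a uniformly random direction with a random reach; a carrier departs
  when the growth direction falls inside its arc and the reach is at least R.
  The marginal per-event departure probability of a surviving carrier is
  p = (w / 2*pi) * P(reach >= R), so the trial-averaged remaining count after
  m events is N * (1 - p)**m — exponential decay in the event index.

* **Fragmented Golgi** — N ministacks sit uniformly in a disc-shaped cell;
  each plasma-membrane hovering event picks a uniform random point, and every
  surviving ministack within the hit radius departs.  With interior placement
  (ministack capture discs fully inside the cell) the per-event hit
  probability is the area fraction q = (hit_radius / cell_radius)**2 and the
  mean remaining count is N * (1 - q)**m.

The mean curves are summarized by fitting the geometric decay law
``y = a * (1 - r)**x`` over the event index x; wall-clock time is
``x * event_interval_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CentralConfig",
    "FragmentedConfig",
    "SimResult",
    "DecayLawFit",
    "simulate_central",
    "simulate_fragmented",
    "fit_decay_law",
    "sweep",
]


@dataclass
class CentralConfig:
    """Central-Golgi geometry: carrier arcs on a ring hit by microtubule growth."""

    n_gpc: int = 20
    arc_width_rad: float = 2.0 * np.pi * 0.05
    ring_radius: float = 1.0
    #: microtubule reach distribution: ("certain",), ("point", L),
    #: ("exponential", scale) or ("uniform", low, high)
    mt_length_dist: tuple = ("certain",)
    event_interval_s: float = 6.0
    n_events: int = 60
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_gpc < 1:
            raise ValueError("need at least one carrier")
        if not (0.0 < self.arc_width_rad <= 2.0 * np.pi / self.n_gpc):
            raise ValueError("arcs must be positive and non-overlapping "
                             "(w <= 2*pi/N)")
        if self.event_interval_s <= 0:
            raise ValueError("event_interval_s must be > 0")

    def reach_survival_prob(self) -> float:
        """P(reach >= ring_radius) under the configured distribution."""
        kind = self.mt_length_dist[0]
        if kind == "certain":
            return 1.0
        if kind == "point":
            return 1.0 if self.mt_length_dist[1] >= self.ring_radius else 0.0
        if kind == "exponential":
            return float(np.exp(-self.ring_radius / self.mt_length_dist[1]))
        if kind == "uniform":
            lo, hi = self.mt_length_dist[1:3]
            return float(np.clip((hi - self.ring_radius) / (hi - lo), 0.0, 1.0))
        raise ValueError(f"unknown reach distribution {kind!r}")

    @property
    def hit_prob(self) -> float:
        """Marginal per-event departure probability of a surviving carrier."""
        return self.arc_width_rad / (2.0 * np.pi) * self.reach_survival_prob()


@dataclass
class FragmentedConfig:
    """Fragmented-Golgi geometry: ministacks in a disc hit by hovering events."""

    cell_radius: float = 10.0
    n_ministacks: int = 30
    hit_radius: float = 10.0 * np.sqrt(0.02)
    event_interval_s: float = 6.0
    n_events: int = 60
    n_trials: int = 1000
    interior_placement: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.hit_radius < self.cell_radius):
            raise ValueError("hit_radius must be positive and below cell_radius")
        if self.n_ministacks < 1:
            raise ValueError("need at least one ministack")

    @property
    def hit_prob(self) -> float:
        """Per-event hit probability of one ministack (exact for interior placement)."""
        return (self.hit_radius / self.cell_radius) ** 2


@dataclass
class SimResult:
    remaining: np.ndarray        # (n_trials, n_events + 1) remaining counts
    mean_curve: np.ndarray       # trial-mean remaining count vs event index
    hit_prob: float              # analytic per-event marginal departure prob.
    config: object = field(repr=False, default=None)

    @property
    def event_index(self) -> np.ndarray:
        return np.arange(self.remaining.shape[1], dtype=float)

    @property
    def time_s(self) -> np.ndarray:
        return self.event_index * self.config.event_interval_s

    def sem_curve(self) -> np.ndarray:
        """Standard error of the trial mean at every event index."""
        return self.remaining.std(axis=0, ddof=1) / np.sqrt(self.remaining.shape[0])


@dataclass
class DecayLawFit:
    a: float
    r: float
    r2: float


def _departure_series(first_hit_events, n, m):
    """Remaining-count series from each carrier's first-hit event (or -1)."""
    remaining = np.full(m + 1, float(n))
    hits = first_hit_events[first_hit_events >= 0]
    if hits.size:
        counts = np.bincount(hits + 1, minlength=m + 1)
        remaining -= np.cumsum(counts)
    return remaining


def simulate_central(cfg: CentralConfig) -> SimResult:
    """Run the central-Golgi microtubule-hit simulation."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_gpc, cfg.n_events
    sector = 2.0 * np.pi / n
    half_w = cfg.arc_width_rad / 2.0
    out = np.empty((cfg.n_trials, m + 1))
    for trial in range(cfg.n_trials):
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        reach_ok = _draw_reach_ok(rng, cfg, m)
        nearest = np.rint(theta / sector).astype(int) % n
        offset = np.abs((theta - nearest * sector + np.pi) % (2.0 * np.pi) - np.pi)
        hit_carrier = np.where((offset <= half_w) & reach_ok, nearest, -1)
        first = np.full(n, -1)
        for ev in range(m):
            c = hit_carrier[ev]
            if c >= 0 and first[c] < 0:
                first[c] = ev
        out[trial] = _departure_series(first[first >= 0], n, m)
    return SimResult(remaining=out, mean_curve=out.mean(axis=0),
                     hit_prob=cfg.hit_prob, config=cfg)


def _draw_reach_ok(rng, cfg: CentralConfig, m: int):
    kind = cfg.mt_length_dist[0]
    if kind == "certain":
        return np.ones(m, dtype=bool)
    if kind == "point":
        return np.full(m, cfg.mt_length_dist[1] >= cfg.ring_radius)
    if kind == "exponential":
        return rng.exponential(cfg.mt_length_dist[1], m) >= cfg.ring_radius
    if kind == "uniform":
        lo, hi = cfg.mt_length_dist[1:3]
        return rng.uniform(lo, hi, m) >= cfg.ring_radius
    raise ValueError(f"unknown reach distribution {kind!r}")


def simulate_fragmented(cfg: FragmentedConfig) -> SimResult:
    """Run the fragmented-Golgi hovering-hit simulation."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_ministacks, cfg.n_events
    place_r = cfg.cell_radius - cfg.hit_radius if cfg.interior_placement \
        else cfg.cell_radius
    out = np.empty((cfg.n_trials, m + 1))
    for trial in range(cfg.n_trials):
        pos = _uniform_disc(rng, n, place_r)
        pts = _uniform_disc(rng, m, cfg.cell_radius)
        d2 = ((pts[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        hit = d2 <= cfg.hit_radius ** 2          # (m, n)
        any_hit = hit.any(axis=0)
        first = np.where(any_hit, hit.argmax(axis=0), -1)
        out[trial] = _departure_series(first[first >= 0], n, m)
    return SimResult(remaining=out, mean_curve=out.mean(axis=0),
                     hit_prob=cfg.hit_prob, config=cfg)


def _uniform_disc(rng, n, radius):
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def fit_decay_law(result) -> DecayLawFit:
    """Least-squares fit of y = a*(1-r)**x to a trial-mean remaining curve.

    ``result`` may be a :class:`SimResult` or a bare mean curve indexed by
    event number.
    """
    y = result.mean_curve if hasattr(result, "mean_curve") else np.asarray(result, float)
    x = np.arange(len(y), dtype=float)
    if np.ptp(y) <= 0:
        raise ValueError("degenerate (constant) mean curve")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        r0 = float(np.clip(1.0 - np.exp(slope), 1e-9, 1.0 - 1e-9))
        a0 = float(np.exp(intercept))
    else:
        r0, a0 = 0.05, float(y[0])
    popt, _ = curve_fit(lambda xx, a, r: a * (1.0 - r) ** xx, x, y,
                        p0=[a0, r0], bounds=([0.0, 0.0], [np.inf, 1.0 - 1e-12]),
                        maxfev=10000)
    a, r = float(popt[0]), float(popt[1])
    resid = y - a * (1.0 - r) ** x
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    return DecayLawFit(a=a, r=r, r2=r2)


def sweep(configs):
    """Run several configurations and collate mean curves with decay-law fits.

    Returns a list of ``(config, SimResult, DecayLawFit)`` triples.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("a sweep needs at least 2 configurations")
    rows = []
    for cfg in configs:
        res = simulate_central(cfg) if isinstance(cfg, CentralConfig) \
            else simulate_fragmented(cfg)
        rows.append((cfg, res, fit_decay_law(res)))
    return rows
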