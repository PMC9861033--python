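"""Synthetic fluorescence-trace generator.

Emulates time-lapse ROI intensity recordings from a confocal FRAP/iFRAP
experiment so the whole analysis chain can be exercised without microscope
data: a ground-truth kinetic law (one of the five curve families), an
additive background, multiplicative fluorophore fading accrued per exposure,
an instantaneous bleach step in the reference channel, i.i.d. Gaussian
per-frame noise, and replicate-to-replicate jitter in plateau length and
acquisition start delay.  Frames are sampled every 6 s by default and a
condition is typically recorded as 6 replicates, matching the acquisition
regime the analysis was designed for.

Seeding: every generator takes an integer seed; replicate sets derive child
seeds from the master seed via ``numpy.random.SeedSequence(seed).spawn``,
so a replicate set is bit-reproducible from its master seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .families import evaluate_family, FAMILY_NPARAMS

__all__ = [
    "GroundTruth",
    "AcquisitionModel",
    "RawTraceSet",
    "generate_trace",
    "generate_replicate_set",
    "generate_frap_recovery",
]


@dataclass
class GroundTruth:
    """Noise-free kinetic law behind a trace.

    ``plateau_len_s`` is a convenience that, when set, overrides the
    breakpoint parameter ``t_b`` of the piecewise families (3, 4, 5);
    ``start_delay_s`` shifts the whole curve right, holding its initial value,
    which emulates the operator-dependent lag before the recording catches the
    process.
    """

    family_id: int
    params: dict
    plateau_len_s: float = 0.0
    start_delay_s: float = 0.0

    def __post_init__(self):
        if self.family_id not in FAMILY_NPARAMS:
            raise ValueError(f"family_id must be 1..5, got {self.family_id}")
        if self.plateau_len_s < 0 or self.start_delay_s < 0:
            raise ValueError("plateau_len_s and start_delay_s must be >= 0")
        for name in ("b", "k"):
            if name in self.params and not self.params[name] > 0:
                raise ValueError(f"rate/slope parameter {name!r} must be > 0")

    def effective_params(self) -> dict:
        p = dict(self.params)
        if self.family_id in (3, 4, 5) and self.plateau_len_s > 0:
            p["t_b"] = float(self.plateau_len_s)
        return p

    def curve(self, time_s):
        """Evaluate the ground-truth curve on a time grid (seconds)."""
        t = np.asarray(time_s, dtype=float)
        shifted = np.clip(t - self.start_delay_s, 0.0, None)
        p = self.effective_params()
        if self.family_id in (3, 4, 5):
            # the evaluator validates t_b against the window; extend it so a
            # delayed curve whose breakpoint falls late stays evaluable
            return evaluate_family(self.family_id, p,
                                   np.concatenate([[p["t_b"]], shifted]))[1:]
        return evaluate_family(self.family_id, p, shifted)

    @property
    def breakpoint_time_s(self):
        """Time at which the decay segment starts, or None for families 1-2."""
        p = self.effective_params()
        if "t_b" in p:
            return float(p["t_b"]) + self.start_delay_s
        return None


@dataclass
class AcquisitionModel:
    """Instrument model applied on top of the ground-truth curve."""

    dt_s: float = 6.0
    n_frames: int = 60
    fade_rate: float = 0.0          # per-frame multiplicative fading fraction
    background_level: float = 0.0   # intensity units
    bleach_frame: int = 0           # index of the first post-bleach frame
    bleach_depth: float = 0.0       # fraction of reference intensity removed
    noise_sd: float = 0.0           # intensity units, homoscedastic Gaussian
    reference_level: float = 100.0  # pre-bleach reference-region intensity
    seed: int = 0

    def __post_init__(self):
        if not self.dt_s > 0:
            raise ValueError("dt_s must be > 0")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if not (0.0 <= self.bleach_depth < 1.0):
            raise ValueError("bleach_depth must be in [0, 1)")
        if not (0 <= self.bleach_frame < self.n_frames):
            raise ValueError("bleach_frame must lie inside the recording")
        for name in ("fade_rate", "background_level", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    @property
    def time_s(self):
        return np.arange(self.n_frames, dtype=float) * self.dt_s

    def fade(self):
        """Per-frame fading envelope (1 - fade_rate)**frame."""
        return (1.0 - self.fade_rate) ** np.arange(self.n_frames, dtype=float)


@dataclass
class RawTraceSet:
    """Per-frame ROI mean intensities: FRAP region, reference, background."""

    time_s: np.ndarray
    ifr: np.ndarray
    irr: np.ndarray
    ibr: np.ndarray
    irr_pre: float
    irr_after: float
    bleach_frame: int
    truth: GroundTruth | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.time_s)
        if not (len(self.ifr) == len(self.irr) == len(self.ibr) == n):
            raise ValueError("all channels must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self):
        return len(self.time_s)


def generate_trace(truth: GroundTruth, acq: AcquisitionModel) -> RawTraceSet:
    """Render one raw trace set from a ground truth and an acquisition model.

    Channel models (frame index j, fade(j) = (1-fade_rate)**j):

    * ``ifr(j) = (truth(t_j) + background) * fade(j) + eps``
    * ``irr(j) = reference_level * fade(j) * (1 - bleach_depth if j >= bleach_frame)``
    * ``ibr(j) = background * fade(j) + eps``

    with eps ~ N(0, noise_sd) i.i.d. per frame.  The reference channel
    carries fading and the bleach step but neither cargo signal nor noise
    (the reference ROI is taken large enough that its shot noise is
    negligible), so the correction can reconstruct the truth curve exactly
    in the noiseless case.
    """
    rng = np.random.default_rng(acq.seed)
    t = acq.time_s
    fade = acq.fade()
    signal = truth.curve(t)
    if not np.all(np.isfinite(signal)):
        raise ValueError("ground-truth curve evaluates to non-finite values")

    bleach = np.ones(acq.n_frames)
    bleach[acq.bleach_frame:] = 1.0 - acq.bleach_depth

    ifr = (signal + acq.background_level) * fade
    irr = acq.reference_level * fade * bleach
    ibr = acq.background_level * fade

    if acq.noise_sd > 0:
        ifr = ifr + rng.normal(0.0, acq.noise_sd, acq.n_frames)
        ibr = ibr + rng.normal(0.0, acq.noise_sd, acq.n_frames)

    j = acq.bleach_frame
    irr_pre = float(acq.reference_level * fade[max(j - 1, 0)])
    irr_after = float(acq.reference_level * fade[j] * (1.0 - acq.bleach_depth))
    return RawTraceSet(time_s=t, ifr=ifr, irr=irr, ibr=ibr,
                       irr_pre=irr_pre, irr_after=irr_after,
                       bleach_frame=j, truth=truth)


def generate_replicate_set(truth: GroundTruth, acq: AcquisitionModel,
                           n_reps: int = 6, plateau_jitter_s: float = 0.0,
                           delay_jitter_s: float = 0.0, seed: int = 0):
    """Generate ``n_reps`` replicates sharing the kinetic law.

    Each replicate draws its plateau length (families 3-5) and start delay
    from uniform windows ``[base, base + jitter]``, emulating the
    heterogeneous horizontal initial parts of real replicate series.  Child
    seeds come from ``SeedSequence(seed).spawn(n_reps)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if plateau_jitter_s < 0 or delay_jitter_s < 0:
        raise ValueError("jitter windows must be >= 0")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_reps)
    jit_rng = np.random.default_rng(master.spawn(1)[0])
    traces = []
    for child in children:
        plateau = truth.plateau_len_s
        if plateau_jitter_s > 0 and truth.family_id in (3, 4, 5):
            base = plateau if plateau > 0 else truth.effective_params().get("t_b", 0.0)
            plateau = base + jit_rng.uniform(0.0, plateau_jitter_s)
        delay = truth.start_delay_s
        if delay_jitter_s > 0:
            delay = delay + jit_rng.uniform(0.0, delay_jitter_s)
        truth_j = replace(truth, plateau_len_s=plateau, start_delay_s=delay)
        acq_j = replace(acq, seed=int(child.generate_state(1)[0] % (2**31)))
        traces.append(generate_trace(truth_j, acq_j))
    return traces


def generate_frap_recovery(fm: float, k: float, acq: AcquisitionModel) -> RawTraceSet:
    """Trace whose FRAP channel recovers as Fm*(1 - exp(-k*t)) after the bleach.

    Pre-bleach frames sit at the plateau Fm; recovery time is measured from
    the first post-bleach frame.  Background, fading and noise apply as in
    :func:`generate_trace`.
    """
    if not (fm > 0 and k > 0):
        raise ValueError("Fm and k must be > 0")
    rng = np.random.default_rng(acq.seed)
    t = acq.time_s
    fade = acq.fade()
    j = acq.bleach_frame
    rel = np.clip(t - t[j], 0.0, None)
    signal = np.where(np.arange(acq.n_frames) < j, fm, fm * (1.0 - np.exp(-k * rel)))

    bleach = np.ones(acq.n_frames)
    bleach[j:] = 1.0 - acq.bleach_depth
    ifr = (signal + acq.background_level) * fade
    irr = acq.reference_level * fade * bleach
    ibr = acq.background_level * fade
    if acq.noise_sd > 0:
        ifr = ifr + rng.normal(0.0, acq.noise_sd, acq.n_frames)
        ibr = ibr + rng.normal(0.0, acq.noise_sd, acq.n_frames)
    irr_pre = float(acq.reference_level * fade[max(j - 1, 0)])
    irr_after = float(acq.reference_level * fade[j] * (1.0 - acq.bleach_depth))
    return RawTraceSet(time_s=t, ifr=ifr, irr=irr, ibr=ibr,
                       irr_pre=irr_pre, irr_after=irr_after, bleach_frame=j)
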