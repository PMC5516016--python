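"""Experimental design: trial schedules and driving/modulatory input regressors.

The emulated task is a retro-cue imagery paradigm: on each trial two of six
stimuli (two faces, two letters, two fruits) are shown for 2 s each, separated
by a jittered inter-stimulus interval; after a jittered fixation period a cue
indicates which stimulus to imagine inside a 3.5 s frame, followed by a
vividness rating (1-4) and a 4 s baseline.  Perception and imagery enter the
dynamic model as boxcar inputs; trial-wise vividness enters as a parametric
modulator that is mean-centred within stimulus category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STIMULI",
    "TimingConfig",
    "Event",
    "Trial",
    "EventSchedule",
    "InputSeries",
    "generate_trial_schedule",
    "build_input_regressors",
    "mean_center_by_category",
    "canonical_hrf",
    "convolve_hrf",
    "resample_to_scans",
    "design_cosine",
]

#: stimulus identifier -> category
STIMULI = {
    "face1": "face",
    "face2": "face",
    "letterD": "letter",
    "letterI": "letter",
    "banana": "fruit",
    "apple": "fruit",
}

EVENT_LABELS = ("stim1", "isi", "stim2", "fix", "cue", "frame", "rating", "baseline")


@dataclass(frozen=True)
class TimingConfig:
    """Event durations (seconds).  Ranges are sampled uniformly per trial."""

    stim_duration: float = 2.0
    isi_range: tuple[float, float] = (1.0, 3.0)
    fix_range: tuple[float, float] = (1.0, 3.0)
    cue_duration: float = 0.5
    frame_duration: float = 3.5
    rating_duration: float = 2.0
    baseline_duration: float = 4.0

    def validate(self) -> None:
        for name in ("stim_duration", "cue_duration", "frame_duration",
                     "rating_duration", "baseline_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("isi_range", "fix_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class Event:
    label: str
    onset: float
    duration: float
    trial_index: int


@dataclass(frozen=True)
class Trial:
    index: int
    category: str
    cued_stimulus: str
    stimuli: tuple[str, str]


@dataclass
class EventSchedule:
    """Ordered event list plus per-trial metadata for one scanning session."""

    events: list[Event]
    trials: list[Trial]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration

    @property
    def categories(self) -> list[str]:
        return [t.category for t in self.trials]

    def events_of(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def validate(self) -> None:
        prev_end = -1e-9
        for e in self.events:
            if e.duration < 0:
                raise ValueError(f"negative duration for event {e}")
            if e.onset < prev_end - 1e-9:
                raise ValueError(f"overlapping events at onset {e.onset}")
            prev_end = e.onset + e.duration
        for t in self.trials:
            frames = [e for e in self.events
                      if e.trial_index == t.index and e.label == "frame"]
            stims = [e for e in self.events
                     if e.trial_index == t.index and e.label in ("stim1", "stim2")]
            if len(frames) != 1:
                raise ValueError(f"trial {t.index} has {len(frames)} frame events")
            if len(stims) != 2:
                raise ValueError(f"trial {t.index} has {len(stims)} stimulus events")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        trial_by_index = {t.index: t for t in self.trials}
        for e in self.events:
            t = trial_by_index[e.trial_index]
            rows.append((e.onset, e.duration, e.label, e.trial_index,
                         t.category, t.cued_stimulus))
        return pd.DataFrame(
            rows,
            columns=["onset", "duration", "trial_type", "trial_index",
                     "category", "cued_stimulus"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSchedule":
        required = {"onset", "duration", "trial_type", "trial_index"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        events = [
            Event(str(r.trial_type), float(r.onset), float(r.duration),
                  int(r.trial_index))
            for r in df.itertuples()
        ]
        trials = []
        for idx in sorted(df["trial_index"].unique()):
            sub = df[df["trial_index"] == idx]
            category = str(sub["category"].iloc[0]) if "category" in df.columns else "unknown"
            cued = str(sub["cued_stimulus"].iloc[0]) if "cued_stimulus" in df.columns else "unknown"
            trials.append(Trial(int(idx), category, cued, (cued, cued)))
        sched = cls(events=events, trials=trials)
        sched.validate()
        return sched


@dataclass
class InputSeries:
    """Experimental inputs on a microtime grid (one column per input)."""

    names: list[str]
    u: np.ndarray          # (n_bins, n_inputs)
    dt: float              # bin width, seconds

    @property
    def n_bins(self) -> int:
        return self.u.shape[0]

    @property
    def total_duration(self) -> float:
        return self.n_bins * self.dt

    def column(self, name: str) -> np.ndarray:
        return self.u[:, self.names.index(name)]


def _balanced_pool(stimuli: list[str], n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws in which each stimulus appears floor(n/6) or ceil(n/6) times."""
    k, r = divmod(n, len(stimuli))
    pool = np.repeat(stimuli, k)
    if r:
        extra = rng.choice(stimuli, size=r, replace=False)
        pool = np.concatenate([pool, extra])
    rng.shuffle(pool)
    return pool


def generate_trial_schedule(
    n_trials: int,
    timing: TimingConfig | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> EventSchedule:
    """Generate a randomised, stimulus-balanced trial schedule.

    Each of the six stimuli serves as the imagery target on (as close as
    possible to) ``n_trials/6`` trials and is perceived ``2 n_trials/6``
    times in total, so a 180-trial session shows each stimulus 60 times and
    has it imagined 30 times.  ISI and pre-cue fixation are drawn uniformly
    from their configured ranges.
    """
    if n_trials < 0:
        raise ValueError(f"n_trials must be >= 0, got {n_trials}")
    timing = timing or TimingConfig()
    timing.validate()
    rng = np.random.default_rng(rng_seed)
    stimuli = list(STIMULI)

    cued = _balanced_pool(stimuli, n_trials, rng)
    other = _balanced_pool(stimuli, n_trials, rng)
    # repair trials whose two stimuli coincide by swapping with another trial
    for i in range(n_trials):
        if other[i] != cued[i]:
            continue
        for j in rng.permutation(n_trials):
            if other[j] != cued[i] and other[i] != cued[j]:
                other[i], other[j] = other[j], other[i]
                break

    events: list[Event] = []
    trials: list[Trial] = []
    t = 0.0
    for i in range(n_trials):
        cue_first = rng.random() < 0.5
        pair = (cued[i], other[i]) if cue_first else (other[i], cued[i])
        isi = rng.uniform(*timing.isi_range)
        fix = rng.uniform(*timing.fix_range)
        for label, dur in (
            ("stim1", timing.stim_duration),
            ("isi", isi),
            ("stim2", timing.stim_duration),
            ("fix", fix),
            ("cue", timing.cue_duration),
            ("frame", timing.frame_duration),
            ("rating", timing.rating_duration),
            ("baseline", timing.baseline_duration),
        ):
            events.append(Event(label, t, dur, i))
            t += dur
        trials.append(Trial(i, STIMULI[cued[i]], cued[i], pair))

    sched = EventSchedule(events=events, trials=trials)
    sched.validate()
    return sched


def mean_center_by_category(
    scores: np.ndarray, categories: list[str] | np.ndarray
) -> np.ndarray:
    """Remove the per-category mean from trial-wise vividness scores.

    Stimulus category systematically shifts reported vividness, so the
    category mean is regressed out before the scores enter the model as a
    parametric modulator.  Idempotent; within-category contrasts unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    categories = np.asarray(categories)
    if scores.shape[0] != categories.shape[0]:
        raise ValueError("scores and categories must have equal length")
    if scores.size == 0:
        raise ValueError("empty category group")
    centred = scores.copy()
    for cat in np.unique(categories):
        mask = categories == cat
        if not mask.any():
            raise ValueError(f"empty category group {cat!r}")
        centred[mask] -= scores[mask].mean()
    return centred


def build_input_regressors(
    schedule: EventSchedule,
    vividness: np.ndarray | None = None,
    dt: float = 0.1,
    center_vividness: bool = True,
) -> InputSeries:
    """Build perception/imagery boxcars and the vividness parametric input.

    Perception is 1 during both stimulus presentations, imagery is 1 during
    the imagery frame, and the vividness input carries the (per-category
    mean-centred) trial rating during the frame, zero elsewhere.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    durations = [e.duration for e in schedule.events if e.duration > 0]
    if durations and dt > min(durations):
        raise ValueError(
            f"dt={dt} exceeds the shortest event duration {min(durations)}; "
            "events would be lost"
        )
    if vividness is None:
        vividness = np.zeros(schedule.n_trials)
    vividness = np.asarray(vividness, dtype=float)
    if vividness.shape[0] != schedule.n_trials:
        raise ValueError("vividness must have one score per trial")
    if center_vividness and schedule.n_trials:
        vividness = mean_center_by_category(vividness, schedule.categories)

    n_bins = int(round(schedule.total_duration / dt)) if schedule.events else 0
    u = np.zeros((n_bins, 3))
    for e in schedule.events:
        lo = int(round(e.onset / dt))
        hi = int(round((e.onset + e.duration) / dt))
        hi = min(hi, n_bins)
        if e.label in ("stim1", "stim2"):
            u[lo:hi, 0] = 1.0
        elif e.label == "frame":
            u[lo:hi, 1] = 1.0
            u[lo:hi, 2] = vividness[e.trial_index]
    return InputSeries(names=["perception", "imagery", "vividness"], u=u, dt=dt)


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    Difference of two gamma densities (response peak ~6 s, undershoot ~16 s,
    undershoot ratio 1/6), sampled at ``dt`` and normalised to unit sum.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0, duration, dt)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.sum()


def convolve_hrf(u: np.ndarray, dt: float, hrf: np.ndarray | None = None) -> np.ndarray:
    """Convolve a microtime regressor with the canonical HRF (causal)."""
    if hrf is None:
        hrf = canonical_hrf(dt)
    return np.convolve(u, hrf)[: len(u)]


def resample_to_scans(x: np.ndarray, dt: float, tr: float,
                      slice_offset: float = 0.0) -> np.ndarray:
    """Sample a microtime signal at scan times ``(k + slice_offset) * TR``."""
    duration = len(x) * dt
    n_scans = int(np.floor(duration / tr))
    times = (np.arange(n_scans) + slice_offset) * tr
    grid = np.arange(len(x)) * dt
    return np.interp(times, grid, x)


def design_cosine(
    u1: np.ndarray,
    u2: np.ndarray,
    dt: float = 0.1,
    convolve: bool = True,
    tr: float | None = 2.0,
    hrf: np.ndarray | None = None,
) -> float:
    """Absolute cosine of the angle between two design regressors.

    By default both regressors are convolved with the canonical HRF and
    resampled at scan times before the angle is taken, mirroring how a
    design-orthogonality check is read off a first-level GLM.
    """
    a, b = np.asarray(u1, dtype=float), np.asarray(u2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("regressors must have equal length")
    if convolve:
        a, b = convolve_hrf(a, dt, hrf), convolve_hrf(b, dt, hrf)
        if tr is not None:
            a = resample_to_scans(a, dt, tr)
            b = resample_to_scans(b, dt, tr)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm regressor")
    return float(abs(a @ b) / (na * nb))
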