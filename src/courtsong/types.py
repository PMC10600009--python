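"""Shared containers for trajectories, song annotations, taps and trials.

Conventions used throughout the package:

- All times are float seconds from recording start (one clock for video-
  and audio-derived events; no frame or sample indices in interfaces).
- Time intervals are half-open ``[start, end)``.
- A *train* is a contiguous run of one song mode (pulse or sine); a *bout*
  is an ordered list of trains. "Simple" bouts contain one mode only,
  "complex" bouts at least one pulse<->sine alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The six bout types used as the fitting target: simple pulse, one
#: pulse->sine alternation, two or more alternations starting with pulse,
#: and the sine-leading counterparts.
SIX_TYPES: tuple[str, ...] = ("p", "ps", "psp...", "s", "sp", "sps...")

#: Collapsed four-category form (leading mode x simple/complex).
CATEGORIES: tuple[str, ...] = ("simple_p", "simple_s", "complex_p", "complex_s")

PULSE = "pulse"
SINE = "sine"

#: Column order of the canonical trajectory CSV.
TRAJECTORY_FIELDS: tuple[str, ...] = (
    "t", "mfDist", "mfAngle", "fmAngle",
    "mFV", "fFV", "mLS", "fLS", "mRS", "fRS",
)


def collapse_modes(modes: list[str]) -> str:
    """Run-length collapse a mode sequence into a label string.

    Adjacent same-mode trains contribute a single letter: labels describe
    mode alternations, not train counts (merging close bouts can create
    adjacent trains of the same mode).
    """
    out: list[str] = []
    for m in modes:
        initial = {PULSE: "p", SINE: "s"}[m]
        if not out or out[-1] != initial:
            out.append(initial)
    return "".join(out)


def label_to_six_type(label: str) -> str:
    """Map a full label ('p', 'ps', 'psps', ...) to one of the six types."""
    if not label:
        raise ValueError("empty bout label")
    if len(label) <= 2:
        return label
    return label[0] + ("sp..." if label[0] == "p" else "ps...")


def label_to_category(label: str) -> str:
    """Map a full label to simple_/complex_ x leading-mode category."""
    if not label:
        raise ValueError("empty bout label")
    kind = "simple" if len(label) == 1 else "complex"
    return f"{kind}_{label[0]}"


@dataclass
class Train:
    """A contiguous pulse or sine train within a bout.

    ``events`` holds pulse-center times for pulse trains (empty for sine).
    ``amplitude`` is the train's amplitude statistic (99th percentile of
    the absolute signal over the loudest microphone, same convention as the
    noise amplitude); NaN when not available (e.g. model-decoded song).
    """

    mode: str
    start: float
    end: float
    amplitude: float = float("nan")
    events: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in (PULSE, SINE):
            raise ValueError(f"unknown train mode {self.mode!r}")
        if self.end < self.start:
            raise ValueError("train end precedes start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Bout:
    """An ordered list of trains forming one song bout."""

    trains: list[Train]

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValueError("bout must contain at least one train")
        starts = [tr.start for tr in self.trains]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("trains within a bout must be time-ordered")

    @property
    def start(self) -> float:
        return self.trains[0].start

    @property
    def end(self) -> float:
        return max(tr.end for tr in self.trains)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def label(self) -> str:
        """Mode-alternation label, e.g. 'p', 'ps', 'psp'."""
        return collapse_modes([tr.mode for tr in self.trains])

    @property
    def six_type(self) -> str:
        return label_to_six_type(self.label)

    @property
    def category(self) -> str:
        return label_to_category(self.label)


@dataclass
class SongAnnotation:
    """Ordered, non-overlapping song bouts plus an optional noise snippet.

    ``noise_segment`` is a (channels, samples) array of raw amplitude
    samples not containing song, used to estimate the noise floor.
    """

    bouts: list[Bout]
    noise_segment: np.ndarray | None = None
    clock_origin: float = 0.0

    def __post_init__(self) -> None:
        ends = [b.end for b in self.bouts]
        starts = [b.start for b in self.bouts]
        for prev_end, nxt_start in zip(ends, starts[1:]):
            if nxt_start < prev_end:
                raise ValueError("bouts must be non-overlapping and time-ordered")
        if self.noise_segment is not None:
            self.noise_segment = np.atleast_2d(np.asarray(self.noise_segment, float))

    def __len__(self) -> int:
        return len(self.bouts)

    def replace_bouts(self, bouts: list[Bout]) -> "SongAnnotation":
        return SongAnnotation(
            bouts=bouts,
            noise_segment=self.noise_segment,
            clock_origin=self.clock_origin,
        )


@dataclass
class CourtshipTrajectory:
    """Male/female kinematic features on a uniform video clock.

    Units: t in seconds, mfDist in mm, angles in degrees in [0, 180],
    forward velocities and lateral speeds in mm/s, rotational speeds in
    rad/s. mfAngle is the angle of the female thorax relative to the male
    body axis; fmAngle the converse.
    """

    t: np.ndarray
    mfDist: np.ndarray
    mfAngle: np.ndarray
    fmAngle: np.ndarray
    mFV: np.ndarray
    fFV: np.ndarray
    mLS: np.ndarray
    fLS: np.ndarray
    mRS: np.ndarray
    fRS: np.ndarray

    def __post_init__(self) -> None:
        for name in TRAJECTORY_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), float))
        n = self.t.size
        if n == 0:
            raise ValueError("empty trajectory")
        for name in TRAJECTORY_FIELDS:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name} shape mismatch")
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"field {name} contains non-finite samples")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-7):
                raise ValueError("t must lie on a uniform grid")
        if np.any(self.mfDist <= 0):
            raise ValueError("mfDist must be positive")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def frame_rate(self) -> float:
        if self.t.size < 2:
            raise ValueError("frame rate undefined for single-sample trajectory")
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def feature(self, name: str) -> np.ndarray:
        if name not in TRAJECTORY_FIELDS or name == "t":
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class TapSeries:
    """Binary foreleg-tap indicator per video frame (shares the video clock)."""

    t: np.ndarray
    is_tap: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.is_tap = np.asarray(self.is_tap)
        if self.t.shape != self.is_tap.shape:
            raise ValueError("t and is_tap must have equal length")
        if not np.all((self.is_tap == 0) | (self.is_tap == 1)):
            raise ValueError("is_tap must be binary")
        self.is_tap = self.is_tap.astype(np.int8)

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def tap_times(self) -> np.ndarray:
        return self.t[self.is_tap == 1]


@dataclass
class Trial:
    """One optogenetic stimulation trial within a block."""

    block_id: int
    irradiance: float
    duty_cycle: float
    t_start: float
    t_end: float
    stim_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for on, off in self.stim_intervals:
            if not (self.t_start <= on <= off <= self.t_end):
                raise ValueError("stimulus interval outside trial window")


@dataclass
class TrialSet:
    """All trials of an optogenetic session, in presentation order."""

    trials: list[Trial]

    def __len__(self) -> int:
        return len(self.trials)

    def stim_intervals(self) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = []
        for tr in self.trials:
            out.extend(tr.stim_intervals)
        return sorted(out)


@dataclass
class BoutDistribution:
    """Normalized counts over the six bout types (optionally per context).

    ``counts`` maps each of :data:`SIX_TYPES` to a raw count; ``freqs``
    to the normalized frequency (NaN for all types when ``n_bout == 0``,
    flagged via :attr:`defined`).
    """

    counts: dict[str, int]
    context: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SIX_TYPES)
        if unknown:
            raise ValueError(f"unknown bout types {sorted(unknown)}")
        self.counts = {k: int(self.counts.get(k, 0)) for k in SIX_TYPES}

    @property
    def n_bout(self) -> int:
        return sum(self.counts.values())

    @property
    def defined(self) -> bool:
        return self.n_bout > 0

    @property
    def freqs(self) -> dict[str, float]:
        n = self.n_bout
        if n == 0:
            return {k: float("nan") for k in SIX_TYPES}
        return {k: v / n for k, v in self.counts.items()}

    def as_vector(self) -> np.ndarray:
        """Frequencies in :data:`SIX_TYPES` order."""
        f = self.freqs
        return np.array([f[k] for k in SIX_TYPES])


__all__ = [
    "SIX_TYPES",
    "CATEGORIES",
    "PULSE",
    "SINE",
    "TRAJECTORY_FIELDS",
    "collapse_modes",
    "label_to_six_type",
    "label_to_category",
    "Train",
    "Bout",
    "SongAnnotation",
    "CourtshipTrajectory",
    "TapSeries",
    "Trial",
    "TrialSet",
    "BoutDistribution",
    "replace",
]
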