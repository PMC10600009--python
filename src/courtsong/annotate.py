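"""Song post-processing and behavioral sequence statistics.

Implements the analysis applied to segmented courtship song: exclusion of
bouts with low-SNR sine song, merging of artificially split bouts,
sequence labeling ('p', 'ps', 'psp', ...), far/near context assignment by
male–female distance, bout-type distributions, trial-wise song
probabilities for optogenetic sessions, rebound-song classification, and
bout-triggered tap-rate statistics.

Boundary conventions follow the "below" wording of the procedures they
implement and are strict: SNR < 1.3 excludes a bout, inter-bout gap
< 0.5 s merges, mean mfDist < 4 mm is "near" (a mean of exactly 4 mm is
"far").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from courtsong.types import (
    SINE,
    SIX_TYPES,
    Bout,
    BoutDistribution,
    CourtshipTrajectory,
    SongAnnotation,
    TapSeries,
    Train,
    TrialSet,
    label_to_category,
)

SNR_THRESHOLD = 1.3
MERGE_GAP_S = 0.5
CONTEXT_THRESHOLD_MM = 4.0


def noise_amplitude(noise_segment: np.ndarray) -> float:
    """Noise floor of a multi-microphone noise snippet.

    The (channels, samples) segment is reduced to one dimension by taking
    the loudest microphone (largest absolute value) at each time point;
    the noise amplitude is the 99th percentile of the absolute value of
    that vector (linear interpolation between order statistics).
    """
    seg = np.atleast_2d(np.asarray(noise_segment, float))
    if seg.size == 0:
        raise ValueError("noise segment is empty")
    loudest = np.take_along_axis(
        seg, np.argmax(np.abs(seg), axis=0)[None, :], axis=0
    )[0]
    return float(np.percentile(np.abs(loudest), 99))


def sine_snr(bout: Bout, noise_amp: float) -> list[float]:
    """Per-sine-train SNR: train amplitude (same 99th-percentile-of-|x|
    convention as the noise amplitude) divided by ``noise_amp``.

    Pulse-only bouts yield an empty list.
    """
    if noise_amp <= 0:
        raise ValueError(
            "noise amplitude must be positive; degenerate noise snippet"
        )
    return [tr.amplitude / noise_amp for tr in bout.trains if tr.mode == SINE]


def filter_bouts_by_snr(
    song: SongAnnotation,
    threshold: float = SNR_THRESHOLD,
    noise_amp: float | None = None,
) -> SongAnnotation:
    """Remove bouts containing any sine train with SNR below ``threshold``.

    ``noise_amp`` defaults to :func:`noise_amplitude` of the song's own
    noise segment. Pulse-only bouts are always retained. Raising the
    threshold can only shrink the retained set.
    """
    if noise_amp is None:
        if song.noise_segment is None:
            raise ValueError("song has no noise segment; pass noise_amp")
        noise_amp = noise_amplitude(song.noise_segment)
    kept = [
        b for b in song.bouts if all(s >= threshold for s in sine_snr(b, noise_amp))
    ]
    return song.replace_bouts(kept)


def merge_close_bouts(song: SongAnnotation, max_gap: float = MERGE_GAP_S) -> SongAnnotation:
    """Merge consecutive bouts whose inter-bout interval is below ``max_gap``.

    Song segmentation occasionally splits bouts at soft sine trains
    (turning one 'psp' into 'ps' + 'sp' close in time); merging with a
    0.5-s threshold undoes such splits. Idempotent: merged bouts are
    separated by at least ``max_gap``.
    """
    if not song.bouts:
        return song
    merged: list[Bout] = []
    current: list[Train] = list(song.bouts[0].trains)
    current_end = song.bouts[0].end
    for b in song.bouts[1:]:
        if b.start - current_end < max_gap:
            current.extend(b.trains)
            current_end = max(current_end, b.end)
        else:
            merged.append(Bout(trains=current))
            current = list(b.trains)
            current_end = b.end
    merged.append(Bout(trains=current))
    return song.replace_bouts(merged)


def label_bout(bout: Bout) -> tuple[str, str]:
    """Label a bout by its mode alternations; returns (label, category).

    Adjacent same-mode trains collapse into one letter. The category
    collapses the label to leading mode x simple/complex, with bouts of
    one or more alternations abbreviated 'ps...' / 'sp...'.
    """
    label = bout.label
    return label, label_to_category(label)


def assign_context(
    bout: Bout,
    traj: CourtshipTrajectory,
    threshold: float = CONTEXT_THRESHOLD_MM,
) -> str:
    """'near' if mean mfDist over the bout is below ``threshold`` mm, else 'far'."""
    # sub-frame tolerance: decoded model bouts can overhang the sampled
    # trajectory by up to one integration step
    if bout.start < traj.t[0] - 1e-3 or bout.end > traj.t[-1] + 1e-3:
        raise ValueError("bout lies outside the trajectory time span")
    sel = (traj.t >= bout.start) & (traj.t < bout.end)
    if not np.any(sel):  # bout shorter than one frame: nearest sample
        sel = np.argmin(np.abs(traj.t - 0.5 * (bout.start + bout.end)))
    mean_dist = float(np.mean(traj.mfDist[sel]))
    return "near" if mean_dist < threshold else "far"


def bout_distribution(
    song: SongAnnotation,
    traj: CourtshipTrajectory | None = None,
    context: str | None = None,
    threshold: float = CONTEXT_THRESHOLD_MM,
) -> BoutDistribution:
    """Counts/frequencies over the six bout types, optionally per context.

    With ``context`` in {'far', 'near'} (requires ``traj``), only bouts
    whose mean mfDist falls in that context are counted.
    """
    if context is not None:
        if traj is None:
            raise ValueError("context split requires a trajectory")
        if context not in ("far", "near"):
            raise ValueError("context must be 'far' or 'near'")
        bouts = [
            b for b in song.bouts if assign_context(b, traj, threshold) == context
        ]
    else:
        bouts = song.bouts
    counts = {k: 0 for k in SIX_TYPES}
    for b in bouts:
        counts[b.six_type] += 1
    return BoutDistribution(counts=counts, context=context)


def song_probabilities(
    trials: TrialSet,
    song: SongAnnotation,
    bin_width: float = 1 / 60,
    traj: CourtshipTrajectory | None = None,
    context: str | None = None,
    threshold: float = CONTEXT_THRESHOLD_MM,
) -> dict:
    """Time-resolved probability of pulse/sine song across trials.

    For each within-trial time bin, the fraction of trials in which a
    train of the given mode is active (train interval overlapping the
    bin). With ``context`` given, only trials whose mean mfDist falls in
    that context enter the denominator.
    """
    trial_list = list(trials.trials)
    if context is not None:
        if traj is None:
            raise ValueError("context split requires a trajectory")
        kept = []
        for tr in trial_list:
            sel = (traj.t >= tr.t_start) & (traj.t < tr.t_end)
            if np.any(sel):
                mean_dist = float(np.mean(traj.mfDist[sel]))
                ctx = "near" if mean_dist < threshold else "far"
                if ctx == context:
                    kept.append(tr)
        trial_list = kept
    if not trial_list:
        raise ValueError("no trials to aggregate")
    trial_len = min(tr.t_end - tr.t_start for tr in trial_list)
    n_bins = int(round(trial_len / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = {"pulse": np.zeros(n_bins), "sine": np.zeros(n_bins)}
    intervals = {"pulse": [], "sine": []}
    for b in song.bouts:
        for tr in b.trains:
            intervals[tr.mode].append((tr.start, tr.end))
    for trial in trial_list:
        for mode in ("pulse", "sine"):
            active = np.zeros(n_bins, bool)
            for s, e in intervals[mode]:
                lo, hi = s - trial.t_start, e - trial.t_start
                if hi <= 0 or lo >= trial_len:
                    continue
                i0 = max(0, int(np.floor(lo / bin_width)))
                i1 = min(n_bins, int(np.ceil(hi / bin_width)) if hi > lo else i0 + 1)
                active[i0:max(i1, i0 + 1)] = True
            counts[mode] += active
    n = len(trial_list)
    return {
        "t": 0.5 * (edges[:-1] + edges[1:]),
        "pulse": counts["pulse"] / n,
        "sine": counts["sine"] / n,
        "n_trials": n,
    }


def classify_rebound(
    bout: Bout, stim_intervals: list[tuple[float, float]]
) -> tuple[str, list[bool]]:
    """Classify a bout against optogenetic stimulus intervals.

    Returns (timing, rebound_flags): timing is 'acute' if the bout starts
    during a stimulus, else 'persistent'. A train is flagged as rebound
    song iff the bout is acute and the train starts after the offset of
    the stimulus during which the bout started.
    """
    ivals = sorted(stim_intervals)
    for a, b in zip(ivals, ivals[1:]):
        if b[0] < a[1]:
            raise ValueError("stimulus intervals must be non-overlapping")
    containing = next(
        ((on, off) for on, off in ivals if on <= bout.start < off), None
    )
    if containing is None:
        return "persistent", [False] * len(bout.trains)
    off = containing[1]
    return "acute", [tr.start >= off for tr in bout.trains]


@dataclass
class TapRateResult:
    """Tap rate during a bout and in the equally sized preceding window."""

    B: float  # bout duration, s
    n_during: int
    n_before: int
    truncated_before: bool = False

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("bout duration must be positive")

    @property
    def R_during(self) -> float:
        return self.n_during / self.B

    @property
    def R_before(self) -> float:
        return self.n_before / self.B


def tap_rate(bout: Bout, taps: TapSeries) -> TapRateResult:
    """Taps per second during the bout (R_during = n_during / B) and in
    the window of equal duration B immediately preceding it.

    If the bout starts less than B after the recording start, the before-
    window is truncated and the result flagged.
    """
    times = taps.tap_times
    B = bout.duration
    if B <= 0:
        raise ValueError("bout duration must be positive")
    n_during = int(np.sum((times >= bout.start) & (times < bout.end)))
    before_start = bout.start - B
    truncated = before_start < taps.t[0]
    n_before = int(np.sum((times >= before_start) & (times < bout.start)))
    return TapRateResult(
        B=B, n_during=n_during, n_before=n_before, truncated_before=truncated
    )


def mean_tap_rates_by_category(
    song: SongAnnotation, taps: TapSeries
) -> dict[str, dict[str, float]]:
    """Per-category mean R_during / R_before over pulse-leading bouts.

    Only bouts with leading pulse song (simple 'p' or complex 'ps...')
    enter, mirroring the bout-triggered tap analysis.
    """
    acc: dict[str, list[TapRateResult]] = {"simple_p": [], "complex_p": []}
    for b in song.bouts:
        if b.duration <= 0:
            continue
        cat = b.category
        if cat in acc:
            acc[cat].append(tap_rate(b, taps))
    out = {}
    for cat, results in acc.items():
        out[cat] = {
            "R_during": float(np.mean([r.R_during for r in results])) if results else float("nan"),
            "R_before": float(np.mean([r.R_before for r in results])) if results else float("nan"),
            "n": len(results),
        }
    return out


__all__ = [
    "SNR_THRESHOLD",
    "MERGE_GAP_S",
    "CONTEXT_THRESHOLD_MM",
    "noise_amplitude",
    "sine_snr",
    "filter_bouts_by_snr",
    "merge_close_bouts",
    "label_bout",
    "assign_context",
    "bout_distribution",
    "song_probabilities",
    "classify_rebound",
    "tap_rate",
    "TapRateResult",
    "mean_tap_rates_by_category",
]
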