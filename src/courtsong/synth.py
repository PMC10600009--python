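"""Seeded synthetic courtship data with the statistical structure of
free male–female recordings.

The generator emulates four data streams consumed by the analysis:

- kinematic trajectories on a 60-Hz video clock, with male–female
  distance (mfDist) following a reflected Ornstein–Uhlenbeck process on
  log-distance so the pair dwells in both the near (< 4 mm) and far
  contexts;
- song annotations: bouts placed by an inhomogeneous point process
  (higher rate near the female), with the bout-type mix a multinomial
  logistic function of mfDist at bout onset — far bouts are almost all
  simple pulse, near bouts a mix dominated by simple pulse (~55%) and
  pulse-leading complex bouts (~30%) — and complex bouts longer than
  simple ones;
- binary tap series whose rate is elevated near the female and during
  complex bouts;
- optogenetic sessions following the 16-block factorial protocol
  (4 irradiances x 5 duty cycles, zero-irradiance blocks pooled, 1/8-Hz
  stimulus frequency, 120-s blocks of 15 trials).

All outputs are fully determined by ``SynthParams.seed``; one integer
seed expands into independent substreams per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from courtsong.types import (
    PULSE,
    SINE,
    Bout,
    CourtshipTrajectory,
    SongAnnotation,
    TapSeries,
    Train,
    Trial,
    TrialSet,
)

_STREAMS = {"trajectory": 0, "song": 1, "taps": 2, "opto": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent per-stage generator derived from the single seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


# Bout-type mix as a multinomial logistic in mfDist (mm) at bout onset,
# with simple pulse as the reference category (logit 0). Intercepts and
# slopes calibrated once (scripts/calibrate_synth.py) so that, after SNR
# filtering and merging, far bouts are > 95% simple pulse and near bouts
# are ~55% simple pulse / ~30% complex 'ps...'.
DEFAULT_TYPE_LOGITS: dict[str, tuple[float, float]] = {
    "complex_p": (2.8, -1.4),
    "simple_s": (1.0, -1.4),
    "complex_s": (1.1, -1.4),
}


@dataclass
class SynthParams:
    """Generator calibration; defaults are the study conditions."""

    video_rate: float = 60.0  # Hz
    # log-distance OU: stationary SD = ou_sigma * sqrt(ou_tau / 2)
    ou_tau: float = 15.0  # s
    ou_sigma: float = 0.26  # log-mm / sqrt(s)
    mean_dist: float = 4.2  # mm, OU mean (and initial value)
    dist_min: float = 0.5  # mm chamber bounds
    dist_max: float = 30.0
    bout_rate_near: float = 0.35  # bouts/s below 4 mm
    bout_rate_far: float = 0.15
    bout_type_logits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_LOGITS)
    )
    duration_lognorm_simple: tuple[float, float] = (-0.4, 0.4)  # (mu, sigma) log-s
    duration_lognorm_complex: tuple[float, float] = (0.7, 0.4)
    alternation_geometric_p: float = 0.45
    min_interbout_gap: float = 0.7  # s, keeps generated bouts distinct under merging
    pulse_ipi: float = 0.035  # s between pulse centers
    tap_rate_base: float = 0.05  # taps/s
    tap_rate_near_gain: float = 0.4
    tap_rate_complex_gain: float = 0.6
    snr_lognorm: tuple[float, float] = (1.1, 0.5)  # (mu, sigma) of log-SNR
    noise_channels: int = 16
    noise_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dist_min <= 0 or self.dist_max <= self.dist_min:
            raise ValueError("chamber bounds must satisfy 0 < dist_min < dist_max")
        for name in ("bout_rate_near", "bout_rate_far", "tap_rate_base",
                     "tap_rate_near_gain", "tap_rate_complex_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.alternation_geometric_p <= 1:
            raise ValueError("alternation_geometric_p must be in (0, 1]")
        for t, (_, slope) in self.bout_type_logits.items():
            if slope > 0:
                raise ValueError(
                    "non-simple-pulse logit slopes must be <= 0 so that "
                    "simple pulse dominates far from the female"
                )
        mu_s, sg_s = self.duration_lognorm_simple
        mu_c, sg_c = self.duration_lognorm_complex
        if mu_c + sg_c**2 / 2 <= mu_s + sg_s**2 / 2:
            raise ValueError("complex bouts must be longer than simple on average")


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflect into [lo, hi]; bounded steps need at most a few passes
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def generate_trajectory(params: SynthParams, duration: float) -> CourtshipTrajectory:
    """Kinematic time series of one courtship recording.

    mfDist follows a mean-reverting (OU) process on log-distance,
    reflected at the chamber bounds; the remaining features are smooth
    correlated noise (independent OU processes with plausible scales).
    In the zero-noise limit mfDist stays at its initial value (the OU
    mean).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(params.seed, "trajectory")
    dt = 1.0 / params.video_rate
    n = int(round(duration * params.video_rate))
    t = np.arange(n) * dt

    lo, hi = math.log(params.dist_min), math.log(params.dist_max)
    mu = math.log(params.mean_dist)
    x = np.empty(n)
    x[0] = mu
    noise = rng.standard_normal(n - 1) * params.ou_sigma * math.sqrt(dt)
    for k in range(1, n):
        step = x[k - 1] + (mu - x[k - 1]) * dt / params.ou_tau + noise[k - 1]
        x[k] = _reflect(step, lo, hi)
    mfdist = np.exp(x)

    def smooth_ou(mean, sd, tau, clip=None):
        y = np.empty(n)
        y[0] = mean
        z = rng.standard_normal(n - 1) * sd * math.sqrt(2 * dt / tau)
        for k in range(1, n):
            y[k] = y[k - 1] + (mean - y[k - 1]) * dt / tau + z[k - 1]
        if clip is not None:
            np.clip(y, clip[0], clip[1], out=y)
        return y

    return CourtshipTrajectory(
        t=t,
        mfDist=mfdist,
        mfAngle=smooth_ou(60.0, 35.0, 5.0, clip=(0.0, 180.0)),
        fmAngle=smooth_ou(90.0, 40.0, 5.0, clip=(0.0, 180.0)),
        mFV=smooth_ou(6.0, 4.0, 2.0),
        fFV=smooth_ou(3.0, 2.0, 2.0),
        mLS=smooth_ou(1.5, 1.0, 2.0),
        fLS=smooth_ou(1.0, 0.8, 2.0),
        mRS=smooth_ou(0.0, 1.5, 1.0),
        fRS=smooth_ou(0.0, 1.0, 1.0),
    )


def _type_probabilities(d: float, logits: dict[str, tuple[float, float]]) -> dict[str, float]:
    weights = {"simple_p": 1.0}
    for typ, (b0, b1) in logits.items():
        weights[typ] = math.exp(b0 + b1 * d)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _make_bout(
    category: str,
    start: float,
    duration: float,
    params: SynthParams,
    rng: np.random.Generator,
) -> Bout:
    if category.startswith("simple"):
        n_trains = 1
    else:
        n_trains = 1 + rng.geometric(params.alternation_geometric_p)
    leading = PULSE if category.endswith("_p") else SINE
    # random split of the bout duration across trains
    frac = rng.dirichlet(np.full(n_trains, 4.0))
    edges = start + np.concatenate(([0.0], np.cumsum(frac))) * duration
    trains = []
    for i in range(n_trains):
        mode = leading if i % 2 == 0 else (SINE if leading == PULSE else PULSE)
        s, e = float(edges[i]), float(edges[i + 1])
        if mode == PULSE:
            events = list(np.arange(s + params.pulse_ipi / 2, e, params.pulse_ipi))
            trains.append(Train(mode=PULSE, start=s, end=e, events=events))
        else:
            snr = float(rng.lognormal(*params.snr_lognorm))
            # the noise segment is normalized to unit noise amplitude, so
            # the train amplitude equals its SNR draw
            trains.append(Train(mode=SINE, start=s, end=e, amplitude=snr))
    return Bout(trains=trains)


def _noise_segment(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    from courtsong.annotate import noise_amplitude

    seg = rng.standard_normal((params.noise_channels, params.noise_samples))
    seg *= 0.3 + rng.random(params.noise_channels)[:, None]  # uneven microphones
    return seg / noise_amplitude(seg)


def generate_song(traj: CourtshipTrajectory, params: SynthParams) -> SongAnnotation:
    """Song bouts conditioned on the trajectory's mfDist.

    Bout onsets follow an inhomogeneous point process (rate
    ``bout_rate_near`` below 4 mm, ``bout_rate_far`` above); the bout
    type is drawn from the logistic mix at onset distance; complex bouts
    draw a geometric number of alternations and longer (lognormal)
    durations. Bouts never overlap.
    """
    rng = _rng(params.seed, "song")
    bouts: list[Bout] = []
    t_end = float(traj.t[-1])
    tcur = float(traj.t[0])
    rate_max = max(params.bout_rate_near, params.bout_rate_far)
    if rate_max > 0:
        while True:
            # thinned Poisson arrivals at the distance-dependent rate
            tcur += rng.exponential(1.0 / rate_max)
            if tcur >= t_end:
                break
            d0 = float(np.interp(tcur, traj.t, traj.mfDist))
            rate0 = params.bout_rate_near if d0 < 4.0 else params.bout_rate_far
            if rng.random() > rate0 / rate_max:
                continue
            probs = _type_probabilities(d0, params.bout_type_logits)
            cats = sorted(probs)
            category = str(rng.choice(cats, p=[probs[c] for c in cats]))
            mu, sg = (
                params.duration_lognorm_simple
                if category.startswith("simple")
                else params.duration_lognorm_complex
            )
            dur = float(rng.lognormal(mu, sg))
            if tcur + dur > t_end:
                break
            bouts.append(_make_bout(category, tcur, dur, params, rng))
            tcur += dur + params.min_interbout_gap
    return SongAnnotation(
        bouts=bouts,
        noise_segment=_noise_segment(params, rng),
        clock_origin=float(traj.t[0]),
    )


def generate_taps(
    traj: CourtshipTrajectory, song: SongAnnotation, params: SynthParams
) -> TapSeries:
    """Bernoulli taps per video frame.

    Per-frame tap probability is (base + near_gain * 1[mfDist < 4 mm]
    + complex_gain * 1[inside a complex bout]) / video_rate.
    """
    if abs(song.clock_origin - float(traj.t[0])) > 1e-9:
        raise ValueError("trajectory and song do not share a clock origin")
    rng = _rng(params.seed, "taps")
    rate = np.full(len(traj), params.tap_rate_base)
    rate[traj.mfDist < 4.0] += params.tap_rate_near_gain
    in_complex = np.zeros(len(traj), bool)
    for b in song.bouts:
        if len(b.label) > 1:
            in_complex |= (traj.t >= b.start) & (traj.t < b.end)
    rate[in_complex] += params.tap_rate_complex_gain
    p = np.clip(rate / traj.frame_rate, 0.0, 1.0)
    return TapSeries(t=traj.t.copy(), is_tap=(rng.random(len(traj)) < p))


@dataclass
class OptoProtocol:
    """Block-design optogenetic stimulation protocol.

    ``blocks`` lists (irradiance in uW/mm^2, duty cycle in (0, 1],
    block duration in s); stimuli repeat at ``stim_frequency`` within
    each block, so each block contains duration * frequency trials.
    """

    blocks: list[tuple[float, float, float]]
    stim_frequency: float = 1.0 / 8.0  # Hz
    block_order: list[int] | None = None

    def __post_init__(self) -> None:
        period = 1.0 / self.stim_frequency
        for irr, duty, dur in self.blocks:
            if not 0 < duty <= 1:
                raise ValueError("duty cycle must be in (0, 1]")
            if irr < 0:
                raise ValueError("irradiance must be >= 0")
            n = dur / period
            if abs(n - round(n)) > 1e-9:
                raise ValueError("stimulus period must divide block duration")
        if self.block_order is None:
            self.block_order = list(range(len(self.blocks)))
        if sorted(self.block_order) != list(range(len(self.blocks))):
            raise ValueError("block_order must be a permutation of the blocks")


def factorial_protocol(
    irradiances: tuple[float, ...] = (0.0, 1.0, 25.0, 205.0),
    duty_cycles: tuple[float, ...] = (1 / 64, 1 / 32, 1 / 16, 1 / 8, 2 / 8),
    block_duration: float = 120.0,
    stim_frequency: float = 1.0 / 8.0,
    shuffle_seed: int | None = None,
) -> OptoProtocol:
    """Full factorial irradiance x duty protocol, pooling zero-irradiance
    blocks into one (16 distinct blocks for the default level sets)."""
    blocks = []
    for irr in irradiances:
        for duty in duty_cycles:
            if irr == 0 and any(b[0] == 0 for b in blocks):
                continue  # pool zero-irradiance blocks
            blocks.append((irr, duty, block_duration))
    order = list(range(len(blocks)))
    if shuffle_seed is not None:
        order = [int(i) for i in np.random.default_rng(shuffle_seed).permutation(len(blocks))]
    return OptoProtocol(
        blocks=blocks, stim_frequency=stim_frequency, block_order=order
    )


@dataclass
class ResponderSpec:
    """Maps (irradiance, duty cycle) to per-trial response probabilities.

    ``p_pulse``: probability of a stimulus-locked pulse train;
    ``p_rebound``: probability of a sine train starting after stimulus
    offset (rebound song when the bout started during the stimulus).
    Probabilities saturate in the product irradiance x duty with
    half-saturation dose ``k``.
    """

    pulse_max: float = 0.9
    rebound_max: float = 0.6
    k: float = 2.0  # uW/mm^2 effective dose at half saturation
    rebound_min_irradiance: float = 0.0

    def p_pulse(self, irradiance: float, duty: float) -> float:
        dose = irradiance * duty
        return self.pulse_max * dose / (dose + self.k)

    def p_rebound(self, irradiance: float, duty: float) -> float:
        if irradiance < self.rebound_min_irradiance:
            return 0.0
        dose = irradiance * duty
        return self.rebound_max * dose / (dose + self.k)


def generate_opto_session(
    protocol: OptoProtocol,
    responder: ResponderSpec,
    seed: int = 0,
) -> tuple[TrialSet, SongAnnotation]:
    """Trials tiled at the stimulus frequency plus the evoked song.

    Each trial spans one stimulus period; the stimulus is on for
    duty * period from trial start. With probability ``p_pulse`` the
    trial contains a pulse train locked to the stimulus; with
    probability ``p_rebound`` a sine train starting after stimulus
    offset (attached to the stimulus-locked bout when present, so it
    classifies as rebound song).
    """
    rng = _rng(seed, "opto")
    period = 1.0 / protocol.stim_frequency
    trials: list[Trial] = []
    bouts: list[Bout] = []
    tcur = 0.0
    for block_idx in protocol.block_order:
        irr, duty, dur = protocol.blocks[block_idx]
        n_trials = int(round(dur * protocol.stim_frequency))
        for _ in range(n_trials):
            on, off = tcur, tcur + duty * period
            trials.append(
                Trial(
                    block_id=block_idx,
                    irradiance=irr,
                    duty_cycle=duty,
                    t_start=tcur,
                    t_end=tcur + period,
                    stim_intervals=[(on, off)] if irr > 0 else [],
                )
            )
            if irr > 0:
                trains: list[Train] = []
                if rng.random() < responder.p_pulse(irr, duty):
                    events = list(np.arange(on + 0.05, off, 0.035))
                    trains.append(
                        Train(mode=PULSE, start=on + 0.04, end=off, events=events)
                    )
                if rng.random() < responder.p_rebound(irr, duty):
                    s0 = off + 0.1
                    trains.append(
                        Train(
                            mode=SINE,
                            start=s0,
                            end=min(s0 + 0.5, tcur + period),
                            amplitude=3.0,
                        )
                    )
                if trains:
                    bouts.append(Bout(trains=trains))
            tcur += period
    return TrialSet(trials=trials), SongAnnotation(bouts=bouts)


__all__ = [
    "SynthParams",
    "DEFAULT_TYPE_LOGITS",
    "generate_trajectory",
    "generate_song",
    "generate_taps",
    "OptoProtocol",
    "factorial_protocol",
    "ResponderSpec",
    "generate_opto_session",
    "replace",
]
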