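"""Four-node spiking circuit model of context-dependent song patterning.

The network comprises four Izhikevich neurons: ``pC2`` (sensory input
node, tonic regime), ``inh`` (tonic inhibitory node providing default
suppression of song circuitry), and ``p`` / ``s`` (pulse and sine song
nodes, rebound regime). Connectivity implements three computational
features:

- *mutual inhibition* between p and s,
- *post-inhibitory rebound* in p and s (spiking on release from
  inhibition, so sine song needs no excitatory drive),
- *disinhibition*: pC2 inhibits inh, which tonically inhibits p and s, so
  strong sensory drive releases the p–s half-center and enables complex
  (alternating) bouts.

The only time-varying input is male–female distance (mfDist), mapped to a
drive current onto pC2 through a decreasing sigmoid, so short distance
means strong drive. Membrane dynamics follow the Izhikevich form

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I + g_e/tau_e + g_i/tau_i
    du/dt = a (b v - u)
    dg/dt = -g / tau

with a spike whenever v reaches 30 mV, after which v <- c and u <- u + d.
Each presynaptic spike increments the postsynaptic conductance by the
synaptic weight (negative increments for inhibition, so g_i <= 0).
Integration is forward Euler at ``dt`` milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from courtsong.types import PULSE, SINE, Bout, SongAnnotation, Train

NODES: tuple[str, ...] = ("pC2", "inh", "p", "s")
_NODE_INDEX = {name: i for i, name in enumerate(NODES)}

VARIANTS: tuple[str, ...] = (
    "full",
    "no_rebound_p",
    "no_rebound_s",
    "no_rebound",
    "no_disinhibition",
    "exc_modulation",
)

SPIKE_THRESHOLD_MV = 30.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Single-neuron parameters: recovery timescale ``a`` (1/ms), recovery
    sensitivity ``b``, reset potential ``c`` (mV), recovery increment ``d``."""

    a: float
    b: float
    c: float
    d: float
    regime: str = "custom"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")


#: Canonical tonic-spiking regime.
TONIC = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=6.0, regime="tonic")
#: Post-inhibitory rebound-burst regime (b = 0.25, c = -52, d = 0, as in
#: the canonical rebound-burst cell, with the recovery timescale slowed to
#: a = 0.005 so that bursts and the pauses between them live on the few-
#: hundred-millisecond timescale of song trains; release from inhibition
#: then triggers a burst rather than a lone spike, which is what sustains
#: pulse/sine trains at the 300-ms decoding timescale).
REBOUND = IzhikevichParams(a=0.005, b=0.25, c=-52.0, d=0.0, regime="rebound")

_REGIME_PRESETS = {"tonic": TONIC, "rebound": REBOUND}


def regime_params(regime: str) -> IzhikevichParams:
    try:
        return _REGIME_PRESETS[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}") from None


@dataclass(frozen=True)
class SynapseSpec:
    """One directed synapse; ``weight`` is a non-negative magnitude, the
    sign of the conductance increment follows ``sign``."""

    pre: str
    post: str
    sign: str  # "excitatory" | "inhibitory"
    weight: float
    tau: float  # ms

    def __post_init__(self) -> None:
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown synapse sign {self.sign!r}")
        if self.weight < 0:
            raise ValueError("synaptic weight magnitude must be >= 0")
        if self.tau <= 0:
            raise ValueError("synaptic time constant must be positive")


@dataclass(frozen=True)
class DistanceNonlinearity:
    """Decreasing sigmoid mapping mfDist (mm) to pC2 drive current.

    drive = I_e * alpha / (1 + exp(-beta * (x0 - mfDist)))

    ``x0`` is aligned by default with the 4-mm behavioral far/near
    threshold; ``I_e`` is the input gain (a free parameter of the fit).
    """

    I_e: float
    alpha: float = 1.0
    beta: float = 3.0  # 1/mm
    x0: float = 4.0  # mm

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.I_e <= 0:
            raise ValueError("alpha, beta and I_e must be positive")


def nl_transform(mfdist, nl: DistanceNonlinearity):
    """Drive current onto pC2 for distance(s) ``mfdist`` (mm)."""
    d = np.asarray(mfdist, float)
    with np.errstate(over="ignore"):  # exp overflow -> drive 0, as intended
        out = nl.I_e * nl.alpha / (1.0 + np.exp(-nl.beta * (nl.x0 - d)))
    return float(out) if out.ndim == 0 else out


# Free parameters of the model fit (all other parameters stay fixed):
# I_e (pC2 input gain), I_tonic (constant current into inh), and the
# global excitatory / inhibitory weights w_e, w_i. Defaults below are the
# package's reference operating point: the full model then produces pure
# simple-pulse output for constant mfDist >= 4 mm and sustained pulse-sine
# alternation below ~3.8 mm.
DEFAULT_TAU_E = 5.0  # ms
DEFAULT_TAU_I = 40.0  # ms
DEFAULT_I_E = 35.0
DEFAULT_I_TONIC = 13.0
DEFAULT_W_E = 21.0
DEFAULT_W_I = 19.0

#: The model's connectivity graph: (pre, post, sign).
CONNECTIVITY: tuple[tuple[str, str, str], ...] = (
    ("p", "s", "inhibitory"),
    ("s", "p", "inhibitory"),
    ("inh", "p", "inhibitory"),
    ("inh", "s", "inhibitory"),
    ("pC2", "inh", "inhibitory"),
    ("pC2", "p", "excitatory"),
)


@dataclass
class CircuitModel:
    """The four-node network plus input mapping and integration settings."""

    nodes: dict[str, IzhikevichParams]
    synapses: list[SynapseSpec]
    I_tonic: float
    nonlinearity: DistanceNonlinearity
    dt: float = 0.1  # ms
    variant: str = "full"

    def __post_init__(self) -> None:
        if set(self.nodes) != set(NODES):
            raise ValueError(f"node set must be exactly {NODES}")
        if self.I_tonic < 0:
            raise ValueError("I_tonic must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for syn in self.synapses:
            if syn.pre not in self.nodes or syn.post not in self.nodes:
                raise ValueError(f"synapse references unknown node: {syn}")

    def with_free_parameters(
        self,
        I_e: float | None = None,
        I_tonic: float | None = None,
        w_e: float | None = None,
        w_i: float | None = None,
    ) -> "CircuitModel":
        """Return a copy with the four free parameters replaced.

        ``w_e`` / ``w_i`` are global: they set the magnitude of every
        excitatory / inhibitory synapse respectively.
        """
        nl = self.nonlinearity
        if I_e is not None:
            nl = replace(nl, I_e=float(I_e))
        synapses = []
        for syn in self.synapses:
            if syn.sign == "excitatory" and w_e is not None:
                syn = replace(syn, weight=float(w_e))
            elif syn.sign == "inhibitory" and w_i is not None:
                syn = replace(syn, weight=float(w_i))
            synapses.append(syn)
        return CircuitModel(
            nodes=dict(self.nodes),
            synapses=synapses,
            I_tonic=float(I_tonic) if I_tonic is not None else self.I_tonic,
            nonlinearity=nl,
            dt=self.dt,
            variant=self.variant,
        )


def default_model(
    I_e: float = DEFAULT_I_E,
    I_tonic: float = DEFAULT_I_TONIC,
    w_e: float = DEFAULT_W_E,
    w_i: float = DEFAULT_W_I,
    tau_e: float = DEFAULT_TAU_E,
    tau_i: float = DEFAULT_TAU_I,
    dt: float = 0.1,
    nonlinearity: DistanceNonlinearity | None = None,
) -> CircuitModel:
    """Build the full model with canonical connectivity and regimes."""
    nl = nonlinearity if nonlinearity is not None else DistanceNonlinearity(I_e=I_e)
    synapses = [
        SynapseSpec(
            pre=pre,
            post=post,
            sign=sign,
            weight=w_e if sign == "excitatory" else w_i,
            tau=tau_e if sign == "excitatory" else tau_i,
        )
        for pre, post, sign in CONNECTIVITY
    ]
    return CircuitModel(
        nodes={"pC2": TONIC, "inh": TONIC, "p": REBOUND, "s": REBOUND},
        synapses=synapses,
        I_tonic=I_tonic,
        nonlinearity=nl,
        dt=dt,
        variant="full",
    )


def apply_variant(model: CircuitModel, variant: str) -> CircuitModel:
    """Return the knockout/replacement variant of ``model``.

    - ``no_rebound_p`` / ``no_rebound_s`` / ``no_rebound``: switch the
      pulse and/or sine node from the rebound to the tonic regime.
    - ``no_disinhibition``: remove the inhibitory synapses from inh onto
      the pulse and sine nodes.
    - ``exc_modulation``: replace the inhibitory weights onto and from the
      inh node with excitatory weights (forming an 'exc' node) and remove
      its tonic input.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    nodes = dict(model.nodes)
    synapses = list(model.synapses)
    I_tonic = model.I_tonic
    if variant in ("no_rebound_p", "no_rebound"):
        nodes["p"] = TONIC
    if variant in ("no_rebound_s", "no_rebound"):
        nodes["s"] = TONIC
    if variant == "no_disinhibition":
        synapses = [
            s for s in synapses if not (s.pre == "inh" and s.post in ("p", "s"))
        ]
    if variant == "exc_modulation":
        tau_e = next(
            (s.tau for s in synapses if s.sign == "excitatory"), DEFAULT_TAU_E
        )
        w_e = next(
            (s.weight for s in synapses if s.sign == "excitatory"), DEFAULT_W_E
        )
        converted = []
        for s in synapses:
            if s.pre == "inh" or s.post == "inh":
                s = replace(s, sign="excitatory", tau=tau_e, weight=w_e)
            converted.append(s)
        synapses = converted
        I_tonic = 0.0
    out = CircuitModel(
        nodes=nodes,
        synapses=synapses,
        I_tonic=I_tonic,
        nonlinearity=model.nonlinearity,
        dt=model.dt,
        variant=variant,
    )
    return out


@dataclass
class NeuronState:
    """Membrane state of one neuron (v in mV; g_e >= 0 >= g_i)."""

    v: float
    u: float
    g_e: float = 0.0
    g_i: float = 0.0


def resting_potential(params: IzhikevichParams) -> float:
    """Stable fixed point of the zero-input membrane dynamics (mV).

    Solves 0.04 v^2 + (5 - b) v + 140 = 0 and returns the lower (stable)
    root. Falls back to the reset potential c when no real fixed point
    exists (intrinsically active cell).
    """
    disc = (5.0 - params.b) ** 2 - 4 * 0.04 * 140.0
    if disc < 0:
        return params.c
    return (-(5.0 - params.b) - np.sqrt(disc)) / (2 * 0.04)


def resting_state(params: IzhikevichParams) -> NeuronState:
    """Quiescent initial condition: v at rest, u = b * v, conductances zero."""
    v = resting_potential(params)
    return NeuronState(v=v, u=params.b * v)


def step_neuron(
    state: NeuronState,
    params: IzhikevichParams,
    I: float,
    dt: float,
    tau_e: float = DEFAULT_TAU_E,
    tau_i: float = DEFAULT_TAU_I,
) -> tuple[NeuronState, bool]:
    """One forward-Euler step of a single neuron; returns (state, spiked).

    Reference implementation of the update used inside the compiled
    network kernel; kept in plain Python for inspection and testing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I + state.g_e / tau_e + state.g_i / tau_i
    du = params.a * (params.b * v - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    g_e = state.g_e - dt * state.g_e / tau_e
    g_i = state.g_i - dt * state.g_i / tau_i
    if not np.isfinite(v_new) or abs(v_new) > 1e8:
        raise FloatingPointError(
            "membrane potential diverged; dt is likely too large for Euler "
            "integration of the quadratic voltage term"
        )
    spiked = v_new >= SPIKE_THRESHOLD_MV
    if spiked:
        v_new = params.c
        u_new = u_new + params.d
    return NeuronState(v=v_new, u=u_new, g_e=g_e, g_i=g_i), bool(spiked)


@dataclass
class SimulationResult:
    """Per-node spike times (seconds) and optional sampled voltage traces."""

    spikes: dict[str, np.ndarray]
    duration: float
    t_start: float = 0.0
    traces: dict[str, np.ndarray] | None = None
    trace_t: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, s in self.spikes.items():
            s = np.asarray(s, float)
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"spike times for {name} must be strictly increasing")
            if s.size and (
                s[0] < self.t_start
                or s[-1] > self.t_start + self.duration + 1e-9
            ):
                raise ValueError(f"spike times for {name} outside the simulated span")
            self.spikes[name] = s


@njit(cache=True)
def _euler_kernel(
    n_steps,
    dt,
    abcd,  # (4, 4) rows per node: a, b, c, d
    I_pc2,  # (n_steps,) drive onto node 0
    I_tonic,  # scalar drive onto node 1
    syn_pre,  # (n_syn,) int
    syn_post,  # (n_syn,) int
    syn_inc,  # (n_syn,) signed conductance increment
    syn_exc,  # (n_syn,) bool: True -> g_e else g_i
    tau_e,
    tau_i,
    trace_every,  # 0 -> no traces
):
    n = 4
    v = np.empty(n)
    u = np.empty(n)
    for i in range(n):
        b = abcd[i, 1]
        disc = (5.0 - b) ** 2 - 0.16 * 140.0
        if disc >= 0:
            v[i] = (-(5.0 - b) - np.sqrt(disc)) / 0.08
        else:
            v[i] = abcd[i, 2]
        u[i] = b * v[i]
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    max_spikes = n_steps // 10 + 16
    spikes = np.empty((n, max_spikes))
    n_spikes = np.zeros(n, np.int64)
    n_trace = n_steps // trace_every + 1 if trace_every > 0 else 0
    traces = np.empty((n, n_trace))
    spiked = np.zeros(n, np.bool_)
    ok = True
    for k in range(n_steps):
        if trace_every > 0 and k % trace_every == 0:
            for i in range(n):
                traces[i, k // trace_every] = v[i]
        for i in range(n):
            if i == 0:
                I = I_pc2[k]
            elif i == 1:
                I = I_tonic
            else:
                I = 0.0
            dv = (
                0.04 * v[i] * v[i] + 5.0 * v[i] + 140.0 - u[i]
                + I + g_e[i] / tau_e + g_i[i] / tau_i
            )
            du = abcd[i, 0] * (abcd[i, 1] * v[i] - u[i])
            v[i] += dt * dv
            u[i] += dt * du
            g_e[i] -= dt * g_e[i] / tau_e
            g_i[i] -= dt * g_i[i] / tau_i
            if not np.isfinite(v[i]) or abs(v[i]) > 1e8:
                ok = False
            spiked[i] = v[i] >= 30.0
            if spiked[i]:
                if n_spikes[i] < max_spikes:
                    spikes[i, n_spikes[i]] = (k + 1) * dt
                    n_spikes[i] += 1
                else:
                    ok = False
                v[i] = abcd[i, 2]
                u[i] += abcd[i, 3]
        if not ok:
            return spikes, n_spikes, traces, False
        for j in range(syn_pre.shape[0]):
            if spiked[syn_pre[j]]:
                if syn_exc[j]:
                    g_e[syn_post[j]] += syn_inc[j]
                else:
                    g_i[syn_post[j]] += syn_inc[j]
    return spikes, n_spikes, traces, True


def simulate(
    model: CircuitModel,
    mfdist_t: np.ndarray,
    mfdist: np.ndarray,
    duration: float | None = None,
    record_traces: bool = False,
    trace_every: int = 10,
) -> SimulationResult:
    """Simulate the network driven by a sampled mfDist series.

    ``mfdist_t`` / ``mfdist`` give distance samples (seconds / mm); the
    drive onto pC2 uses previous-value (step) hold at the integration
    resolution. ``duration`` defaults to the span of the series. The
    result is fully determined by the model and input (no noise).
    """
    mfdist_t = np.asarray(mfdist_t, float)
    mfdist = np.asarray(mfdist, float)
    if mfdist_t.size == 0 or mfdist_t.size != mfdist.size:
        raise ValueError("mfdist series must be non-empty and aligned")
    if duration is None:
        duration = float(mfdist_t[-1] - mfdist_t[0])
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt_s = model.dt * 1e-3
    n_steps = int(round(duration / dt_s))
    # step-hold interpolation of the drive onto the integration grid
    t_grid = mfdist_t[0] + np.arange(n_steps) * dt_s
    idx = np.searchsorted(mfdist_t, t_grid, side="right") - 1
    idx = np.clip(idx, 0, mfdist.size - 1)
    drive = nl_transform(mfdist[idx], model.nonlinearity)
    drive = np.asarray(drive, float)

    abcd = np.empty((4, 4))
    for i, name in enumerate(NODES):
        p = model.nodes[name]
        abcd[i] = (p.a, p.b, p.c, p.d)
    n_syn = len(model.synapses)
    syn_pre = np.empty(n_syn, np.int64)
    syn_post = np.empty(n_syn, np.int64)
    syn_inc = np.empty(n_syn)
    syn_exc = np.empty(n_syn, np.bool_)
    for j, syn in enumerate(model.synapses):
        syn_pre[j] = _NODE_INDEX[syn.pre]
        syn_post[j] = _NODE_INDEX[syn.post]
        syn_exc[j] = syn.sign == "excitatory"
        syn_inc[j] = syn.weight if syn_exc[j] else -syn.weight
    tau_e = next(
        (s.tau for s in model.synapses if s.sign == "excitatory"), DEFAULT_TAU_E
    )
    tau_i = next(
        (s.tau for s in model.synapses if s.sign == "inhibitory"), DEFAULT_TAU_I
    )
    spikes, n_spikes, traces, ok = _euler_kernel(
        n_steps,
        model.dt,
        abcd,
        drive,
        model.I_tonic,
        syn_pre,
        syn_post,
        syn_inc,
        syn_exc,
        tau_e,
        tau_i,
        trace_every if record_traces else 0,
    )
    if not ok:
        raise FloatingPointError(
            "simulation diverged or spike buffer overflow; dt is likely too "
            "large for Euler integration"
        )
    t0 = float(mfdist_t[0])  # outputs share the input series' clock
    spike_dict = {
        name: spikes[i, : n_spikes[i]] * 1e-3 + t0 for i, name in enumerate(NODES)
    }
    result = SimulationResult(spikes=spike_dict, duration=duration, t_start=t0)
    if record_traces:
        result.traces = {name: traces[i].copy() for i, name in enumerate(NODES)}
        result.trace_t = t0 + np.arange(traces.shape[1]) * trace_every * dt_s
    return result


def _spikes_to_trains(spike_times: np.ndarray, mode: str, train_gap: float) -> list[Train]:
    """Group one node's spikes into trains: consecutive spikes with
    inter-spike interval <= train_gap belong to the same train."""
    if spike_times.size == 0:
        return []
    breaks = np.where(np.diff(spike_times) > train_gap)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [spike_times.size - 1]))
    return [
        Train(mode=mode, start=float(spike_times[i]), end=float(spike_times[j]))
        for i, j in zip(starts, ends)
    ]


def decode_song(
    result: SimulationResult,
    alternation_window: float = 0.3,
    train_gap: float = 0.3,
) -> SongAnnotation:
    """Decode p/s spike trains into a song annotation.

    Within-node spikes with ISI <= ``train_gap`` form one train. A train
    separated by at least ``alternation_window`` from the activity of the
    other node stands alone (simple bout); trains whose gap to the
    ongoing bout is smaller are merged, producing complex bouts.
    Overlapping (interleaved) trains always merge.
    """
    trains = _spikes_to_trains(result.spikes["p"], PULSE, train_gap)
    trains += _spikes_to_trains(result.spikes["s"], SINE, train_gap)
    trains.sort(key=lambda tr: (tr.start, tr.mode))
    bouts: list[Bout] = []
    current: list[Train] = []
    current_end = -np.inf
    for tr in trains:
        if current and tr.start - current_end >= alternation_window:
            bouts.append(Bout(trains=current))
            current = []
            current_end = -np.inf
        current.append(tr)
        current_end = max(current_end, tr.end)
    if current:
        bouts.append(Bout(trains=current))
    return SongAnnotation(bouts=bouts)


__all__ = [
    "NODES",
    "VARIANTS",
    "CONNECTIVITY",
    "IzhikevichParams",
    "TONIC",
    "REBOUND",
    "regime_params",
    "SynapseSpec",
    "DistanceNonlinearity",
    "nl_transform",
    "CircuitModel",
    "default_model",
    "apply_variant",
    "NeuronState",
    "resting_state",
    "step_neuron",
    "SimulationResult",
    "simulate",
    "decode_song",
]
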