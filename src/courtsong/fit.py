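"""Genetic-algorithm fitting of the circuit's four free parameters.

The four free parameters — the pC2 input gain I_e, the tonic current
I_tonic into the inh node, and the global excitatory / inhibitory weights
w_e / w_i — are fit to a target bout-type distribution over the six types
('p', 'ps', 'psp...', 's', 'sp', 'sps...'). Each candidate is evaluated
by simulating the circuit on the snippet's mfDist series, decoding the
spike trains into bouts, and scoring

    objective = RMSD(six-type frequencies) + 0.1 * |n_bout_sim - n_bout_target|

so that reproducing the bout distribution is prioritized over matching
the bout count. A small real-coded GA (elitism, tournament selection,
blend crossover, bounded Gaussian mutation) minimizes the objective;
knockout variants are compared by their achieved fit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from courtsong import annotate
from courtsong.circuit import CircuitModel, apply_variant, decode_song, simulate
from courtsong.types import (
    SIX_TYPES,
    Bout,
    BoutDistribution,
    CourtshipTrajectory,
    SongAnnotation,
    Train,
)

PARAM_NAMES: tuple[str, ...] = ("I_e", "I_tonic", "w_e", "w_i")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "I_e": (1.0, 50.0),
    "I_tonic": (0.0, 20.0),
    "w_e": (0.5, 30.0),
    "w_i": (0.5, 30.0),
}


def objective(sim_dist: BoutDistribution, target_dist: BoutDistribution) -> float:
    """Root-mean-squared frequency difference plus 0.1 per bout-count unit.

    An empty simulated song scores with all-zero frequencies (the model
    sang nothing); an empty target is rejected.
    """
    if target_dist.n_bout == 0:
        raise ValueError("target distribution is empty")
    tvec = target_dist.as_vector()
    svec = (
        sim_dist.as_vector() if sim_dist.n_bout > 0 else np.zeros(len(SIX_TYPES))
    )
    rmsd = float(np.sqrt(np.mean((svec - tvec) ** 2)))
    return rmsd + 0.1 * abs(sim_dist.n_bout - target_dist.n_bout)


@dataclass
class Snippet:
    """A song window plus its aligned mfDist series, clock shifted to 0."""

    song: SongAnnotation
    t: np.ndarray
    mfdist: np.ndarray
    t_offset: float = 0.0

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def target_distribution(self) -> BoutDistribution:
        return annotate.bout_distribution(self.song)


def select_snippet(
    song: SongAnnotation,
    traj: CourtshipTrajectory,
    length: float = 400.0,
    min_far_fraction: float = 0.10,
    seed: int = 0,
    max_retries: int = 200,
    threshold: float = 4.0,
) -> Snippet:
    """Uniformly random window with at least ``min_far_fraction`` of its
    bouts produced far from the female (mean mfDist > ``threshold`` mm).

    Raises after ``max_retries`` draws without a qualifying window.
    """
    span = float(traj.t[-1] - traj.t[0])
    if span < length:
        raise ValueError("recording shorter than requested snippet length")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        t0 = float(traj.t[0]) + rng.uniform(0.0, span - length)
        t1 = t0 + length
        bouts = [b for b in song.bouts if b.start >= t0 and b.end <= t1]
        if not bouts:
            continue
        far = sum(
            1 for b in bouts if annotate.assign_context(b, traj, threshold) == "far"
        )
        if far / len(bouts) < min_far_fraction:
            continue
        sel = (traj.t >= t0) & (traj.t <= t1)
        shifted = [
            Bout(
                trains=[
                    Train(
                        mode=tr.mode,
                        start=tr.start - t0,
                        end=tr.end - t0,
                        amplitude=tr.amplitude,
                        events=[e - t0 for e in tr.events],
                    )
                    for tr in b.trains
                ]
            )
            for b in bouts
        ]
        return Snippet(
            song=SongAnnotation(bouts=shifted, noise_segment=song.noise_segment),
            t=traj.t[sel] - t0,
            mfdist=traj.mfDist[sel].copy(),
            t_offset=t0,
        )
    raise ValueError(
        f"no window of {length} s with >= {min_far_fraction:.0%} far bouts "
        f"found in {max_retries} draws"
    )


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters (desk-scale defaults)."""

    population_size: int = 32
    n_generations: int = 40
    mutation_prob: float = 0.1
    crossover_prob: float = 0.5
    elitism: int = 1
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    tournament_size: int = 3
    mutation_scale: float = 0.15  # fraction of each bound range
    immigrants: int = 2  # fresh uniform draws per generation
    warm_start: bool = True  # seed the population with the template's own parameters
    cache_decimals: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")
        if set(self.bounds) != set(PARAM_NAMES):
            raise ValueError(f"bounds must cover exactly {PARAM_NAMES}")
        for name, (lo, hi) in self.bounds.items():
            if not np.all(np.isfinite([lo, hi])) or hi <= lo or lo < 0:
                raise ValueError(f"invalid bounds for {name}")

    def derive(self, seed: int) -> "GAConfig":
        """Copy with a different seed (for replicate fits)."""
        return GAConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            mutation_prob=self.mutation_prob,
            crossover_prob=self.crossover_prob,
            elitism=self.elitism,
            bounds=dict(self.bounds),
            tournament_size=self.tournament_size,
            mutation_scale=self.mutation_scale,
            immigrants=self.immigrants,
            warm_start=self.warm_start,
            cache_decimals=self.cache_decimals,
            seed=int(seed) % 2**31,
        )


@dataclass
class FitResult:
    """Best parameters, objective, and the per-generation best trace."""

    params: dict[str, float]
    objective: float
    trace: list[float]
    variant: str
    snippet_id: str = ""
    n_bout_sim: int = 0
    n_bout_target: int = 0
    n_evaluations: int = 0

    @property
    def delta_n_bout(self) -> int:
        return abs(self.n_bout_sim - self.n_bout_target)


def evaluate_candidate(
    template: CircuitModel,
    params: dict[str, float],
    snippet: Snippet,
    target: BoutDistribution | None = None,
) -> tuple[float, int]:
    """Objective of one parameter vector; returns (score, n_bout_sim)."""
    if target is None:
        target = snippet.target_distribution()
    model = template.with_free_parameters(**params)
    try:
        result = simulate(model, snippet.t, snippet.mfdist)
    except FloatingPointError:
        return float("inf"), 0
    song = decode_song(result)
    sim_dist = annotate.bout_distribution(song)
    return objective(sim_dist, target), sim_dist.n_bout


def run_ga(
    template: CircuitModel,
    snippet: Snippet,
    cfg: GAConfig | None = None,
) -> FitResult:
    """Fit (I_e, I_tonic, w_e, w_i) of ``template`` to the snippet's
    six-type bout distribution. Reproducible under ``cfg.seed``;
    evaluations are cached by rounded parameter vector.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    target = snippet.target_distribution()
    if target.n_bout == 0:
        raise ValueError("target snippet contains no bouts")
    lo = np.array([cfg.bounds[k][0] for k in PARAM_NAMES])
    hi = np.array([cfg.bounds[k][1] for k in PARAM_NAMES])
    pop = lo + rng.random((cfg.population_size, 4)) * (hi - lo)
    if cfg.warm_start and cfg.population_size > 1:
        current = {
            "I_e": template.nonlinearity.I_e,
            "I_tonic": template.I_tonic,
            "w_e": next(
                (s.weight for s in template.synapses if s.sign == "excitatory"),
                lo[2],
            ),
            "w_i": next(
                (s.weight for s in template.synapses if s.sign == "inhibitory"),
                lo[3],
            ),
        }
        pop[0] = np.clip([current[k] for k in PARAM_NAMES], lo, hi)
    cache: dict[tuple, tuple[float, int]] = {}

    def score(vec: np.ndarray) -> tuple[float, int]:
        key = tuple(np.round(vec, cfg.cache_decimals))
        if key not in cache:
            cache[key] = evaluate_candidate(
                template, dict(zip(PARAM_NAMES, vec)), snippet, target
            )
        return cache[key]

    trace: list[float] = []
    scores = np.array([score(v)[0] for v in pop])
    for _ in range(cfg.n_generations):
        order = np.argsort(scores, kind="stable")
        pop, scores = pop[order], scores[order]
        if not np.isfinite(scores[0]):
            raise FloatingPointError("all GA evaluations non-finite")
        trace.append(float(scores[0]))
        elite = pop[: cfg.elitism].copy()
        n_imm = min(cfg.immigrants, cfg.population_size - cfg.elitism)
        children = [
            lo + rng.random(4) * (hi - lo) for _ in range(n_imm)
        ]  # random immigrants guard against population collapse
        while len(children) < cfg.population_size - cfg.elitism:
            idx = rng.integers(0, cfg.population_size, cfg.tournament_size)
            a = pop[idx[np.argmin(scores[idx])]]
            idx = rng.integers(0, cfg.population_size, cfg.tournament_size)
            b = pop[idx[np.argmin(scores[idx])]]
            child = a.copy()
            if rng.random() < cfg.crossover_prob:
                mix = rng.random(4)
                child = mix * a + (1 - mix) * b
            mutate = rng.random(4) < cfg.mutation_prob
            child = np.where(
                mutate,
                child + rng.standard_normal(4) * cfg.mutation_scale * (hi - lo),
                child,
            )
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elite] + children)
        scores = np.array([score(v)[0] for v in pop])
    order = np.argsort(scores, kind="stable")
    pop, scores = pop[order], scores[order]
    trace.append(float(scores[0]))
    best = pop[0]
    best_score, n_sim = score(best)
    return FitResult(
        params=dict(zip(PARAM_NAMES, map(float, best))),
        objective=float(best_score),
        trace=trace,
        variant=template.variant,
        n_bout_sim=n_sim,
        n_bout_target=target.n_bout,
        n_evaluations=len(cache),
    )


def compare_variants(
    template: CircuitModel,
    variants: list[str],
    snippets: list[Snippet],
    cfg: GAConfig | None = None,
) -> pd.DataFrame:
    """One GA fit per (variant, snippet); returns a tidy table of fit
    errors for ranking model variants.

    Each fit derives its own seed from ``cfg.seed`` and its row indices,
    so results are independent of evaluation order.
    """
    if len(variants) < 1:
        raise ValueError("need at least one variant")
    cfg = cfg or GAConfig()
    rows = []
    for vi, variant in enumerate(variants):
        model = apply_variant(template, variant)
        for si, snippet in enumerate(snippets):
            res = run_ga(model, snippet, cfg.derive(cfg.seed * 1009 + vi * 101 + si))
            rows.append(
                {
                    "variant": variant,
                    "snippet": si,
                    "objective": res.objective,
                    "n_bout_sim": res.n_bout_sim,
                    "n_bout_target": res.n_bout_target,
                    **{f"param_{k}": v for k, v in res.params.items()},
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "objective",
    "Snippet",
    "select_snippet",
    "GAConfig",
    "FitResult",
    "evaluate_candidate",
    "run_ga",
    "compare_variants",
]
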