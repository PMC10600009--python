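"""Fit the circuit's four free parameters to synthetic song statistics.

Selects a 120-s snippet with at least 10% far bouts from a synthetic
recording and runs a small genetic algorithm minimizing the
RMSD + 0.1 * |delta n_bout| objective over (I_e, I_tonic, w_e, w_i).
The trace is the best objective per generation (non-increasing under
elitism); lower is better, 0 means the six-type bout distribution and
the bout count are matched exactly.
"""

from courtsong import annotate, circuit, fit, synth

params = synth.SynthParams(seed=5)
traj = synth.generate_trajectory(params, 600.0)
song = annotate.merge_close_bouts(
    annotate.filter_bouts_by_snr(synth.generate_song(traj, params))
)
snippet = fit.select_snippet(song, traj, length=120.0, seed=3)
target = snippet.target_distribution()
print(f"target ({target.n_bout} bouts):",
      {k: round(v, 2) for k, v in target.freqs.items()})

cfg = fit.GAConfig(population_size=12, n_generations=10, seed=1)
res = fit.run_ga(circuit.default_model(), snippet, cfg)
print("best parameters:", {k: round(v, 2) for k, v in res.params.items()})
print(f"objective {res.objective:.3f} after {res.n_evaluations} evaluations")
print("trace:", [round(x, 3) for x in res.trace])
print(f"simulated {res.n_bout_sim} bouts vs {res.n_bout_target} in the target")
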