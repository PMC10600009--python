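"""Generate a synthetic courtship recording and compute bout statistics.

Builds a 30-min seeded recording (trajectory + song + taps), applies the
annotation pipeline (SNR filter at 1.3, 0.5-s bout merging), and prints
the bout-type mix split by far/near context (4-mm threshold). Far from
the female nearly all bouts are simple pulse; near her, complex
pulse-leading bouts take a large share and carry the elevated tap rate.
"""

from courtsong import annotate, synth

params = synth.SynthParams(seed=1)
traj = synth.generate_trajectory(params, duration=1800.0)
song = synth.generate_song(traj, params)
taps = synth.generate_taps(traj, song, params)

clean = annotate.merge_close_bouts(annotate.filter_bouts_by_snr(song))
print(f"{len(song.bouts)} bouts generated, {len(clean.bouts)} after SNR filter + merge")

for context in ("far", "near"):
    dist = annotate.bout_distribution(clean, traj, context=context)
    mix = ", ".join(f"{k}: {100 * v:.1f}%" for k, v in dist.freqs.items())
    print(f"{context:>4} (n={dist.n_bout}): {mix}")

rates = annotate.mean_tap_rates_by_category(clean, taps)
for cat in ("simple_p", "complex_p"):
    r = rates[cat]
    print(
        f"tap rate {cat}: during={r['R_during']:.3f}/s "
        f"before={r['R_before']:.3f}/s (n={r['n']} bouts)"
    )
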