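"""One-time calibration of the synthetic bout-type mix.

Runs the full annotation pipeline (SNR filter, bout merging, labeling,
context assignment) on synthetic data for a grid of multinomial-logit
coefficients and prints the far/near bout-type fractions, to check the
generator against its calibration targets: far simple-pulse fraction
> 95%, near simple-pulse ~55%, near complex 'ps...' ~30%.

The shipped defaults (synth.DEFAULT_TYPE_LOGITS) were chosen with this
script; rerun it after changing generator parameters:

    python scripts/calibrate_synth.py
"""

import numpy as np

from courtsong import annotate, synth


def context_stats(logits: dict, seed: int = 1, duration: float = 9000.0) -> dict:
    params = synth.SynthParams(seed=seed, bout_type_logits=logits)
    traj = synth.generate_trajectory(params, duration)
    song = synth.generate_song(traj, params)
    clean = annotate.merge_close_bouts(annotate.filter_bouts_by_snr(song))
    out = {}
    for context in ("far", "near"):
        dist = annotate.bout_distribution(clean, traj, context=context)
        f = dist.freqs
        out[context] = {
            "simple_p_pct": 100 * f["p"],
            "complex_ps_pct": 100 * (f["ps"] + f["psp..."]),
            "n_bout": dist.n_bout,
        }
    return out


def main() -> None:
    candidates = [
        synth.DEFAULT_TYPE_LOGITS,
        {"complex_p": (2.6, -1.3), "simple_s": (0.8, -1.3), "complex_s": (0.9, -1.3)},
        {"complex_p": (3.0, -1.5), "simple_s": (1.2, -1.5), "complex_s": (1.3, -1.5)},
    ]
    for logits in candidates:
        tag = "(default)" if logits is synth.DEFAULT_TYPE_LOGITS else ""
        print(f"logits={logits} {tag}")
        for seed in (1, 2, 3):
            stats = context_stats(logits, seed=seed)
            print(
                f"  seed {seed}: far p {stats['far']['simple_p_pct']:.1f}% "
                f"(n={stats['far']['n_bout']}), "
                f"near p {stats['near']['simple_p_pct']:.1f}%, "
                f"near ps... {stats['near']['complex_ps_pct']:.1f}% "
                f"(n={stats['near']['n_bout']})"
            )


if __name__ == "__main__":
    main()
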