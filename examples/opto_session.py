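"""Simulate an optogenetic session and classify rebound song.

Builds the 16-block factorial protocol (irradiances 0/1/25/205 uW/mm^2 x
duty cycles 1/64..2/8, pooled zero blocks, 1/8-Hz stimulation, 120-s
blocks of 15 trials), draws stimulus-locked pulse and post-offset sine
responses, and computes trial-wise song probabilities plus the rebound
classification (sine starting after stimulus offset within a bout that
started during the stimulus).
"""

import numpy as np

from courtsong import annotate, synth

protocol = synth.factorial_protocol(shuffle_seed=0)
responder = synth.ResponderSpec(pulse_max=0.9, rebound_max=0.6, k=2.0)
trials, song = synth.generate_opto_session(protocol, responder, seed=1)
print(f"{len(protocol.blocks)} blocks, {len(trials)} trials, "
      f"{len(song.bouts)} evoked bouts")

probs = annotate.song_probabilities(trials, song, bin_width=0.25)
print(f"peak P(pulse) across trials: {probs['pulse'].max():.2f}; "
      f"peak P(sine): {probs['sine'].max():.2f}")

stim = trials.stim_intervals()
n_rebound = sum(
    any(annotate.classify_rebound(b, stim)[1]) for b in song.bouts
)
print(f"{n_rebound} bouts contain rebound song "
      "(train starting after the offset of the stimulus the bout began in)")
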