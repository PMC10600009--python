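"""Simulate the four-node circuit at constant far/near distance.

The only input is male-female distance, mapped to a drive current on the
pC2 node. Weak drive (4.2 mm) yields pure simple pulse song; strong
drive (1.5 mm) silences the tonic inhibitory node (disinhibition) and
releases the pulse-sine half-center, producing complex 'psp...' bouts.
"""

import numpy as np

from courtsong import circuit

model = circuit.default_model()
t = np.arange(0.0, 20.0, 1 / 60)

for dist in (4.2, 1.5):
    result = circuit.simulate(model, t, np.full_like(t, dist))
    song = circuit.decode_song(result)
    labels = [b.label if len(b.label) <= 10 else b.label[:10] + "..."
              for b in song.bouts]
    counts = {name: result.spikes[name].size for name in circuit.NODES}
    print(f"mfDist = {dist} mm: spikes {counts}")
    print(f"  decoded bouts: {labels}")
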