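import numpy as np
import pytest

from courtsong import annotate, synth
from courtsong.types import PULSE, SINE, Bout, SongAnnotation, Train


def make_bout(spec: str, start: float = 0.0, train_dur: float = 0.5,
              gap: float = 0.05, amplitude: float = 3.0) -> Bout:
    """Bout from a compact mode string, e.g. 'psp' -> pulse, sine, pulse."""
    trains = []
    t = start
    for ch in spec:
        mode = PULSE if ch == "p" else SINE
        if mode == PULSE:
            trains.append(Train(mode=mode, start=t, end=t + train_dur,
                                events=list(np.arange(t + 0.02, t + train_dur, 0.035))))
        else:
            trains.append(Train(mode=mode, start=t, end=t + train_dur,
                                amplitude=amplitude))
        t += train_dur + gap
    return Bout(trains=trains)


@pytest.fixture(scope="session")
def default_params():
    return synth.SynthParams(seed=1)


@pytest.fixture(scope="session")
def medium_dataset(default_params):
    """A 1200-s synthetic recording shared across tests (seeded)."""
    traj = synth.generate_trajectory(default_params, 1200.0)
    song = synth.generate_song(traj, default_params)
    taps = synth.generate_taps(traj, song, default_params)
    return traj, song, taps


@pytest.fixture(scope="session")
def clean_song(medium_dataset):
    _, song, _ = medium_dataset
    return annotate.merge_close_bouts(annotate.filter_bouts_by_snr(song))
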