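"""Song post-processing and behavioral statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from courtsong import annotate, synth
from courtsong.types import (
    PULSE,
    SINE,
    Bout,
    CourtshipTrajectory,
    SongAnnotation,
    TapSeries,
    Train,
    collapse_modes,
)
from tests.conftest import make_bout


def flat_trajectory(dist, duration=100.0, fps=60.0):
    n = int(duration * fps)
    t = np.arange(n) / fps
    d = np.full(n, float(dist)) if np.isscalar(dist) else np.asarray(dist)
    z = np.ones(n)
    return CourtshipTrajectory(t=t, mfDist=d, mfAngle=z, fmAngle=z, mFV=z,
                               fFV=z, mLS=z, fLS=z, mRS=z, fRS=z)


class TestNoiseAmplitude:
    def test_constant_two_channel_takes_loudest(self):
        seg = np.vstack([np.full(100, 1.0), np.full(100, -3.0)])
        assert annotate.noise_amplitude(seg) == pytest.approx(3.0)

    def test_single_channel_matches_percentile(self):
        samples = np.arange(1.0, 101.0)
        expected = np.percentile(samples, 99)  # linear interpolation
        assert annotate.noise_amplitude(samples[None, :]) == pytest.approx(expected)

    def test_all_zero_segment_gives_zero(self):
        assert annotate.noise_amplitude(np.zeros((2, 50))) == 0.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            annotate.noise_amplitude(np.empty((2, 0)))


class TestSineSnr:
    def test_ratio(self):
        bout = Bout(trains=[Train(mode=SINE, start=0, end=1, amplitude=2.6)])
        assert annotate.sine_snr(bout, 2.0) == [pytest.approx(1.3)]

    def test_pulse_only_bout_empty(self):
        assert annotate.sine_snr(make_bout("p"), 1.0) == []

    def test_degenerate_noise_rejected(self):
        with pytest.raises(ValueError):
            annotate.sine_snr(make_bout("s"), 0.0)

    def test_filter_pass_rate_matches_lognormal_tail(self):
        # generated sine SNRs are lognormal; the SNR>=1.3 pass rate of
        # sine-containing bouts must match the analytic tail probability
        params = synth.SynthParams(seed=7)
        traj = flat_trajectory(2.0, duration=4000.0)
        song = synth.generate_song(traj, params)
        sine_bouts = [b for b in song.bouts if "s" in b.label]
        assert len(sine_bouts) > 200
        noise_amp = annotate.noise_amplitude(song.noise_segment)
        kept = annotate.filter_bouts_by_snr(song, 1.3)
        kept_sine = [b for b in kept.bouts if "s" in b.label]
        mu, sg = params.snr_lognorm
        p_pass = 1.0 - norm.cdf((np.log(1.3) - mu) / sg)
        # bouts can contain several sine trains; per-bout pass prob is
        # p_pass ** n_trains, so compare against the exact product
        expected = np.mean(
            [p_pass ** sum(tr.mode == SINE for tr in b.trains) for b in sine_bouts]
        )
        observed = len(kept_sine) / len(sine_bouts)
        sd = np.sqrt(expected * (1 - expected) / len(sine_bouts))
        assert abs(observed - expected) < 4 * sd


class TestSnrFilter:
    def test_zero_threshold_is_identity(self):
        song = SongAnnotation(bouts=[make_bout("ps"), make_bout("p", start=2.0)])
        out = annotate.filter_bouts_by_snr(song, threshold=0.0, noise_amp=1.0)
        assert len(out.bouts) == 2

    def test_low_snr_sine_removes_whole_bout(self):
        song = SongAnnotation(bouts=[make_bout("ps", amplitude=1.2)])
        out = annotate.filter_bouts_by_snr(song, threshold=1.3, noise_amp=1.0)
        assert out.bouts == []

    def test_infinite_threshold_keeps_only_pulse_bouts(self):
        song = SongAnnotation(
            bouts=[make_bout("p"), make_bout("ps", start=3.0), make_bout("s", start=6.0)]
        )
        out = annotate.filter_bouts_by_snr(song, threshold=np.inf, noise_amp=1.0)
        assert [b.label for b in out.bouts] == ["p"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        song = SongAnnotation(
            bouts=[make_bout("ps", start=3.0 * i, amplitude=rng.lognormal(0.3, 0.6))
                   for i in range(30)]
        )
        counts = [
            len(annotate.filter_bouts_by_snr(song, thr, noise_amp=1.0).bouts)
            for thr in (0.5, 1.0, 1.3, 2.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMergeCloseBouts:
    def test_split_psp_is_restored(self):
        ps = make_bout("ps", start=9.0)  # ends at 10.05
        sp = make_bout("sp", start=10.3)
        merged = annotate.merge_close_bouts(SongAnnotation(bouts=[ps, sp]))
        assert len(merged.bouts) == 1
        assert merged.bouts[0].label == "psp"  # adjacent s trains collapse

    def test_gap_above_threshold_unmerged(self):
        a = make_bout("p", start=0.0, train_dur=1.0)
        b = make_bout("s", start=1.6)
        merged = annotate.merge_close_bouts(SongAnnotation(bouts=[a, b]))
        assert len(merged.bouts) == 2

    def test_chain_of_close_bouts_collapses_transitively(self):
        # oracle: transitive closure over pairwise gaps < 0.5 s
        bouts = [make_bout("p", start=1.3 * i, train_dur=0.9) for i in range(3)]
        merged = annotate.merge_close_bouts(SongAnnotation(bouts=bouts))
        assert len(merged.bouts) == 1
        assert merged.bouts[0].label == "p"

    def test_idempotent(self, clean_song):
        once = annotate.merge_close_bouts(clean_song)
        twice = annotate.merge_close_bouts(once)
        assert [(b.start, b.end, b.label) for b in once.bouts] == [
            (b.start, b.end, b.label) for b in twice.bouts
        ]


class TestLabelBout:
    def test_single_pulse_train(self):
        assert annotate.label_bout(make_bout("p")) == ("p", "simple_p")

    def test_pulse_sine_pulse(self):
        assert annotate.label_bout(make_bout("psp")) == ("psp", "complex_p")

    def test_adjacent_same_mode_trains_collapse(self):
        assert annotate.label_bout(make_bout("ssp")) == ("sp", "complex_s")

    @given(st.lists(st.sampled_from([PULSE, SINE]), min_size=1, max_size=12))
    @settings(max_examples=500, deadline=None)
    def test_label_equals_run_length_encoding_oracle(self, modes):
        bout = make_bout("".join("p" if m == PULSE else "s" for m in modes))
        # run-length-encoding oracle
        rle = []
        for m in modes:
            if not rle or rle[-1] != m:
                rle.append(m)
        expected = "".join("p" if m == PULSE else "s" for m in rle)
        assert bout.label == expected
        assert collapse_modes(modes) == expected


class TestAssignContext:
    def test_near_exemplar(self):
        traj = flat_trajectory(1.5)
        assert annotate.assign_context(make_bout("p", start=10.0), traj) == "near"

    def test_far_exemplar(self):
        traj = flat_trajectory(4.2)
        assert annotate.assign_context(make_bout("p", start=10.0), traj) == "far"

    def test_boundary_mean_exactly_four_is_far(self):
        traj = flat_trajectory(4.0)
        assert annotate.assign_context(make_bout("p", start=10.0), traj) == "far"

    def test_bout_outside_span_rejected(self):
        traj = flat_trajectory(2.0, duration=5.0)
        with pytest.raises(ValueError):
            annotate.assign_context(make_bout("p", start=10.0), traj)


class TestBoutDistribution:
    def test_single_bout(self):
        dist = annotate.bout_distribution(SongAnnotation(bouts=[make_bout("p")]))
        assert dist.freqs["p"] == 1.0
        assert sum(dist.freqs.values()) == pytest.approx(1.0)

    def test_hand_count(self):
        song = SongAnnotation(
            bouts=[
                make_bout("p", start=0.0),
                make_bout("p", start=2.0),
                make_bout("ps", start=4.0),
                make_bout("psp", start=7.0),
            ]
        )
        dist = annotate.bout_distribution(song)
        assert dist.as_vector() == pytest.approx([0.5, 0.25, 0.25, 0, 0, 0])

    def test_empty_song_flagged_undefined(self):
        dist = annotate.bout_distribution(SongAnnotation(bouts=[]))
        assert not dist.defined
        assert all(np.isnan(v) for v in dist.freqs.values())

    def test_normalization_per_context_split(self, clean_song, medium_dataset):
        traj, _, _ = medium_dataset
        for context in (None, "far", "near"):
            dist = annotate.bout_distribution(clean_song, traj, context=context)
            assert abs(sum(dist.freqs.values()) - 1.0) < 1e-12


class TestSongProbabilities:
    def _trials(self, n=15, period=8.0):
        from courtsong.types import Trial, TrialSet

        return TrialSet(
            trials=[
                Trial(block_id=0, irradiance=25.0, duty_cycle=0.125,
                      t_start=i * period, t_end=(i + 1) * period,
                      stim_intervals=[(i * period, i * period + 1.0)])
                for i in range(n)
            ]
        )

    def test_mode_active_in_all_trials_gives_one(self):
        trials = self._trials(n=5)
        bouts = [make_bout("p", start=i * 8.0 + 2.0, train_dur=1.0) for i in range(5)]
        probs = annotate.song_probabilities(trials, SongAnnotation(bouts=bouts),
                                            bin_width=0.5)
        bin_idx = np.searchsorted(probs["t"], 2.3)
        assert probs["pulse"][bin_idx] == pytest.approx(1.0)

    def test_fraction_of_trials_hand_count(self):
        trials = self._trials(n=15)
        bouts = [make_bout("s", start=i * 8.0 + 3.0, train_dur=1.0) for i in range(3)]
        probs = annotate.song_probabilities(trials, SongAnnotation(bouts=bouts),
                                            bin_width=0.5)
        assert probs["n_trials"] == 15
        bin_idx = np.searchsorted(probs["t"], 3.3)
        assert probs["sine"][bin_idx] == pytest.approx(3 / 15)

    def test_zero_trials_rejected(self):
        from courtsong.types import TrialSet

        with pytest.raises(ValueError):
            annotate.song_probabilities(TrialSet(trials=[]), SongAnnotation(bouts=[]))


class TestClassifyRebound:
    def test_sine_after_offset_in_stim_started_bout_is_rebound(self):
        bout = Bout(trains=[
            Train(mode=PULSE, start=1.0, end=1.8),
            Train(mode=SINE, start=2.2, end=2.8),
        ])
        timing, flags = annotate.classify_rebound(bout, [(0.5, 2.0)])
        assert timing == "acute"
        assert flags == [False, True]

    def test_bout_after_offset_is_persistent(self):
        bout = make_bout("ps", start=3.0)
        timing, flags = annotate.classify_rebound(bout, [(0.0, 2.0)])
        assert timing == "persistent"
        assert not any(flags)

    def test_bout_inside_stimulus_is_acute_without_rebound(self):
        bout = make_bout("ps", start=0.5)
        timing, flags = annotate.classify_rebound(bout, [(0.0, 5.0)])
        assert timing == "acute"
        assert not any(flags)

    def test_matches_brute_force_scan_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            onsets = np.sort(rng.uniform(0, 50, 5))
            ivals = [(float(o), float(o + rng.uniform(0.5, 2.0))) for o in onsets]
            ivals = [iv for i, iv in enumerate(ivals)
                     if i == 0 or iv[0] >= ivals[i - 1][1]]
            n_tr = rng.integers(1, 5)
            t0 = rng.uniform(0, 50)
            trains = []
            t = t0
            for i in range(n_tr):
                dur = rng.uniform(0.1, 1.0)
                trains.append(Train(mode=PULSE if i % 2 == 0 else SINE,
                                    start=t, end=t + dur))
                t += dur + rng.uniform(0.0, 0.5)
            bout = Bout(trains=trains)
            timing, flags = annotate.classify_rebound(bout, ivals)
            # brute force: scan every (train, interval) pair
            containing = [iv for iv in ivals if iv[0] <= bout.start < iv[1]]
            if not containing:
                assert timing == "persistent" and not any(flags)
            else:
                assert timing == "acute"
                off = containing[0][1]
                assert flags == [tr.start >= off for tr in bout.trains]


class TestTapRate:
    def _taps(self, times, duration=100.0, fps=60.0):
        n = int(duration * fps)
        t = np.arange(n) / fps
        is_tap = np.zeros(n, int)
        for tt in times:
            is_tap[int(round(tt * fps))] = 1
        return TapSeries(t=t, is_tap=is_tap)

    def test_rate_is_count_over_duration(self):
        bout = make_bout("p", start=10.0, train_dur=2.0)
        taps = self._taps([10.2, 10.6, 11.0, 11.4])
        res = annotate.tap_rate(bout, taps)
        assert res.R_during == pytest.approx(2.0)
        assert res.n_before == 0

    def test_no_taps_gives_zero_rates(self):
        bout = make_bout("p", start=10.0, train_dur=2.0)
        res = annotate.tap_rate(bout, self._taps([]))
        assert res.R_during == 0.0 and res.R_before == 0.0

    def test_truncated_before_window_flagged(self):
        bout = make_bout("p", start=0.5, train_dur=2.0)
        res = annotate.tap_rate(bout, self._taps([]))
        assert res.truncated_before

    def test_complex_bouts_have_higher_tap_rate(self, medium_dataset):
        traj, song, taps = medium_dataset
        rates = annotate.mean_tap_rates_by_category(song, taps)
        assert rates["complex_p"]["R_during"] > rates["simple_p"]["R_during"]
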