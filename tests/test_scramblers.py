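import itertools

import numpy as np
import pytest

from vocscram.audio import AudioSignal, envelope, normalize, total_energy
from vocscram.scramblers import (
    Provenance,
    ScrambleParams,
    frequency_scramble,
    phase_scramble,
    scramble,
    time_scramble,
)
from vocscram.synthetic import make_burst
from tests.conftest import SR, tone


def burst(valence="anger", seed=3, duration=1.0, f0=140.0):
    return make_burst("male", valence, duration, f0, sample_rate=SR, seed=seed)


class TestScrambleParams:
    def test_unknown_method(self):
        with pytest.raises(ValueError):
            ScrambleParams(method="wavelet")

    def test_hop_exceeding_window(self):
        with pytest.raises(ValueError):
            ScrambleParams(method="frequency", fft_window=256, fft_hop=512)

    def test_ramp_too_long(self):
        with pytest.raises(ValueError):
            ScrambleParams(method="time", time_window_ms=2.0, ramp_ms=1.0)


class TestFrequencyScramble:
    params = ScrambleParams(method="frequency", seed=5)

    def test_identity_permutation_reconstructs(self):
        sig = burst()
        out = frequency_scramble(
            sig, self.params, permutation=lambda rng, n: np.arange(n)
        )
        expected = normalize(sig).samples[: len(out)]
        assert np.max(np.abs(out.samples - expected)) < 1e-6

    def test_deterministic(self):
        sig = burst()
        a = frequency_scramble(sig, self.params)
        b = frequency_scramble(sig, self.params)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        sig = burst()
        a = frequency_scramble(sig, ScrambleParams(method="frequency", seed=1))
        b = frequency_scramble(sig, ScrambleParams(method="frequency", seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_per_window_magnitudes_and_rms_preserved(self):
        """Window-level oracle: replay the recorded permutations on the
        input's analysis windows and check the magnitude multiset and the
        RMS of every rebuilt window against the original window's."""
        sig = burst()
        recorded = []

        def record(rng, n):
            perm = rng.permutation(n)
            recorded.append(perm)
            return perm

        frequency_scramble(sig, self.params, permutation=record)

        win, hop = self.params.fft_window, self.params.fft_hop
        x = normalize(sig).samples
        n_windows = 1 + (len(x) - win) // hop
        padded = np.concatenate(
            [np.zeros(hop), x[: win + (n_windows - 1) * hop], np.zeros(hop)]
        )
        taper = np.hanning(win + 1)[:win]
        shuffleable = np.arange(1, win // 2)
        starts = range(0, len(padded) - win + 1, hop)
        assert len(recorded) == len(list(starts))
        for perm, start in zip(recorded, starts):
            chunk = padded[start : start + win] * taper
            spec = np.fft.rfft(chunk)
            scrambled = spec.copy()
            scrambled[shuffleable] = spec[shuffleable][perm]
            assert np.allclose(
                np.sort(np.abs(scrambled)), np.sort(np.abs(spec)), rtol=1e-9
            )
            rebuilt = np.fft.irfft(scrambled, n=win)
            rms_in = np.sqrt(np.mean(chunk**2))
            if rms_in > 1e-9:
                assert np.sqrt(np.mean(rebuilt**2)) == pytest.approx(
                    rms_in, rel=0.01
                )

    def test_energy_preserved_before_normalization(self):
        sig = burst()
        raw = frequency_scramble(sig, self.params, normalize_output=False)
        x = normalize(sig).samples[: len(raw)]
        assert total_energy(raw) == pytest.approx(float(np.sum(x**2)), rel=0.01)

    def test_broadband_envelope_similar(self):
        sig = burst(valence="happiness", duration=1.5)
        out = frequency_scramble(sig, self.params)
        reference = normalize(sig).samples[: len(out)]
        e_in = envelope(AudioSignal(reference, SR)).values
        e_out = envelope(out).values
        assert np.corrcoef(e_in, e_out)[0, 1] > 0.8

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="window"):
            frequency_scramble(AudioSignal(np.ones(100), SR), self.params)


class TestPhaseScramble:
    def test_tone_below_threshold_unchanged(self, sine_220):
        params = ScrambleParams(method="phase", pitch_threshold_hz=300.0, seed=1)
        out, threshold = phase_scramble(sine_220, params)
        assert threshold == 300.0
        expected = normalize(sine_220).samples
        assert np.max(np.abs(out.samples - expected)) < 1e-6

    def test_low_component_kept_high_band_magnitude_kept(self):
        sr = SR
        t = np.arange(sr) / sr
        sig = AudioSignal(
            np.sin(2 * np.pi * 200 * t) + 0.5 * np.sin(2 * np.pi * 1500 * t), sr
        )
        params = ScrambleParams(method="phase", pitch_threshold_hz=300.0, seed=2)
        out, _ = phase_scramble(sig, params, normalize_output=False)
        spec_in = np.fft.rfft(normalize(sig).samples)
        spec_out = np.fft.rfft(out.samples)
        freqs = np.fft.rfftfreq(len(sig), 1 / sr)
        low = freqs <= 300.0
        assert np.allclose(spec_out[low], spec_in[low], atol=1e-8)
        mags_in, mags_out = np.sort(np.abs(spec_in)), np.sort(np.abs(spec_out))
        assert np.max(np.abs(mags_in - mags_out)) < 1e-6 * mags_in.max()

    def test_sorted_magnitude_and_energy_preserved(self):
        sig = burst()
        params = ScrambleParams(method="phase", seed=3)
        out, threshold = phase_scramble(sig, params, normalize_output=False)
        x = normalize(sig).samples
        assert 75 <= threshold <= 2000
        assert len(out) == len(sig)
        assert total_energy(out) == pytest.approx(float(np.sum(x**2)), rel=0.01)
        mags_in = np.sort(np.abs(np.fft.rfft(x)))
        mags_out = np.sort(np.abs(np.fft.rfft(out.samples)))
        assert np.max(np.abs(mags_in - mags_out)) < 1e-6 * mags_in.max()

    def test_deterministic(self):
        sig = burst()
        params = ScrambleParams(method="phase", seed=4)
        a, _ = phase_scramble(sig, params)
        b, _ = phase_scramble(sig, params)
        assert np.array_equal(a.samples, b.samples)

    def test_threshold_above_nyquist(self, sine_220):
        params = ScrambleParams(method="phase", pitch_threshold_hz=SR, seed=0)
        with pytest.raises(ValueError, match="Nyquist"):
            phase_scramble(sine_220, params)

    def test_unvoiced_signal_without_threshold(self):
        noise = AudioSignal(np.random.default_rng(0).standard_normal(SR), SR)
        with pytest.raises(ValueError, match="threshold"):
            phase_scramble(noise, ScrambleParams(method="phase", seed=0))


class TestTimeScramble:
    params = ScrambleParams(method="time", time_window_ms=6.0, seed=7)

    def test_duration_conserved_exactly(self):
        sig = burst()
        out = time_scramble(sig, self.params)
        assert len(out) == len(sig)

    def test_identity_permutation_only_tapers_edges(self, sine_220):
        win = int(round(0.006 * SR))
        n_windows = int(np.ceil(len(sine_220) / win))
        out = time_scramble(
            sine_220, self.params, permutation=list(range(n_windows))
        )
        expected = normalize(sine_220).samples
        n_ramp = int(round(0.001 * SR))
        mask = np.ones(len(expected), dtype=bool)
        for b in range(0, len(expected), win):
            mask[b : b + n_ramp] = False
            mask[max(0, b - n_ramp) : b] = False
        mask[-n_ramp:] = False
        # interiors match up to the global renormalization scalar
        e, o = expected[mask], out.samples[mask]
        scale = (o @ e) / (e @ e)
        assert np.max(np.abs(o - scale * e)) < 1e-9

    def test_energy_strictly_reduced(self):
        sig = burst()
        raw = time_scramble(sig, self.params, normalize_output=False)
        assert total_energy(raw) < total_energy(normalize(sig))

    def test_window_multiset_invariant(self):
        """48 kHz, 120 ms, 12-ms windows: exactly 10 windows whose
        interiors (outside the ramps) are a permutation of the input's."""
        sr = 48000
        rng = np.random.default_rng(12)
        sig = AudioSignal(rng.uniform(-1, 1, int(0.120 * sr)), sr)
        params = ScrambleParams(method="time", time_window_ms=12.0, seed=9)
        win = int(round(0.012 * sr))
        n_ramp = int(round(0.001 * sr))
        assert len(sig) == 10 * win
        out = time_scramble(sig, params, normalize_output=False)
        x = normalize(sig).samples

        def interiors(arr):
            return sorted(
                tuple(np.round(arr[b + n_ramp : b + win - n_ramp], 12))
                for b in range(0, len(arr), win)
            )

        assert interiors(out.samples) == interiors(x)

    def test_brute_force_four_window_oracle(self):
        """The seeded output must equal one of the 24 explicit
        permutations of a 4-window toy signal, ramps applied."""
        sr = 8000
        win = int(round(0.006 * sr))  # 48 samples
        n_ramp = int(round(0.001 * sr))  # 8 samples
        rng = np.random.default_rng(21)
        x = rng.uniform(-1, 1, 4 * win)
        sig = AudioSignal(x, sr)
        params = ScrambleParams(method="time", time_window_ms=6.0, seed=13)
        out = time_scramble(sig, params, normalize_output=False)

        xn = x * (0.99 / np.max(np.abs(x)))
        ramp_up = np.linspace(0, 1, n_ramp, endpoint=False)
        windows = [xn[i * win : (i + 1) * win].copy() for i in range(4)]
        for w in windows:
            w[:n_ramp] *= ramp_up
            w[-n_ramp:] *= ramp_up[::-1]
        matches = [
            np.max(np.abs(out.samples - np.concatenate([windows[i] for i in p])))
            < 1e-12
            for p in itertools.permutations(range(4))
        ]
        assert sum(matches) == 1

    def test_trailing_remainder_kept(self):
        sr = 8000
        win = int(round(0.006 * sr))
        sig = AudioSignal(
            np.random.default_rng(2).uniform(-1, 1, 3 * win + 11), sr
        )
        out = time_scramble(sig, self.params)
        assert len(out) == len(sig)

    def test_signal_too_short(self):
        with pytest.raises(ValueError, match="two"):
            time_scramble(AudioSignal(np.ones(10), SR), self.params)

    def test_bad_permutation_rejected(self):
        sig = burst()
        with pytest.raises(ValueError, match="permutation"):
            time_scramble(sig, self.params, permutation=[0, 0, 1])

    def test_deterministic(self):
        sig = burst()
        a = time_scramble(sig, self.params)
        b = time_scramble(sig, self.params)
        assert np.array_equal(a.samples, b.samples)


class TestDispatcher:
    def test_frequency_dispatch_matches_direct(self):
        sig = burst()
        params = ScrambleParams(method="frequency", seed=6)
        via_dispatch, prov = scramble(sig, params)
        direct = frequency_scramble(sig, params)
        assert np.array_equal(via_dispatch.samples, direct.samples)
        assert prov.method == "frequency"
        assert prov.seed == 6

    def test_time_window_sizes_differ_same_duration(self):
        sig = burst()
        out6, _ = scramble(sig, ScrambleParams(method="time", time_window_ms=6, seed=1))
        out12, _ = scramble(
            sig, ScrambleParams(method="time", time_window_ms=12, seed=1)
        )
        assert len(out6) == len(out12) == len(sig)
        assert not np.array_equal(out6.samples, out12.samples)

    def test_phase_provenance_records_threshold(self):
        sig = burst()
        _, prov = scramble(sig, ScrambleParams(method="phase", seed=2))
        assert prov.pitch_threshold_hz is not None
        assert 75 <= prov.pitch_threshold_hz <= 2000

    def test_provenance_sidecar_round_trip(self, tmp_path):
        sig = burst()
        _, prov = scramble(sig, ScrambleParams(method="phase", seed=2))
        path = prov.write(tmp_path / "out.json")
        back = Provenance.read(path)
        assert back == prov
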