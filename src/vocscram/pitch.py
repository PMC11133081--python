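"""Fundamental-frequency (F0) estimation.

Frame-wise normalized autocorrelation with sub-sample (parabolic) lag
interpolation. The median F0 over voiced frames is the stimulus-specific
threshold used by phase scrambling; the default analysis range of
75-2000 Hz is wide enough to cover both male and female affect bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vocscram.audio import AudioSignal

#: smallest normalized-autocorrelation peak accepted as voiced
DEFAULT_VOICING_THRESHOLD = 0.45
#: frames with RMS below this fraction of the loudest frame are unvoiced
SILENCE_FRACTION = 0.01
#: a shorter-lag peak this close to the global maximum wins (octave guard)
OCTAVE_PEAK_FACTOR = 0.95


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 estimates; unvoiced frames hold NaN."""

    times_s: np.ndarray
    f0_hz: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0_hz)


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def pitch_track(
    signal: AudioSignal,
    fmin: float = 75.0,
    fmax: float = 2000.0,
    frame_ms: float = 40.0,
    hop_ms: float = 10.0,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
) -> PitchTrack:
    """Estimate per-frame F0 by normalized autocorrelation.

    Each frame is mean-subtracted and its autocorrelation is normalized
    by the geometric mean of the energies of the two overlapping
    segments, so a perfectly periodic frame peaks at 1 at the period
    lag. Local maxima in the lag range [sr/fmax, sr/fmin] are candidate
    periods; among candidates within ``OCTAVE_PEAK_FACTOR`` of the best
    one the shortest lag wins, which suppresses period-doubling errors
    on strongly harmonic input. Frames whose best peak falls below
    ``voicing_threshold``, or that are near-silent, are unvoiced (NaN).
    """
    sr = signal.sample_rate
    nyquist = sr / 2
    if not 0 < fmin < fmax < nyquist:
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    frame_len = int(round(frame_ms / 1000 * sr))
    hop = max(1, int(round(hop_ms / 1000 * sr)))
    min_frame = int(np.ceil(2 * sr / fmin))
    if frame_len < min_frame:
        raise ValueError(
            f"frame of {frame_ms} ms too short for fmin={fmin} Hz; "
            f"need at least {min_frame / sr * 1000:.1f} ms (two periods)"
        )
    x = signal.samples
    if len(x) < frame_len:
        # single short frame: analyze what we have if it still fits fmin
        if len(x) < min_frame:
            return PitchTrack(times_s=np.empty(0), f0_hz=np.empty(0))
        frame_len = len(x)
    frames = _frame(x, frame_len, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    n_frames = len(frames)
    times = (np.arange(n_frames) * hop + frame_len / 2) / sr

    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(frame_len - 1, int(np.ceil(sr / fmin)))

    # raw autocorrelation of every frame via FFT
    nfft = 1 << int(np.ceil(np.log2(2 * frame_len)))
    spectra = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spectra * np.conj(spectra), n=nfft, axis=1)[:, : frame_len]

    # normalization: r(tau) = acf(tau) / sqrt(E[0:N-tau] * E[tau:N])
    sq = frames**2
    csum = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    total = csum[:, -1:]
    taus = np.arange(frame_len)
    e_head = total - (csum[:, -1:] - csum[:, frame_len - taus])  # E[0 : N-tau]
    e_tail = total - csum[:, taus]  # E[tau : N]
    denom = np.sqrt(np.maximum(e_head * e_tail, 1e-300))
    r = acf / denom

    rms = np.sqrt(sq.mean(axis=1))
    rms_gate = max(SILENCE_FRACTION * rms.max(initial=0.0), 1e-8)

    f0 = np.full(n_frames, np.nan)
    band = r[:, lag_min : lag_max + 1]
    for i in range(n_frames):
        if rms[i] < rms_gate:
            continue
        seg = band[i]
        interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
        peaks = np.flatnonzero(interior) + 1
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(seg))])
        best = seg[peaks].max()
        if best < voicing_threshold:
            continue
        lag_rel = peaks[seg[peaks] >= OCTAVE_PEAK_FACTOR * best][0]
        lag = lag_rel + lag_min
        # parabolic interpolation around the peak for sub-sample lag
        if 1 <= lag < frame_len - 1:
            y0, y1, y2 = r[i, lag - 1], r[i, lag], r[i, lag + 1]
            denom_p = y0 - 2 * y1 + y2
            if denom_p < 0:
                lag = lag + 0.5 * (y0 - y2) / denom_p
        f0[i] = np.clip(sr / lag, fmin, fmax)

    return PitchTrack(times_s=times, f0_hz=f0)


def median_pitch(
    signal: AudioSignal,
    fmin: float = 75.0,
    fmax: float = 2000.0,
    **kwargs,
) -> float:
    """Median F0 over voiced frames, in Hz.

    Raises if no frame is voiced; callers that must scramble such a
    signal should supply an explicit threshold instead.
    """
    track = pitch_track(signal, fmin=fmin, fmax=fmax, **kwargs)
    voiced = track.f0_hz[track.voiced]
    if len(voiced) == 0:
        raise ValueError(
            "no voiced frames found; supply an explicit pitch threshold "
            "(pitch_threshold_hz) instead of estimating one"
        )
    return float(np.median(voiced))
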