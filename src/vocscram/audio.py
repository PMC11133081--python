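"""Audio I/O, normalization, and acoustic diagnostics.

The unit of exchange is :class:`AudioSignal`, a mono float waveform with
a sample rate. Diagnostics (amplitude envelope, Welch power spectral
density, total energy) are the quantities used to characterize what each
scrambling transform preserves or destroys.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt, welch


class WavIOError(IOError):
    """Raised for missing files or unsupported WAV encodings."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio waveform.

    Parameters
    ----------
    samples
        Amplitudes, dimensionless, nominal range [-1, 1].
    sample_rate
        Samples per second (Hz), > 0.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal samples must be one-dimensional (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class EnvelopeSeries:
    """Non-negative amplitude envelope sampled at ``frame_rate`` Hz."""

    values: np.ndarray
    frame_rate: float


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density: ascending frequencies, power >= 0."""

    frequencies_hz: np.ndarray
    power: np.ndarray


_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file as a mono :class:`AudioSignal`.

    Integer PCM is rescaled to [-1, 1); multi-channel audio is downmixed
    by averaging the channels. Raises :class:`WavIOError` for missing
    files or encodings the RIFF reader does not support.
    """
    path = Path(path)
    if not path.exists():
        raise WavIOError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise WavIOError(f"unsupported WAV encoding in {path}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(
    signal: AudioSignal, path: str | Path, subtype: str = "pcm16"
) -> Path:
    """Write ``signal`` to ``path`` as WAV.

    ``subtype`` is ``"pcm16"`` (default) or ``"float32"``. Integer
    output requires samples within [-1, 1]; out-of-range input raises
    with a hint to normalize first.
    """
    if len(signal.samples) == 0:
        raise ValueError("cannot write an empty signal")
    path = Path(path)
    if subtype == "pcm16":
        peak = np.max(np.abs(signal.samples))
        if peak > 1.0 + 1e-12:
            raise ValueError(
                f"samples exceed [-1, 1] (peak {peak:.4f}); "
                "apply normalize() before writing integer PCM"
            )
        scaled = np.clip(np.round(signal.samples * 2**15), -(2**15), 2**15 - 1)
        wavfile.write(str(path), signal.sample_rate, scaled.astype(np.int16))
    elif subtype == "float32":
        wavfile.write(
            str(path), signal.sample_rate, signal.samples.astype(np.float32)
        )
    else:
        raise ValueError(f"unsupported subtype: {subtype!r}")
    return path


def normalize(signal: AudioSignal, peak: float = 0.99) -> AudioSignal:
    """Peak-normalize so that max |sample| equals ``peak``.

    Pure positive rescaling: the waveform shape is untouched. All-zero
    input has no defined scale and raises.
    """
    if peak <= 0:
        raise ValueError("target peak must be positive")
    current = np.max(np.abs(signal.samples)) if len(signal.samples) else 0.0
    if current == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return AudioSignal(
        samples=signal.samples * (peak / current), sample_rate=signal.sample_rate
    )


def envelope(signal: AudioSignal, smoothing_hz: float = 50.0) -> EnvelopeSeries:
    """Amplitude envelope: analytic-signal modulus, low-passed.

    The magnitude of the Hilbert analytic signal is smoothed with a
    zero-phase Butterworth low-pass at ``smoothing_hz`` (default 50 Hz,
    i.e. structure slower than ~20 ms is kept). Values are clipped at
    zero, since filtering can produce small negative excursions.
    """
    nyquist = signal.sample_rate / 2
    if not 0 < smoothing_hz < nyquist:
        raise ValueError(f"smoothing_hz must be in (0, {nyquist})")
    if len(signal.samples) == 0:
        raise ValueError("empty signal")
    magnitude = np.abs(hilbert(signal.samples))
    # filtfilt needs some padding room; fall back to the raw modulus for
    # very short inputs
    sos = butter(4, smoothing_hz, btype="low", fs=signal.sample_rate, output="sos")
    if len(magnitude) > 50:
        smoothed = sosfiltfilt(sos, magnitude)
    else:
        smoothed = magnitude
    return EnvelopeSeries(
        values=np.maximum(smoothed, 0.0), frame_rate=float(signal.sample_rate)
    )


def power_spectral_density(
    signal: AudioSignal, segment_length: int = 1024
) -> PowerSpectrum:
    """Welch-averaged one-sided PSD with Hann segments.

    Integrates (approximately) to the signal variance for zero-mean
    stationary input.
    """
    if segment_length > len(signal.samples):
        raise ValueError(
            f"segment_length {segment_length} exceeds signal length "
            f"{len(signal.samples)}"
        )
    freqs, power = welch(
        signal.samples,
        fs=signal.sample_rate,
        window="hann",
        nperseg=segment_length,
        detrend=False,
    )
    return PowerSpectrum(frequencies_hz=freqs, power=power)


def total_energy(signal: AudioSignal) -> float:
    """Sum of squared samples."""
    return float(np.sum(signal.samples**2))
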