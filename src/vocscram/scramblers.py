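"""The four scrambling transforms for vocal affect bursts.

Three families, each a deterministic function of the input signal and a
seeded parameter set:

* **frequency scrambling** — short-time real FFT in 1024-sample windows
  at 512-sample hops; within each window the positive-frequency
  coefficients are randomly permuted across bins (fresh permutation per
  window), the window is rescaled to its original RMS, and windows are
  recombined by Hann overlap-add. Flattens where energy sits in
  frequency while keeping the broadband amplitude envelope.
* **phase scrambling** — one whole-signal real FFT; coefficients at or
  below a pitch threshold (by default the stimulus's median F0) are left
  untouched, while above the threshold the phases are permuted among
  bins with magnitudes kept. Preserves the magnitude spectrum, hence the
  total energy, but destroys fine temporal structure above the pitch.
* **time scrambling** — the normalized waveform is cut into consecutive
  6-ms or 12-ms windows, the window order is permuted, and each window
  receives a 1-ms onset/offset amplitude ramp to suppress crackling at
  the joins. Duration is conserved exactly; the ramps remove a little
  energy. The 6-ms grain sits just above the ~4-ms temporal resolution
  of human hearing, so even the finer variant destroys temporal order at
  every perceptually resolvable scale.

All methods normalize the input first and the output last (peak 0.99).
DC and Nyquist bins are never permuted: they must stay real for a real
output signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from vocscram.audio import AudioSignal, normalize
from vocscram.pitch import median_pitch

Method = Literal["frequency", "phase", "time"]

#: target peak after normalization, matching audio.normalize's default
_PEAK = 0.99


@dataclass(frozen=True)
class ScrambleParams:
    """Seeded configuration for one scrambling run.

    ``fft_window``/``fft_hop`` apply to the frequency method,
    ``pitch_threshold_hz`` to the phase method (None means "estimate the
    median F0 of the input"), ``time_window_ms``/``ramp_ms`` to the time
    method. ``seed`` fixes every random choice, making the output fully
    reproducible.
    """

    method: Method
    fft_window: int = 1024
    fft_hop: int = 512
    pitch_threshold_hz: float | None = None
    time_window_ms: float = 6.0
    ramp_ms: float = 1.0
    ramp_shape: Literal["linear", "cosine"] = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("frequency", "phase", "time"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.fft_hop > self.fft_window:
            raise ValueError("fft_hop must not exceed fft_window")
        if self.time_window_ms <= 2 * self.ramp_ms:
            raise ValueError("time window must be longer than twice the ramp")


@dataclass
class Provenance:
    """What produced an output file; written as a JSON sidecar."""

    method: str
    params: dict
    seed: int
    pitch_threshold_hz: float | None = None
    extra: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "Provenance":
        return cls(**json.loads(Path(path).read_text()))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def frequency_scramble(
    signal: AudioSignal,
    params: ScrambleParams,
    permutation: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    normalize_output: bool = True,
) -> AudioSignal:
    """Shuffle FFT-bin positions within each short-time analysis window.

    The normalized input is trimmed to a whole number of hop steps so
    every window is full-size. Per Hann-tapered window the positive-
    frequency coefficients (excluding DC and Nyquist) are permuted to
    random bin positions, the window is rescaled so its RMS matches the
    original window's, and the windows are recombined by overlap-add;
    the Hann taper at hop = window/2 satisfies constant overlap-add, so
    an identity permutation reconstructs the input exactly.

    The signal is zero-padded by one hop at each end before analysis so
    that every retained sample sits in the constant-overlap region; the
    overlap-add result is rescaled to the trimmed input's total energy
    (a single global scalar), since shuffling bin positions conserves
    each window's energy but tapered overlap-add of incoherent windows
    does not sum it back coherently.

    ``permutation`` is a test hook: a callable ``(rng, n) -> index
    array`` replacing the random permutation of the ``n`` shuffleable
    bins. ``normalize_output=False`` returns the energy-matched
    overlap-add result without the final peak normalization (used by
    energy diagnostics).
    """
    win, hop = params.fft_window, params.fft_hop
    if win % (2 * hop) != 0:
        raise ValueError("fft_window must be an even multiple of fft_hop (COLA)")
    if len(signal) < win:
        raise ValueError(
            f"signal of {len(signal)} samples is shorter than one "
            f"{win}-sample analysis window"
        )
    x = normalize(signal).samples
    n_windows = 1 + (len(x) - win) // hop
    n_trim = win + (n_windows - 1) * hop
    x = x[:n_trim]
    padded = np.concatenate([np.zeros(hop), x, np.zeros(hop)])

    rng = _rng(params.seed)
    taper = np.hanning(win + 1)[:win]  # periodic Hann: COLA-1 at hop = win/2
    out = np.zeros(len(padded))
    n_bins = win // 2 + 1
    shuffleable = np.arange(1, n_bins - 1)  # keep DC and Nyquist in place

    for start in range(0, len(padded) - win + 1, hop):
        chunk = padded[start : start + win] * taper
        spec = np.fft.rfft(chunk)
        if permutation is None:
            perm = rng.permutation(len(shuffleable))
        else:
            perm = np.asarray(permutation(rng, len(shuffleable)))
        scrambled = spec.copy()
        scrambled[shuffleable] = spec[shuffleable][perm]
        rebuilt = np.fft.irfft(scrambled, n=win)
        # keep the window's amplitude (RMS) as in the original window
        rms_in = np.sqrt(np.mean(chunk**2))
        rms_out = np.sqrt(np.mean(rebuilt**2))
        if rms_out > 0:
            rebuilt *= rms_in / rms_out
        out[start : start + win] += rebuilt

    out = out[hop : hop + n_trim]
    energy_in = float(np.sum(x**2))
    energy_out = float(np.sum(out**2))
    if energy_out > 0:
        out *= np.sqrt(energy_in / energy_out)
    result = AudioSignal(samples=out, sample_rate=signal.sample_rate)
    return normalize(result) if normalize_output else result


def phase_scramble(
    signal: AudioSignal,
    params: ScrambleParams,
    normalize_output: bool = True,
) -> tuple[AudioSignal, float]:
    """Permute spectral phases above a pitch threshold.

    One real FFT of the whole normalized signal; bins with center
    frequency at or below the threshold (``params.pitch_threshold_hz``,
    or the stimulus's median F0 when unset) keep their complex values.
    Above the threshold the phase angles — the two-argument arctangent
    of each coefficient — are randomly permuted among bins while the
    magnitudes stay in place, so the magnitude spectrum (and with it the
    total energy) is preserved exactly. Returns the scrambled signal and
    the threshold that was used.
    """
    if len(signal) == 0:
        raise ValueError("empty signal")
    threshold = params.pitch_threshold_hz
    if threshold is None:
        threshold = median_pitch(signal)
    nyquist = signal.sample_rate / 2
    if threshold >= nyquist:
        raise ValueError(
            f"pitch threshold {threshold} Hz is at or above Nyquist ({nyquist} Hz)"
        )

    x = normalize(signal).samples
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / signal.sample_rate)

    high = freqs > threshold
    high[0] = False
    if n % 2 == 0:
        high[-1] = False  # Nyquist bin must stay real

    rng = _rng(params.seed)
    idx = np.flatnonzero(high)
    magnitudes = np.abs(spec[idx])
    phases = np.angle(spec[idx])
    spec[idx] = magnitudes * np.exp(1j * phases[rng.permutation(len(idx))])

    out = np.fft.irfft(spec, n=n)
    result = AudioSignal(samples=out, sample_rate=signal.sample_rate)
    if normalize_output:
        result = normalize(result)
    return result, float(threshold)


def _ramp(n_ramp: int, shape: str) -> np.ndarray:
    if shape == "cosine":
        return 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp, endpoint=False)))
    return np.linspace(0, 1, n_ramp, endpoint=False)


def time_scramble(
    signal: AudioSignal,
    params: ScrambleParams,
    permutation: Sequence[int] | None = None,
    normalize_output: bool = True,
) -> AudioSignal:
    """Cut the waveform into short windows, shuffle them, ramp the joins.

    The normalized input is partitioned into consecutive windows of
    ``time_window_ms`` (a trailing remainder is kept as a final shorter
    window), the window order is permuted, and each window receives
    onset and offset amplitude ramps of ``ramp_ms`` before the windows
    are concatenated. The sample count is conserved exactly; the ramps
    strictly reduce energy wherever the windows carry signal.

    ``permutation`` is a test hook: an explicit ordering of the windows
    replacing the seeded shuffle.
    """
    sr = signal.sample_rate
    win = int(round(params.time_window_ms / 1000 * sr))
    n_ramp = int(round(params.ramp_ms / 1000 * sr))
    if win <= 2 * n_ramp:
        raise ValueError("time window must be longer than twice the ramp")
    if len(signal) < 2 * win:
        raise ValueError("signal must span at least two time windows")

    x = normalize(signal).samples
    bounds = list(range(0, len(x), win))
    windows = [x[b : b + win] for b in bounds]
    if permutation is None:
        order = _rng(params.seed).permutation(len(windows))
    else:
        order = np.asarray(permutation)
        if sorted(order.tolist()) != list(range(len(windows))):
            raise ValueError("permutation must reorder all windows exactly once")

    pieces = []
    for i in order:
        w = windows[i].copy()
        r = min(n_ramp, len(w) // 2)
        if r > 0:
            ramp = _ramp(r, params.ramp_shape)
            w[:r] *= ramp
            w[-r:] *= ramp[::-1]
        pieces.append(w)
    out = np.concatenate(pieces)
    result = AudioSignal(samples=out, sample_rate=sr)
    return normalize(result) if normalize_output else result


def scramble(
    signal: AudioSignal, params: ScrambleParams
) -> tuple[AudioSignal, Provenance]:
    """Dispatch to the requested scrambling method.

    Returns the scrambled signal together with a :class:`Provenance`
    record of the method, parameters, seed, and (for phase scrambling)
    the pitch threshold actually used.
    """
    prov = Provenance(
        method=params.method,
        params=asdict(params),
        seed=params.seed,
    )
    if params.method == "frequency":
        out = frequency_scramble(signal, params)
    elif params.method == "phase":
        out, threshold = phase_scramble(signal, params)
        prov.pitch_threshold_hz = threshold
    elif params.method == "time":
        out = time_scramble(signal, params)
        prov.extra["time_window_ms"] = params.time_window_ms
    else:  # pragma: no cover - guarded by ScrambleParams
        raise ValueError(f"unknown method: {params.method!r}")
    return out, prov
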