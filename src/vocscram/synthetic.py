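"""Synthetic affect-burst stimuli and rating datasets.

Real affect bursts (brief nonspeech emotional vocalizations) are not
redistributable, so this module generates stand-ins with just enough
structure to exercise every other module: harmonic vocal-like bursts
whose envelope and pitch contour follow one of three valence archetypes,
and rating tables with the branching trial structure of the validation
study and configurable mean shifts per manipulation x valence cell.

Archetypes (minimal caricatures, no claim of perceptual validity):

* ``neutral`` — a sustained tone: flat F0, smooth attack/release.
* ``happiness`` — a piecewise melody: 4-6 voiced segments separated by
  >= 30 ms pauses, with F0 rising across segments.
* ``anger`` — a rough burst: F0 jitter, added broadband noise, sharp
  attack and slow decay.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from vocscram.audio import AudioSignal
from vocscram.ratings import COLUMNS, MANIPULATIONS, VALENCES

#: speaker identifiers following the sex-letter + number convention
DEFAULT_FEMALE_IDS = ("f45", "f46", "f53", "f58", "f60")
DEFAULT_MALE_IDS = ("m6", "m42", "m55", "m59", "m61")


@dataclass(frozen=True)
class SyntheticSpec:
    """Settings for one synthetic stimulus set."""

    n_speakers: int = 10
    duration_range_s: tuple[float, float] = (0.24, 2.61)
    f0_female_hz: tuple[float, float] = (170.0, 280.0)
    f0_male_hz: tuple[float, float] = (95.0, 160.0)
    sample_rate: int = 44100
    seed: int = 0


@dataclass(frozen=True)
class Stimulus:
    """One generated original burst with its metadata."""

    stimulus_id: str
    speaker_sex: str
    valence_category: str
    duration_s: float
    f0_hz: float
    signal: AudioSignal


def _harmonic(phase: np.ndarray, n_harmonics: int) -> np.ndarray:
    out = np.zeros_like(phase)
    for k in range(1, n_harmonics + 1):
        out += np.sin(k * phase) / k
    return out


def _attack_release(n: int, sr: int, attack_s: float, release_s: float) -> np.ndarray:
    env = np.ones(n)
    na = min(int(attack_s * sr), n // 2)
    nr = min(int(release_s * sr), n // 2)
    if na > 0:
        env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    if nr > 0:
        env[n - nr :] = 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
    return env


def make_burst(
    speaker_sex: str,
    valence: str,
    duration: float,
    f0: float,
    sample_rate: int = 44100,
    seed: int = 0,
) -> AudioSignal:
    """Generate one synthetic affect burst.

    A harmonic complex (up to 8 harmonics, 1/k amplitude rolloff) on an
    F0 contour and amplitude envelope chosen by the valence archetype.
    Fixed (arguments, seed) give a bit-identical waveform.
    """
    if valence not in VALENCES:
        raise ValueError(f"unknown valence: {valence!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    sr = sample_rate
    n = int(round(duration * sr))
    n_harm = max(1, min(8, int(0.45 * sr / (f0 * 1.2))))

    if valence == "neutral":
        f0_inst = np.full(n, f0)
        env = _attack_release(n, sr, 0.05, 0.08)
        noise_level = 0.0
    elif valence == "anger":
        # slow multiplicative jitter around f0, ~1.5% RMS
        n_ctrl = max(4, int(duration * 40))
        ctrl = 1.0 + np.clip(rng.normal(0, 0.015, n_ctrl), -0.04, 0.04)
        f0_inst = f0 * np.interp(
            np.arange(n), np.linspace(0, n - 1, n_ctrl), ctrl
        )
        env = _attack_release(n, sr, 0.005, 0.05)
        env *= np.exp(-np.arange(n) / (0.8 * n))  # slow decay after the attack
        noise_level = 0.12
    else:  # happiness: segmented melody with brief pauses, rising F0
        seg_min, pause_min, pause_max = 0.04, 0.03, 0.07
        n_seg = int(rng.integers(4, 7))
        while n_seg > 2 and n_seg * seg_min + (n_seg - 1) * pause_min > duration:
            n_seg -= 1
        n_pause = n_seg - 1
        pauses = rng.uniform(pause_min, pause_max, n_pause)
        budget = duration - pauses.sum()
        if budget < n_seg * seg_min:
            pauses *= max(0.0, duration - n_seg * seg_min) / max(pauses.sum(), 1e-9)
            budget = duration - pauses.sum()
        weights = rng.uniform(0.7, 1.3, n_seg)
        seg_lens = budget * weights / weights.sum()
        f0_inst = np.zeros(n)
        env = np.zeros(n)
        pos = 0.0
        for k in range(n_seg):
            a = int(round(pos * sr))
            b = min(n, int(round((pos + seg_lens[k]) * sr)))
            rise = 1.0 + 0.15 * (k / max(n_seg - 1, 1))
            f0_inst[a:b] = f0 * rise
            seg_n = b - a
            if seg_n > 0:
                env[a:b] = _attack_release(seg_n, sr, 0.01, 0.015)
            pos += seg_lens[k] + (pauses[k] if k < n_pause else 0.0)
        f0_inst[f0_inst == 0] = f0  # keep the phase integral well-defined
        noise_level = 0.0

    phase = 2 * np.pi * np.cumsum(f0_inst) / sr
    phase += rng.uniform(0, 2 * np.pi)
    x = _harmonic(phase, n_harm) * env
    if noise_level > 0:
        x += noise_level * np.max(np.abs(x)) * rng.standard_normal(n) * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioSignal(samples=x, sample_rate=sr)


def make_stimulus_set(spec: SyntheticSpec) -> list[Stimulus]:
    """Generate the original bursts: n_speakers x 3 valences.

    Half of the speakers are "female" (high F0 range), half "male" (low
    F0 range); each speaker contributes one burst per valence with a
    duration drawn from ``duration_range_s``.
    """
    rng = np.random.default_rng(spec.seed)
    n_f = spec.n_speakers // 2 + spec.n_speakers % 2
    ids: list[tuple[str, str]] = []
    for i in range(n_f):
        sid = DEFAULT_FEMALE_IDS[i] if i < len(DEFAULT_FEMALE_IDS) else f"f{70 + i}"
        ids.append((sid, "female"))
    for i in range(spec.n_speakers - n_f):
        sid = DEFAULT_MALE_IDS[i] if i < len(DEFAULT_MALE_IDS) else f"m{70 + i}"
        ids.append((sid, "male"))

    stimuli = []
    for sid, sex in ids:
        lo, hi = spec.f0_female_hz if sex == "female" else spec.f0_male_hz
        f0 = float(rng.uniform(lo, hi))
        for valence in VALENCES:
            duration = float(rng.uniform(*spec.duration_range_s))
            burst_seed = int(rng.integers(2**31))
            stimuli.append(
                Stimulus(
                    stimulus_id=sid,
                    speaker_sex=sex,
                    valence_category=valence,
                    duration_s=duration,
                    f0_hz=f0,
                    signal=make_burst(
                        sex, valence, duration, f0, spec.sample_rate, burst_seed
                    ),
                )
            )
    return stimuli


def stimulus_metadata(stimuli: list[Stimulus]) -> pd.DataFrame:
    """Metadata table (no waveforms) for a stimulus set."""
    return pd.DataFrame(
        [
            {
                "stimulus_id": s.stimulus_id,
                "speaker_sex": s.speaker_sex,
                "valence_category": s.valence_category,
                "duration_s": s.duration_s,
                "f0_hz": s.f0_hz,
            }
            for s in stimuli
        ]
    )


Cell = tuple[str, str]  # (manipulation, valence_category)


@dataclass
class RatingEffectSpec:
    """Ground-truth structure of a synthetic rating dataset.

    ``cell_means`` are the latent valence means (0-100) per
    (manipulation, valence) cell; ``apparency_probs`` give the
    probability of each voice-apparency response 1-4 per cell;
    ``gender_probs`` give (correct, wrong, unsure) probabilities for the
    gender choice when a voice is detected. ``rating_sd`` is the
    trial-level noise SD on the slider; ``participant_sd`` adds an
    optional per-participant intercept.
    """

    n_participants: int = 60
    cell_means: Mapping[Cell, float] = field(default_factory=dict)
    apparency_probs: Mapping[Cell, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    gender_probs: Mapping[Cell, tuple[float, float, float]] = field(
        default_factory=dict
    )
    rating_sd: float = 18.0
    participant_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, p in self.apparency_probs.items():
            if not np.isclose(sum(p), 1.0):
                raise ValueError(f"apparency probabilities of {cell} must sum to 1")
        for cell, p in self.gender_probs.items():
            if not np.isclose(sum(p), 1.0):
                raise ValueError(f"gender probabilities of {cell} must sum to 1")
        for cell, m in self.cell_means.items():
            if not 0 <= m <= 100:
                raise ValueError(f"cell mean of {cell} outside [0, 100]")


def default_effect_spec(
    n_participants: int = 60, seed: int = 0, **overrides
) -> RatingEffectSpec:
    """Effect structure emulating the validation study's pattern.

    Originals separate clearly by valence and are nearly always heard as
    voices. Among the scrambled cells, only phase-scrambled neutral
    bursts stay at the original-neutral mean; every other scrambled cell
    is shifted toward the unpleasant end. Frequency scrambling has the
    lowest voice-apparency, phase-scrambled neutral the highest among
    scrambled versions, and 12-ms time scrambling a higher one than
    6-ms. Gender accuracy is high for originals and degraded but
    above-chance for scrambled versions.
    """
    ref = 55.0
    cell_means: dict[Cell, float] = {
        ("original", "neutral"): ref,
        ("original", "anger"): 15.0,
        ("original", "happiness"): 85.0,
        ("phase_scr", "neutral"): ref + 1.0,
        ("phase_scr", "anger"): ref - 8.0,
        ("phase_scr", "happiness"): ref - 15.5,
        ("freq_scr", "neutral"): ref - 17.5,
        ("freq_scr", "anger"): ref - 15.5,
        ("freq_scr", "happiness"): ref - 6.5,
        ("time12_scr", "neutral"): ref - 14.5,
        ("time12_scr", "anger"): ref - 16.0,
        ("time12_scr", "happiness"): ref - 7.0,
        ("time6_scr", "neutral"): ref - 19.0,
        ("time6_scr", "anger"): ref - 16.0,
        ("time6_scr", "happiness"): ref - 8.5,
    }
    apparency: dict[Cell, tuple[float, float, float, float]] = {}
    gender: dict[Cell, tuple[float, float, float]] = {}
    for valence in VALENCES:
        apparency[("original", valence)] = (0.01, 0.03, 0.16, 0.80)
        gender[("original", valence)] = (0.90, 0.04, 0.06)
        for manip in ("freq_scr", "phase_scr", "time12_scr", "time6_scr"):
            gender[(manip, valence)] = (0.55, 0.20, 0.25)
    for valence in VALENCES:
        apparency[("freq_scr", valence)] = (0.50, 0.30, 0.15, 0.05)
        apparency[("time12_scr", valence)] = (0.25, 0.30, 0.28, 0.17)
        apparency[("time6_scr", valence)] = (0.35, 0.32, 0.22, 0.11)
    apparency[("phase_scr", "neutral")] = (0.12, 0.22, 0.34, 0.32)
    apparency[("phase_scr", "anger")] = (0.25, 0.30, 0.28, 0.17)
    apparency[("phase_scr", "happiness")] = (0.35, 0.32, 0.22, 0.11)

    kwargs = dict(
        n_participants=n_participants,
        cell_means=cell_means,
        apparency_probs=apparency,
        gender_probs=gender,
        seed=seed,
    )
    kwargs.update(overrides)
    return RatingEffectSpec(**kwargs)


def make_ratings(
    stimuli_meta: pd.DataFrame, effects: RatingEffectSpec
) -> pd.DataFrame:
    """Simulate the full rating dataset.

    One trial per participant x stimulus x manipulation. Voice apparency
    is drawn from the cell's distribution; the branch fields (rating
    type, gender response) follow the trial's branching logic; the
    valence rating is the cell mean plus Gaussian noise, clipped to
    [0, 100] and rounded to integers.
    """
    required = {"stimulus_id", "valence_category"}
    if not required <= set(stimuli_meta.columns):
        raise ValueError(f"stimuli metadata needs columns {sorted(required)}")
    if "speaker_sex" in stimuli_meta.columns:
        sex_of = dict(
            zip(stimuli_meta["stimulus_id"], stimuli_meta["speaker_sex"])
        )
    else:
        sex_of = {
            sid: ("female" if str(sid).startswith("f") else "male")
            for sid in stimuli_meta["stimulus_id"]
        }

    design = stimuli_meta[["stimulus_id", "valence_category"]].drop_duplicates()
    cells = [
        (m, v) for m in MANIPULATIONS for v in design["valence_category"].unique()
    ]
    uncovered = [
        c
        for c in cells
        if c not in effects.cell_means
        or c not in effects.apparency_probs
        or c not in effects.gender_probs
    ]
    if uncovered:
        raise ValueError(f"effect spec does not cover cells: {uncovered}")

    rng = np.random.default_rng(effects.seed)
    participants = [f"p{str(i + 1).zfill(2)}" for i in range(effects.n_participants)]
    intercepts = dict(
        zip(
            participants,
            rng.normal(0, effects.participant_sd, effects.n_participants),
        )
    )

    rows = []
    for _, stim in design.iterrows():
        sid, valence = stim["stimulus_id"], stim["valence_category"]
        true_sex = sex_of[sid]
        wrong_sex = "male" if true_sex == "female" else "female"
        for manip in MANIPULATIONS:
            cell = (manip, valence)
            app_p = effects.apparency_probs[cell]
            gen_p = effects.gender_probs[cell]
            mean = effects.cell_means[cell]
            apparency = rng.choice([1, 2, 3, 4], size=len(participants), p=app_p)
            noise = rng.normal(0, effects.rating_sd, len(participants))
            outcome = rng.choice(
                ["correct", "wrong", "unsure"], size=len(participants), p=gen_p
            )
            listens = 1 + rng.poisson(0.2, len(participants))
            for j, pid in enumerate(participants):
                detected = apparency[j] >= 3
                if detected:
                    gender = {
                        "correct": true_sex,
                        "wrong": wrong_sex,
                        "unsure": "not_identifiable",
                    }[outcome[j]]
                else:
                    gender = "absent"
                rating = int(
                    np.clip(round(mean + intercepts[pid] + noise[j]), 0, 100)
                )
                rows.append(
                    (
                        pid,
                        sid,
                        valence,
                        manip,
                        int(apparency[j]),
                        gender,
                        rating,
                        "expression" if detected else "reaction",
                        int(listens[j]),
                    )
                )
    return pd.DataFrame(rows, columns=COLUMNS)
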