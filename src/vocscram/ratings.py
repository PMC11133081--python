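"""Rating-study data model and summaries.

Each trial follows a branching procedure: the listener first judges on a
4-point scale how apparent a human voice is in the sound. A rating of 1
or 2 (no voice) branches to a *reaction* rating — the valence of the
listener's own response — with no gender question; a rating of 3 or 4
(voice detected) branches to a gender choice plus an *expression*
rating of the speaker's affect. Both valence sliders record integers
0-100 (0 = extremely negative).

This module validates trial tables against that branching logic,
applies the participant exclusion rule (participants whose ratings do
not differentiate the unmanipulated stimuli), and produces the
descriptive summaries: per-cell valence means with standard errors,
gender-accuracy tallies, and per-participant condition means feeding
the equivalence analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

VALENCES = ("neutral", "anger", "happiness")
MANIPULATIONS = ("original", "freq_scr", "phase_scr", "time12_scr", "time6_scr")
GENDER_RESPONSES = ("not_identifiable", "female", "male", "absent")
RATING_TYPES = ("expression", "reaction")

COLUMNS = [
    "participant_id",
    "stimulus_id",
    "valence_category",
    "manipulation",
    "apparency",
    "gender_response",
    "valence_rating",
    "rating_type",
    "n_listens",
]


@dataclass(frozen=True)
class TrialRecord:
    """One participant x stimulus rating trial."""

    participant_id: str
    stimulus_id: str
    valence_category: str
    manipulation: str
    apparency: int
    gender_response: str
    valence_rating: int
    rating_type: str
    n_listens: int = 1

    def __post_init__(self) -> None:
        problems = _violations(
            self.valence_category,
            self.manipulation,
            self.apparency,
            self.gender_response,
            self.valence_rating,
            self.rating_type,
            self.n_listens,
        )
        if problems:
            raise ValueError(f"invalid trial: {', '.join(problems)}")


def _violations(
    valence_category, manipulation, apparency, gender_response,
    valence_rating, rating_type, n_listens,
) -> list[str]:
    codes = []
    if valence_category not in VALENCES:
        codes.append("bad_valence_category")
    if manipulation not in MANIPULATIONS:
        codes.append("bad_manipulation")
    if apparency not in (1, 2, 3, 4):
        codes.append("bad_apparency")
    if gender_response not in GENDER_RESPONSES:
        codes.append("bad_gender_response")
    if not 0 <= valence_rating <= 100:
        codes.append("rating_out_of_range")
    if rating_type not in RATING_TYPES:
        codes.append("bad_rating_type")
    if n_listens < 1:
        codes.append("bad_n_listens")
    if apparency in (1, 2):
        if rating_type != "reaction":
            codes.append("branching_violation_rating_type")
        if gender_response != "absent":
            codes.append("branching_violation_gender")
    elif apparency in (3, 4):
        if rating_type != "expression":
            codes.append("branching_violation_rating_type")
        if gender_response == "absent":
            codes.append("branching_violation_gender")
    return codes


def load_trials(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate a trials CSV.

    Returns ``(trials, rejects)``: rows passing all branching and range
    checks, and a reject report with the original line number and the
    violation codes of every invalid row. A missing column is fatal.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials CSV missing required columns: {missing}")
    df = df[COLUMNS].copy()
    for col in ("apparency", "valence_rating", "n_listens"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    codes = []
    for row in df.itertuples(index=False):
        if any(
            pd.isna(v)
            for v in (row.apparency, row.valence_rating, row.n_listens)
        ):
            codes.append(["unparseable_numeric"])
            continue
        codes.append(
            _violations(
                row.valence_category,
                row.manipulation,
                int(row.apparency),
                row.gender_response,
                int(row.valence_rating),
                row.rating_type,
                int(row.n_listens),
            )
        )
    bad = np.array([len(c) > 0 for c in codes])
    rejects = df[bad].copy()
    rejects["line"] = np.flatnonzero(bad) + 2  # header is line 1
    rejects["violations"] = [";".join(c) for c, b in zip(codes, bad) if b]
    trials = df[~bad].copy()
    for col in ("apparency", "valence_rating", "n_listens"):
        trials[col] = trials[col].astype(int)
    return trials.reset_index(drop=True), rejects.reset_index(drop=True)


def exclude_nondifferentiating_participants(
    trials: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants who do not differentiate the original stimuli.

    For each participant, the mean valence rating of the *original*
    stimuli is computed per valence category; a participant whose range
    of category means (max - min) falls below ``threshold`` rating
    points gave effectively the same answer to angry, neutral, and happy
    originals and is excluded. Participants with no original-stimulus
    trials cannot be assessed; they are kept and a warning names them.
    """
    originals = trials[trials["manipulation"] == "original"]
    means = (
        originals.groupby(["participant_id", "valence_category"])["valence_rating"]
        .mean()
        .unstack()
    )
    spread = means.max(axis=1) - means.min(axis=1)
    excluded = sorted(spread[spread < threshold].index.tolist())
    unassessable = sorted(
        set(trials["participant_id"]) - set(means.index)
    )
    if unassessable:
        warnings.warn(
            "participants without original-stimulus trials kept but not "
            f"assessed: {unassessable}",
            stacklevel=2,
        )
    kept = trials[~trials["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def valence_summary(
    trials: pd.DataFrame, split_by_rating_type: bool = True
) -> pd.DataFrame:
    """Mean, SE, and n of valence ratings per design cell.

    Cells are (stimulus, valence, manipulation) x rating type when
    ``split_by_rating_type`` (matching the expression/reaction panel
    split of the descriptive figures); combinations with no ratings are
    emitted with n = 0, and SE is NaN when n < 2.
    """
    keys = ["stimulus_id", "valence_category", "manipulation"]
    if split_by_rating_type:
        keys = keys + ["rating_type"]
    grouped = trials.groupby(keys)["valence_rating"].agg(
        mean_rating="mean", se_rating=lambda v: v.sem(ddof=1), n="count"
    )
    # emit empty cells: every observed stimulus cell x both rating types
    observed = trials[
        ["stimulus_id", "valence_category", "manipulation"]
    ].drop_duplicates()
    if split_by_rating_type:
        full = observed.merge(
            pd.DataFrame({"rating_type": list(RATING_TYPES)}), how="cross"
        )
        full_index = pd.MultiIndex.from_frame(full[keys])
        grouped = grouped.reindex(full_index)
    out = grouped.reset_index()
    out["n"] = out["n"].fillna(0).astype(int)
    return out.sort_values(keys).reset_index(drop=True)


def collapse_ratings(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool expression and reaction ratings onto one valence scale.

    Both branches use the same 0-100 slider, so collapsing keeps every
    value unchanged and simply treats them as one variable; the original
    ``rating_type`` column is retained as an annotation. Downstream
    means over a collapsed cell therefore equal the rating-count-
    weighted mean of the two per-type means.
    """
    out = trials.copy()
    out.attrs["collapsed"] = True
    return out


def gender_accuracy(
    trials: pd.DataFrame, speaker_sex_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tally gender-decision accuracy for voice-detected trials.

    Only trials with apparency 3 or 4 carry a gender response. Per
    (stimulus, valence, manipulation) cell the tally reports ``total``
    voice-detected trials and how many responses were ``correct``
    (matching the speaker's sex), ``wrong``, or ``unsure`` (the
    not-identifiable option). ``speaker_sex_map`` maps stimulus IDs to
    "female"/"male"; when omitted, the ID's leading letter convention
    (f45 -> female, m42 -> male) is used.
    """
    if speaker_sex_map is None:
        speaker_sex_map = {}
        for sid in trials["stimulus_id"].unique():
            prefix = str(sid)[:1].lower()
            if prefix == "f":
                speaker_sex_map[sid] = "female"
            elif prefix == "m":
                speaker_sex_map[sid] = "male"
    unknown = set(trials["stimulus_id"]) - set(speaker_sex_map)
    if unknown:
        raise ValueError(f"stimuli missing from speaker_sex_map: {sorted(unknown)}")

    detected = trials[trials["apparency"] >= 3].copy()
    detected["true_sex"] = detected["stimulus_id"].map(speaker_sex_map)
    detected["outcome"] = np.select(
        [
            detected["gender_response"] == "not_identifiable",
            detected["gender_response"] == detected["true_sex"],
        ],
        ["unsure", "correct"],
        default="wrong",
    )
    keys = ["stimulus_id", "valence_category", "manipulation"]
    counts = (
        detected.groupby(keys)["outcome"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["correct", "wrong", "unsure"], fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    # cells where no voice was ever detected still get a zero row
    observed = trials[keys].drop_duplicates()
    counts = (
        counts.reindex(pd.MultiIndex.from_frame(observed[keys]))
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    cols = keys + ["total", "correct", "wrong", "unsure"]
    return counts[cols].sort_values(keys).reset_index(drop=True)


def participant_condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean rating per (manipulation, valence) cell.

    Collapses over the stimulus identities within a cell, producing the
    pairing unit for the equivalence tests.
    """
    means = (
        trials.groupby(["participant_id", "manipulation", "valence_category"])[
            "valence_rating"
        ]
        .mean()
        .reset_index()
    )
    return means


def midpoint_fraction(trials: pd.DataFrame, midpoint: int = 50) -> pd.DataFrame:
    """Diagnostic: share of exactly-midpoint slider responses per cell.

    Sliders with a centered default thumb inflate the midpoint, because
    undecided listeners tend to leave it in place; a high fraction flags
    cells whose mean is dragged toward the scale center.
    """
    keys = ["manipulation", "valence_category"]
    frac = (
        trials.assign(at_mid=trials["valence_rating"] == midpoint)
        .groupby(keys)["at_mid"]
        .mean()
        .rename("midpoint_fraction")
        .reset_index()
    )
    return frac
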