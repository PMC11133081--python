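"""Paired equivalence testing for valence ratings.

Classical paired tests ask whether two conditions *differ*; failing to
reject that null does not establish sameness. Equivalence testing flips
the burden: the null is that the mean paired difference lies *outside*
the interval (-delta, +delta), and two one-sided tests (TOST) must both
reject — H0(1): mu1 - mu2 >= delta and H0(2): mu1 - mu2 <= -delta — to
conclude that the difference is practically negligible.

Because slider-based valence ratings are far from normal, the one-sided
tests are rank-based: Wilcoxon signed-rank tests on the differences
shifted by -delta (lower-tail alternative) and +delta (upper-tail
alternative). A parametric paired-t TOST is provided as a cross-check.
The half-width delta is taken, by default, from the data itself: the
standard deviation of the reference-condition ratings. Uncertainty
around each difference is summarized with a percentile bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EquivalenceResult:
    """Outcome of one paired equivalence comparison."""

    comparison: str
    delta: float
    point_difference: float
    ci_low: float
    ci_high: float
    p_upper: float  # H0(1): mean difference >= +delta
    p_lower: float  # H0(2): mean difference <= -delta
    equivalent: bool
    n: int
    note: str = ""


def delta_from_reference(ratings) -> float:
    """Equivalence half-width: sample SD (n-1) of reference ratings.

    ``ratings`` are the per-participant mean ratings of the reference
    condition (here: original neutral bursts).
    """
    ratings = np.asarray(ratings, dtype=float)
    if len(ratings) < 2:
        raise ValueError("need at least two reference ratings to compute delta")
    return float(np.std(ratings, ddof=1))


def _wilcoxon_one_sided(values: np.ndarray, alternative: str) -> float:
    """One-sided Wilcoxon signed-rank p-value, robust to degenerate input."""
    if np.allclose(values, 0.0):
        # all differences sit exactly on the boundary: no evidence either way
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(values, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue)


def tost_npar(
    diffs, delta: float, alpha: float = 0.05, comparison: str = ""
) -> EquivalenceResult:
    """Nonparametric paired TOST via shifted Wilcoxon signed-rank tests.

    H0(1) (difference >= +delta) is tested by a lower-tail signed-rank
    test on ``diffs - delta``; H0(2) (difference <= -delta) by an
    upper-tail test on ``diffs + delta``. Equivalence is declared iff
    both one-sided p-values fall below ``alpha``. The reported point
    difference is the mean of the paired differences.
    """
    diffs = np.asarray(diffs, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if len(diffs) < 2:
        raise ValueError("need at least two paired differences")
    note = ""
    degenerate = np.allclose(diffs - delta, 0.0) or np.allclose(diffs + delta, 0.0)
    if degenerate:
        note = "all differences equal a boundary of the equivalence interval"
        warnings.warn(note, stacklevel=2)
    p_upper = _wilcoxon_one_sided(diffs - delta, "less")
    p_lower = _wilcoxon_one_sided(diffs + delta, "greater")
    mean_diff = float(np.mean(diffs))
    return EquivalenceResult(
        comparison=comparison,
        delta=delta,
        point_difference=mean_diff,
        ci_low=np.nan,
        ci_high=np.nan,
        p_upper=p_upper,
        p_lower=p_lower,
        equivalent=bool(p_upper < alpha and p_lower < alpha),
        n=len(diffs),
        note=note,
    )


def tost_paired_t(
    diffs, delta: float, alpha: float = 0.05, comparison: str = ""
) -> EquivalenceResult:
    """Parametric paired TOST (one-sample t tests on shifted differences)."""
    diffs = np.asarray(diffs, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if len(diffs) < 2:
        raise ValueError("need at least two paired differences")
    n = len(diffs)
    mean, sd = np.mean(diffs), np.std(diffs, ddof=1)
    se = sd / np.sqrt(n)
    if se == 0:
        p_upper = 0.0 if mean < delta else 1.0
        p_lower = 0.0 if mean > -delta else 1.0
    else:
        p_upper = float(stats.t.cdf((mean - delta) / se, df=n - 1))
        p_lower = float(stats.t.sf((mean + delta) / se, df=n - 1))
    return EquivalenceResult(
        comparison=comparison,
        delta=delta,
        point_difference=float(mean),
        ci_low=np.nan,
        ci_high=np.nan,
        p_upper=p_upper,
        p_lower=p_lower,
        equivalent=bool(p_upper < alpha and p_lower < alpha),
        n=n,
    )


def bootstrap_ci(
    diffs,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    statistic: str = "mean",
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean (or median) paired difference."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least two paired differences")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small; percentile bounds will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
    resampled = diffs[idx]
    if statistic == "median":
        estimates = np.median(resampled, axis=1)
    else:
        estimates = resampled.mean(axis=1)
    lo, hi = np.percentile(
        estimates, [100 * (1 - level) / 2, 100 * (1 + level) / 2]
    )
    return float(lo), float(hi)


# canonical ordering of the comparison rows: method blocks x valences
MANIPULATION_ORDER = ["freq_scr", "phase_scr", "time12_scr", "time6_scr"]
VALENCE_ORDER = ["neutral", "anger", "happiness"]


def equivalence_table(
    condition_means: pd.DataFrame,
    reference: tuple[str, str] = ("original", "neutral"),
    delta: float | None = None,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Equivalence of every scrambled condition against a reference.

    ``condition_means`` holds per-participant condition means with
    columns ``participant_id``, ``manipulation``, ``valence_category``,
    ``valence_rating`` (each participant's mean over the stimuli of that
    cell). Every (manipulation, valence) cell whose manipulation differs
    from the reference's is paired within participant against the
    reference cell and tested for equivalence; delta defaults to the SD
    of the reference-condition participant means. Participants missing
    either side of a pair are dropped from that comparison and counted
    in the row's ``n_missing``.
    """
    required = {"participant_id", "manipulation", "valence_category", "valence_rating"}
    missing_cols = required - set(condition_means.columns)
    if missing_cols:
        raise ValueError(f"condition_means missing columns: {sorted(missing_cols)}")

    ref_manip, ref_val = reference
    ref = condition_means[
        (condition_means["manipulation"] == ref_manip)
        & (condition_means["valence_category"] == ref_val)
    ].set_index("participant_id")["valence_rating"]
    if ref.empty:
        raise ValueError(f"reference condition {reference} not present")
    if delta is None:
        delta = delta_from_reference(ref.to_numpy())

    manips = [
        m
        for m in MANIPULATION_ORDER
        if m in set(condition_means["manipulation"]) and m != ref_manip
    ]
    # any manipulations outside the canonical list come last, sorted
    extras = sorted(
        set(condition_means["manipulation"]) - set(manips) - {ref_manip}
    )
    valences = [
        v for v in VALENCE_ORDER if v in set(condition_means["valence_category"])
    ]
    n_comparisons = sum(
        1
        for m in manips + extras
        for v in valences
        if not condition_means[
            (condition_means["manipulation"] == m)
            & (condition_means["valence_category"] == v)
        ].empty
    )
    alpha_eff = alpha / n_comparisons if (bonferroni and n_comparisons) else alpha

    rows = []
    boot_rng = np.random.default_rng(seed)
    for manip in manips + extras:
        for val in valences:
            cond = condition_means[
                (condition_means["manipulation"] == manip)
                & (condition_means["valence_category"] == val)
            ].set_index("participant_id")["valence_rating"]
            if cond.empty:
                continue
            paired = pd.concat(
                [cond.rename("cond"), ref.rename("ref")], axis=1, join="inner"
            ).dropna()
            n_missing = max(len(cond), len(ref)) - len(paired)
            label = f"{manip} {val}"
            if len(paired) < 2:
                rows.append(
                    {
                        "comparison": label,
                        "difference": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_upper": np.nan,
                        "p_lower": np.nan,
                        "equivalent": False,
                        "n": len(paired),
                        "n_missing": n_missing,
                        "note": "insufficient complete pairs",
                    }
                )
                continue
            diffs = (paired["cond"] - paired["ref"]).to_numpy()
            res = tost_npar(diffs, delta=delta, alpha=alpha_eff, comparison=label)
            lo, hi = bootstrap_ci(
                diffs, n_boot=n_boot, seed=int(boot_rng.integers(2**31))
            )
            rows.append(
                {
                    "comparison": label,
                    "difference": res.point_difference,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_upper": res.p_upper,
                    "p_lower": res.p_lower,
                    "equivalent": res.equivalent,
                    "n": res.n,
                    "n_missing": n_missing,
                    "note": res.note,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["delta"] = delta
    table.attrs["alpha"] = alpha_eff
    table.attrs["reference"] = reference
    return table
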