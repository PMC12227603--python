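"""Cohort statistics: tissue HER2 rule, A/A'/B/C grouping, concordance,
rank correlation, group comparisons and survival.

Grouping logic
--------------
Tissue HER2 status follows the IHC/FISH consensus rule: IHC 0/1+ negative,
IHC 3+ positive, IHC 2+ resolved by FISH with a strict ratio > 2.0.
Patients are then stratified by the pair (tissue status, CTC status):

* A — tissue-positive (A' marks the subset with a CTC measurement);
* B — tissue-negative but CTC HER2-positive;
* C — negative in both.

A tissue-negative patient without a CTC measurement cannot be told apart
between B and C and is rejected rather than guessed.

Hypothesis tests are the standard nonparametric companions of a small
non-normal cohort: Spearman correlation, Kruskal-Wallis, two-sided
Mann-Whitney for pairwise contrasts, Pearson chi-square for categorical
associations, and Kaplan-Meier curves with a k-sample log-rank test for
progression-free survival.  No multiplicity correction is applied by
default; Holm-adjusted p-values are available on request.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ctcflow.errors import (
    MissingFISHError,
    UnclassifiableError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "Concordance",
    "SurvivalCurve",
    "assign_group",
    "assign_groups",
    "categorical_association",
    "concordance",
    "group_emt_summary",
    "holm_adjust",
    "km_estimate",
    "kruskal_wallis",
    "logrank_test",
    "pairwise_rank_test",
    "round_half_up",
    "spearman_rho",
    "tissue_her2_status",
]

IHC_SCORES = ("0", "1+", "2+", "3+")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (57 from 56.52...).

    Python's builtin ``round`` is banker's rounding; percent concordance is
    reported with the conventional half-up rule instead.
    """
    return int(math.floor(x + 0.5))


def tissue_her2_status(
    ihc_score: str, fish_ratio: float | None = None
) -> str:
    """Histological HER2 call from IHC, with FISH resolving equivocal 2+.

    IHC 0/1+ -> negative, 3+ -> positive; 2+ is positive iff the
    HER2:CEP17 FISH ratio strictly exceeds 2.0.  A FISH ratio supplied with
    a non-equivocal score is ignored with a warning.
    """
    score = str(ihc_score).strip()
    if score == "1":
        score = "1+"
    if score not in IHC_SCORES:
        raise ValidationError(
            f"IHC score must be one of {IHC_SCORES}, got {ihc_score!r}"
        )
    if score == "2+":
        if fish_ratio is None or (
            isinstance(fish_ratio, float) and math.isnan(fish_ratio)
        ):
            raise MissingFISHError(
                "IHC 2+ is equivocal and needs a FISH ratio"
            )
        if fish_ratio <= 0:
            raise ValidationError(f"FISH ratio must be > 0, got {fish_ratio}")
        return "positive" if fish_ratio > 2.0 else "negative"
    if fish_ratio is not None and not (
        isinstance(fish_ratio, float) and math.isnan(fish_ratio)
    ):
        warnings.warn(
            f"FISH ratio given with IHC {score}; ignored", stacklevel=2
        )
    return "positive" if score == "3+" else "negative"


def assign_group(
    tissue: str, ctc: str | None = None
) -> tuple[str, bool]:
    """Map (tissue status, CTC status) to a group letter plus the A' flag.

    Returns ``(group, a_prime)``; ``a_prime`` is True only for
    tissue-positive patients that also carry a CTC measurement.
    """
    if tissue not in ("positive", "negative"):
        raise ValidationError(f"bad tissue status {tissue!r}")
    if ctc is not None and ctc not in ("positive", "negative"):
        raise ValidationError(f"bad CTC status {ctc!r}")
    if tissue == "positive":
        return "A", ctc is not None
    if ctc is None:
        raise UnclassifiableError(
            "tissue-negative patient without CTC status: cannot separate "
            "group B from group C"
        )
    return ("B", False) if ctc == "positive" else ("C", False)


def assign_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`assign_group` over a cohort table.

    Expects ``tissue_her2`` and ``ctc_her2_status`` columns; returns a copy
    with ``group`` and ``a_prime`` columns filled in.
    """
    out = records.copy()
    groups, primes = [], []
    for tissue, ctc in zip(out["tissue_her2"], out["ctc_her2_status"]):
        if ctc is None or (isinstance(ctc, float) and math.isnan(ctc)):
            ctc = None
        g, ap = assign_group(tissue, ctc)
        groups.append(g)
        primes.append(ap)
    out["group"] = groups
    out["a_prime"] = primes
    return out


@dataclass(frozen=True)
class Concordance:
    n_concordant: int
    n_total: int

    @property
    def percent(self) -> int:
        return round_half_up(100.0 * self.n_concordant / self.n_total)


def concordance(records: pd.DataFrame) -> Concordance:
    """Tissue/CTC HER2 agreement over patients with both statuses.

    Patients lacking a CTC status are excluded from numerator and
    denominator alike.
    """
    both = records.dropna(subset=["ctc_her2_status"])
    both = both[both["ctc_her2_status"].isin(["positive", "negative"])]
    if len(both) == 0:
        raise UndefinedStatisticError(
            "no patients with both tissue and CTC HER2 status"
        )
    agree = int((both["tissue_her2"] == both["ctc_her2_status"]).sum())
    return Concordance(n_concordant=agree, n_total=len(both))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("need >= 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError(
            "rank correlation undefined for a constant vector"
        )
    return float(stats.spearmanr(x, y).statistic)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df.

    Degenerate input with every value identical across all groups yields
    (H=0, p=1) rather than an error: zero between-group rank variance means
    no evidence against the null.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("every group needs >= 1 value")
    if sum(len(a) for a in arrays) < 3:
        raise ValidationError("need >= 3 values in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def pairwise_rank_test(group_i, group_j) -> float:
    """Two-sided Mann-Whitney rank-sum p-value (exact for small ties-free
    samples, normal approximation with tie correction otherwise)."""
    a = np.asarray(group_i, dtype=float)
    b = np.asarray(group_j, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def holm_adjust(pvalues) -> list[float]:
    """Holm step-down adjustment (optional; off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with at-risk counts.

    ``median`` is the smallest observed time at which survival drops to
    <= 0.5, or ``None`` when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    @property
    def median_label(self) -> str:
        return "not reached" if self.median is None else f"{self.median:g}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``times`` are months on study (> 0); ``events`` flags progression/death
    (True) versus censoring (False).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValidationError("empty survival input")
    if len(t) != len(e):
        raise ValidationError("times and events must have equal length")
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValidationError("times must be positive and finite")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
        .to_numpy(dtype=float)
    )
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return SurvivalCurve(
        times=grid, survival=surv, at_risk=at_risk, median=median
    )


def logrank_test(groups: dict) -> tuple[float, float]:
    """k-sample log-rank test across survival groups.

    ``groups`` maps label -> (times, events).  Returns (chi-square, p) with
    k - 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    times, events, labels = [], [], []
    total_events = 0
    for label, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValidationError(f"group {label!r} is empty")
        times.append(t)
        events.append(e)
        labels.extend([label] * len(t))
        total_events += int(e.sum())
    if total_events == 0:
        raise UndefinedStatisticError("no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.array(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def categorical_association(table) -> float:
    """Pearson chi-square p-value for an r x c contingency table.

    No continuity correction; warns when any expected count is below 5
    (the asymptotic approximation degrades there).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("need a table with >= 2 rows and >= 2 columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValidationError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("zero-margin row or column")
    res = stats.chi2_contingency(obs, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn(
            "expected cell count below 5; chi-square approximation is "
            "unreliable",
            stacklevel=2,
        )
    return float(res.pvalue)


def group_emt_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Median EMT-index (full precision + 2-decimal display) per stratum.

    Strata are A' (tissue-positive patients with CTC data), B and C;
    patients without an EMT measurement are excluded.
    """
    rec = records.dropna(subset=["emt_index"])
    strata = {
        "A'": rec[(rec["group"] == "A") & rec["a_prime"]],
        "B": rec[rec["group"] == "B"],
        "C": rec[rec["group"] == "C"],
    }
    rows = []
    for label, sub in strata.items():
        if len(sub) == 0:
            continue
        vals = sub["emt_index"].to_numpy()
        rows.append(
            {
                "stratum": label,
                "n": len(vals),
                "median": float(np.median(vals)),
                "median_display": f"{np.median(vals):.2f}",
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)
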