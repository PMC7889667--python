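"""Diagnostic evaluation of prognostic scores for 90-day and 1-year graft loss.

A score is treated as a diagnostic test for a dichotomized outcome (graft
loss by a horizon). Discrimination is summarised by the C-statistic / AUC —
the probability that a random event patient outscores a random non-event
patient, ties counting one half — with a DeLong standard error and normal
95% CI. At quantile-derived cut-offs (first quartile, median, third
quartile, ninth decile by default) sensitivity, specificity and the
diagnostic odds ratio

    DOR = (sens * spec) / ((1 - sens) * (1 - spec))

are tabulated; the higher the DOR, the greater the discriminative power.
Baseline cohort comparisons use the Mann-Whitney U test (continuous) and
Fisher's exact test (categorical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from cci_lt.cci_core import round_half_away

DEFAULT_CUTOFF_PROBS: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90)


@dataclass(frozen=True)
class BinaryOutcomeSet:
    """Scores paired with a dichotomized outcome at one horizon.

    Patients censored alive before the horizon are excluded at construction
    (their number is kept in ``n_excluded``); the set therefore contains only
    patients whose event status at the horizon is known.
    """

    scores: np.ndarray
    outcomes: np.ndarray  # boolean, True = event (graft loss by horizon)
    horizon: float
    patient_ids: Optional[np.ndarray] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "outcomes", np.asarray(self.outcomes, dtype=bool))
        if self.scores.shape != self.outcomes.shape:
            raise ValueError("scores and outcomes must have equal length")

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n_nonevents(self) -> int:
        return int((~self.outcomes).sum())


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan


@dataclass(frozen=True)
class DiagnosticRow:
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    dor: float
    boundary: bool = False  # True when sens or spec hit 0/1 and DOR is 0 or inf


@dataclass(frozen=True)
class DiagnosticTable:
    """Per-score diagnostic summary in the layout of a score-comparison table."""

    score_name: str
    auc: float
    auc_se: float
    ci_low: float
    ci_high: float
    rows: tuple[DiagnosticRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain the AUC")


def dichotomize_graft_loss(
    times: Sequence[float],
    events: Sequence[bool],
    horizon: float,
    patient_ids: Optional[Sequence] = None,
    scores: Optional[Sequence[float]] = None,
) -> BinaryOutcomeSet:
    """Dichotomize survival data at a horizon.

    Event: graft loss at time <= horizon. Non-event: followed beyond the
    horizon without loss. Patients censored loss-free before the horizon are
    excluded and counted in ``n_excluded``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if np.any(times < 0):
        raise ValueError("follow-up times must be non-negative")
    is_event = events & (times <= horizon)
    is_nonevent = times > horizon
    keep = is_event | is_nonevent
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"no patient has a determinable {horizon:g}-day outcome (all censored early)")
    scores_arr = np.asarray(scores, dtype=float)[keep] if scores is not None else np.full(keep.sum(), np.nan)
    ids_arr = np.asarray(patient_ids)[keep] if patient_ids is not None else None
    return BinaryOutcomeSet(
        scores=scores_arr,
        outcomes=is_event[keep],
        horizon=float(horizon),
        patient_ids=ids_arr,
        n_excluded=n_excluded,
    )


def _delong_auc_se(event_scores: np.ndarray, nonevent_scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong standard error via midrank placements."""
    m, n = len(event_scores), len(nonevent_scores)
    combined = np.concatenate([event_scores, nonevent_scores])
    ranks = stats.rankdata(combined)  # midranks
    ranks_events = stats.rankdata(event_scores)
    ranks_nonevents = stats.rankdata(nonevent_scores)
    # placement of each event among non-events, and vice versa
    v10 = (ranks[:m] - ranks_events) / n
    v01 = 1.0 - (ranks[m:] - ranks_nonevents) / m
    auc = float(v10.mean())
    if m < 2 or n < 2:
        return auc, math.nan
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    return auc, math.sqrt(s10 / m + s01 / n)


def roc_auc(outcome_set: BinaryOutcomeSet) -> tuple[float, float, tuple[float, float]]:
    """C-statistic of a score for the dichotomized outcome.

    Returns (AUC, SE, (ci_low, ci_high)) with the DeLong SE and a normal 95%
    CI truncated to [0, 1]. Requires at least one event and one non-event.
    """
    ev = outcome_set.scores[outcome_set.outcomes]
    ne = outcome_set.scores[~outcome_set.outcomes]
    if len(ev) == 0 or len(ne) == 0:
        raise ValueError("ROC needs at least one event and one non-event")
    auc, se = _delong_auc_se(ev, ne)
    if math.isnan(se):
        ci = (0.0, 1.0)
    else:
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return auc, se, ci


def quantile_cutoffs(
    scores: Sequence[float], probs: Sequence[float] = DEFAULT_CUTOFF_PROBS
) -> list[float]:
    """Quantiles by linear interpolation of order statistics at rank 1 + (n-1)p."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores to derive quantile cut-offs")
    if any(not (0 < p < 1) for p in probs):
        raise ValueError("cut-off probabilities must lie strictly between 0 and 1")
    return [float(q) for q in np.quantile(scores, list(probs), method="linear")]


def confusion_at_cutoff(
    outcome_set: BinaryOutcomeSet, cutoff: float, *, positive_if_equal: bool = False
) -> ConfusionCounts:
    """Cross-classify test positivity (score > cutoff, or >= with the switch) vs outcome."""
    positive = outcome_set.scores >= cutoff if positive_if_equal else outcome_set.scores > cutoff
    ev = outcome_set.outcomes
    return ConfusionCounts(
        tp=int((positive & ev).sum()),
        fp=int((positive & ~ev).sum()),
        tn=int((~positive & ~ev).sum()),
        fn=int((~positive & ev).sum()),
    )


def diagnostic_odds_ratio(sens: float, spec: float) -> float:
    """DOR from a sensitivity/specificity pair (proportions in [0, 1]).

    At a boundary (sens or spec exactly 0 or 1) the ratio is reported as 0 or
    inf without any continuity correction; 0/0 combinations give nan.
    """
    for name, v in (("sensitivity", sens), ("specificity", spec)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sens * spec
    den = (1.0 - sens) * (1.0 - spec)
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def dor_from_counts(counts: ConfusionCounts, correction: float = 0.0) -> float:
    """DOR = (tp*tn)/(fp*fn); ``correction`` (e.g. Haldane 0.5) is added to every cell."""
    tp, fp, tn, fn = (c + correction for c in (counts.tp, counts.fp, counts.tn, counts.fn))
    if fp * fn == 0.0:
        return math.nan if tp * tn == 0.0 else math.inf
    return (tp * tn) / (fp * fn)


def diagnostic_table(
    score_name: str,
    outcome_set: BinaryOutcomeSet,
    cutoffs: Optional[Sequence[float]] = None,
    *,
    positive_if_equal: bool = False,
) -> DiagnosticTable:
    """AUC plus per-cut-off sensitivity/specificity/DOR rows for one score."""
    auc, se, ci = roc_auc(outcome_set)
    rows = []
    for c in sorted(cutoffs if cutoffs is not None else []):
        cc = confusion_at_cutoff(outcome_set, c, positive_if_equal=positive_if_equal)
        sens, spec = cc.sensitivity, cc.specificity
        dor = diagnostic_odds_ratio(sens, spec)
        rows.append(
            DiagnosticRow(
                cutoff=float(c),
                sensitivity=round_half_away(100.0 * sens, 1),
                specificity=round_half_away(100.0 * spec, 1),
                dor=dor,
                boundary=not math.isfinite(dor),
            )
        )
    return DiagnosticTable(score_name, auc, se, ci[0], ci[1], tuple(rows))


def compare_scores(
    outcome_sets: Mapping[str, BinaryOutcomeSet],
    cutoffs_by_score: Optional[Mapping[str, Sequence[float]]] = None,
) -> list[DiagnosticTable]:
    """One DiagnosticTable per score, sorted by AUC descending.

    All sets must come from the same cohort and horizon (checked on patient
    ids when available). Binary scores such as the EAD flag go through the
    same ROC machinery, yielding the two-point trapezoid AUC
    (sens + spec) / 2.
    """
    sets = list(outcome_sets.items())
    if not sets:
        raise ValueError("no scores to compare")
    _, first = sets[0]
    for name, s in sets[1:]:
        if s.horizon != first.horizon:
            raise ValueError(f"score {name!r} evaluated at a different horizon")
        if (
            first.patient_ids is not None
            and s.patient_ids is not None
            and not np.array_equal(first.patient_ids, s.patient_ids)
        ):
            raise ValueError(f"score {name!r} covers a different patient set")
    tables = [
        diagnostic_table(name, s, (cutoffs_by_score or {}).get(name))
        for name, s in sets
    ]
    return sorted(tables, key=lambda t: t.auc, reverse=True)


def compare_cohorts(
    group_a: Sequence[float],
    group_b: Sequence[float],
    kind: str = "continuous",
) -> tuple[float, float]:
    """Two-cohort baseline comparison: (statistic, p-value).

    ``kind="continuous"``: Mann-Whitney U with the tie-corrected normal
    approximation. ``kind="categorical"``: the groups are 0/1 indicators and
    a two-sided Fisher's exact test is run on the implied 2x2 table.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "categorical":
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("categorical comparison expects 0/1 indicators")
        table = [[int(a.sum()), int(a.size - a.sum())], [int(b.sum()), int(b.size - b.sum())]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown comparison kind {kind!r}")
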