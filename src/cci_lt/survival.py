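"""Graft survival by CCI stratum and Cox proportional-hazards modelling.

Kaplan-Meier product-limit curves and the log-rank test describe survival
across the five CCI risk strata (0-12.2, 12.3-29.6, 29.7-47.3, 47.4-84.9,
85-100, i.e. the training-set quartile/ninth-decile bands). Cox regression
quantifies covariate effects on the graft-loss hazard; a backward-Wald
procedure screens univariably significant covariates (p < 0.20) and then
iteratively drops the least significant one until all retained covariates
fall below the removal threshold. MELD and D-MELD are never allowed into the
same model (D-MELD is donor age x MELD, a built-in collinearity).

KM and log-rank computations are delegated to lifelines; Cox fitting to the
statsmodels proportional-hazards machinery (Breslow tie handling by default,
Efron optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

#: Right-closed CCI stratum boundaries: [0, 12.2], (12.2, 29.6], (29.6, 47.3],
#: (47.3, 84.9], (84.9, 100].
CCI_STRATUM_BOUNDS: tuple[float, ...] = (12.2, 29.6, 47.3, 84.9)
CCI_STRATUM_LABELS: tuple[str, ...] = (
    "0.0-12.2",
    "12.3-29.6",
    "29.7-47.3",
    "47.4-84.9",
    "85.0-100.0",
)

#: Covariate pairs that must never enter one multivariable model together.
COLLINEAR_PAIRS: tuple[tuple[str, str], ...] = (("meld", "d_meld"),)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time (days, > 0), graft-loss flag, covariates."""

    patient_id: str
    time: float
    event: bool
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"follow-up time must be positive, got {self.time} for {self.patient_id!r}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(0)=1 and S non-increasing over event times."""

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    beta: float
    se: float
    wald: float  # (beta / se)^2
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CoxFitResult:
    effects: tuple[CovariateEffect, ...]
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "breslow"

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def minus_2_log_likelihood(self) -> float:
        return -2.0 * self.log_likelihood


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of backward-Wald selection: final model plus the removal order."""

    final: Optional[CoxFitResult]
    retained: tuple[str, ...]
    removed: tuple[tuple[str, float], ...]  # (covariate, p at removal)


def _records_frame(records: Sequence[SurvivalRecord], covariates: Sequence[str] = ()) -> pd.DataFrame:
    if not records:
        raise ValueError("no survival records")
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time": r.time, "event": bool(r.event)}
        for c in covariates:
            if c not in r.covariates:
                raise ValueError(f"record {r.patient_id!r} is missing covariate {c!r}")
            row[c] = float(r.covariates[c])
        rows.append(row)
    return pd.DataFrame(rows)


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod(1 - d_i / n_i).

    Events and censorings at identical times are resolved events-first (the
    censored patient is still at risk when the tied event occurs).
    """
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index and df["time"].min() > 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups: (chi-square, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    times, events, labels = [], [], []
    for i, g in enumerate(groups):
        for r in g:
            times.append(r.time)
            events.append(bool(r.event))
            labels.append(i)
    if not any(events):
        raise ValueError("log-rank needs at least one event overall")
    res = multivariate_logrank_test(np.asarray(times), np.asarray(labels), np.asarray(events))
    df = len(groups) - 1
    chi2 = float(res.test_statistic)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def cci_strata(scores: Sequence[float]) -> list[int]:
    """Assign each CCI value to one of the five risk strata (1..5, right-closed bands)."""
    out = []
    for s in scores:
        if not (0.0 <= s <= 100.0):
            raise ValueError(f"CCI value out of range [0, 100]: {s}")
        out.append(int(np.searchsorted(CCI_STRATUM_BOUNDS, s, side="left")) + 1)
    return out


def _check_collinearity(x: np.ndarray, names: Sequence[str]) -> None:
    if x.shape[1] < 2:
        return
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 0.9999:
                raise ValueError(f"covariates {names[i]!r} and {names[j]!r} are collinear")


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    *,
    ties: str = "breslow",
) -> CoxFitResult:
    """Cox proportional-hazards fit by partial-likelihood maximisation.

    Tie handling is Breslow by default (Efron via ``ties="efron"``). A
    covariate with zero variance cannot move the partial likelihood; it is
    reported with beta 0 and HR 1 (SE/p undefined). Exactly collinear
    covariate pairs are rejected by name.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie-handling method {ties!r}")
    df = _records_frame(records, covariates)
    if not df["event"].any():
        raise ValueError("Cox fit needs at least one event")
    x_all = df[list(covariates)].to_numpy(dtype=float)
    degenerate = [c for c in covariates if np.ptp(df[c].to_numpy()) == 0.0]
    active = [c for c in covariates if c not in degenerate]
    effects: dict[str, CovariateEffect] = {
        c: CovariateEffect(c, 0.0, math.nan, math.nan, 1.0, math.nan, math.nan, math.nan)
        for c in degenerate
    }
    llf = math.nan
    if active:
        x = df[active].to_numpy(dtype=float)
        _check_collinearity(x, active)
        model = PHReg(df["time"].to_numpy(), x, status=df["event"].to_numpy(dtype=int), ties=ties)
        res = model.fit(method="newton", disp=False, maxiter=100, tol=1e-8)
        llf = float(res.llf)
        for i, c in enumerate(active):
            beta = float(res.params[i])
            se = float(res.bse[i])
            effects[c] = CovariateEffect(
                name=c,
                beta=beta,
                se=se,
                wald=(beta / se) ** 2 if se > 0 else math.inf,
                hr=math.exp(beta),
                ci_low=math.exp(beta - 1.96 * se),
                ci_high=math.exp(beta + 1.96 * se),
                p_value=float(res.pvalues[i]),
            )
    elif x_all.size:
        # all-degenerate model: partial likelihood at beta = 0
        model = PHReg(
            df["time"].to_numpy(),
            np.zeros((len(df), 1)),
            status=df["event"].to_numpy(dtype=int),
            ties=ties,
        )
        llf = float(model.loglike(np.zeros(1)))
    return CoxFitResult(
        effects=tuple(effects[c] for c in covariates),
        log_likelihood=llf,
        n=len(df),
        n_events=int(df["event"].sum()),
        ties=ties,
    )


def univariable_screen(
    records: Sequence[SurvivalRecord],
    candidates: Sequence[str],
    *,
    entry_p: float = 0.20,
    ties: str = "breslow",
) -> tuple[dict[str, CoxFitResult], list[str]]:
    """Univariable Cox fit per candidate; keep those with p < ``entry_p``."""
    fits = {c: cox_fit(records, [c], ties=ties) for c in candidates}
    kept = [c for c in candidates if fits[c].effect(c).p_value < entry_p]
    return fits, kept


def backward_wald_select(
    records: Sequence[SurvivalRecord],
    candidates: Sequence[str],
    *,
    removal_p: float = 0.10,
    ties: str = "breslow",
    collinear_pairs: Sequence[tuple[str, str]] = COLLINEAR_PAIRS,
    drop_from_pair: str = "second",
) -> SelectionResult:
    """Backward-Wald covariate elimination from a pre-screened candidate set.

    Starting from the full multivariable model, the covariate with the
    largest Wald p-value is removed while that p-value is >= ``removal_p``,
    refitting after each removal. Of any declared collinear pair present
    among the candidates (MELD / D-MELD by default) only one member enters:
    ``drop_from_pair`` selects which is excluded up front ("first" or
    "second"); run the procedure twice to obtain the two parallel models.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    current = list(dict.fromkeys(candidates))
    for a, b in collinear_pairs:
        if a in current and b in current:
            current.remove(b if drop_from_pair == "second" else a)
    removed: list[tuple[str, float]] = []
    final: Optional[CoxFitResult] = None
    while current:
        final = cox_fit(records, current, ties=ties)
        pvals = {c: final.effect(c).p_value for c in current}
        # nan p-values (degenerate covariates) are removed first
        worst = max(current, key=lambda c: (math.isnan(pvals[c]), pvals[c]))
        worst_p = pvals[worst]
        if math.isnan(worst_p) or worst_p >= removal_p:
            current.remove(worst)
            removed.append((worst, worst_p))
            final = None
        else:
            break
    return SelectionResult(final=final, retained=tuple(current), removed=tuple(removed))
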