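"""End-to-end orchestration: score -> diagnostics -> survival, with reports.

`run_pipeline` takes a cohort (a named synthetic preset or delimited-text
files), computes the CCI per patient from the complication events, evaluates
CCI / MELD / D-MELD / BAR / EAD as diagnostic tests for graft loss at each
horizon (90 and 365 days by default), stratifies Kaplan-Meier graft survival
by the five CCI bands with a log-rank test, and fits univariable plus
backward-Wald multivariable Cox models (two parallel models so MELD and
D-MELD never share one model). An optional subgroup filter (e.g.
``"donor_age >= 70"``) re-runs the diagnostic evaluation on a subset, as in
the aged-donor sub-analysis.

All computation happens in memory first; report files are only written once
every stage has succeeded, so a failing run leaves no partial outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from cci_lt.cci_core import (
    ClavienDindoGrade,
    ComplicationEvent,
    compute_cci,
    grade_clinical_event,
    round_half_away,
)
from cci_lt.diagnostics import (
    DEFAULT_CUTOFF_PROBS,
    DiagnosticTable,
    compare_scores,
    dichotomize_graft_loss,
    quantile_cutoffs,
)
from cci_lt.survival import (
    SelectionResult,
    SurvivalRecord,
    backward_wald_select,
    cci_strata,
    cox_fit,
    km_fit,
    logrank_test,
    univariable_screen,
    CCI_STRATUM_LABELS,
)
from cci_lt.synthetic_cohort import generate_cohort, preset

SCORE_COLUMNS: tuple[str, ...] = ("cci", "meld", "d_meld", "bar", "ead_flag")
COX_COVARIATES: tuple[str, ...] = ("cci", "donor_age", "meld", "d_meld", "bar", "ead_flag")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Provide either ``preset_label`` (with ``n_patients`` and ``seed``) or the
    two input file paths. ``subgroup`` is a pandas query string over the
    patient table (e.g. ``"donor_age >= 70"``) evaluated as an additional
    diagnostic re-run, not a replacement of the full-cohort analysis.
    """

    preset_label: Optional[str] = None
    n_patients: int = 1262
    seed: int = 0
    events_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    horizons: tuple[float, ...] = (90.0, 365.0)
    cutoff_probs: tuple[float, ...] = DEFAULT_CUTOFF_PROBS
    positive_if_equal: bool = False
    subgroup: Optional[str] = None
    day_cutoff: Optional[int] = None
    outdir: Path = Path("results")

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")
        if any(not (0 < p < 1) for p in self.cutoff_probs):
            raise ValueError("cutoff probabilities must lie strictly in (0, 1)")
        if list(self.cutoff_probs) != sorted(self.cutoff_probs):
            raise ValueError("cutoff probabilities must be sorted ascending")
        if self.preset_label is None and (self.events_path is None or self.patients_path is None):
            raise ValueError("provide a preset_label or both events_path and patients_path")


@dataclass
class ReportBundle:
    """In-memory results of one run; ``write`` serialises them under an output directory."""

    scores: pd.DataFrame
    diagnostics: dict[float, list[DiagnosticTable]]
    subgroup_diagnostics: dict[float, list[DiagnosticTable]]
    km_strata: pd.DataFrame
    logrank: tuple[float, int, float]
    cox_univariable: pd.DataFrame
    cox_multivariable: pd.DataFrame
    run_log: list[str] = field(default_factory=list)

    def write(self, outdir: Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _save(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            df.to_csv(path, index=False)
            written.append(path)

        _save(self.scores, "cci_scores.csv")
        for horizon, tables in self.diagnostics.items():
            _save(_diagnostics_frame(tables), f"diagnostics_{int(horizon)}d.csv")
        for horizon, tables in self.subgroup_diagnostics.items():
            _save(_diagnostics_frame(tables), f"diagnostics_subgroup_{int(horizon)}d.csv")
        _save(self.km_strata, "km_strata.csv")
        _save(self.cox_univariable, "cox_univariable.csv")
        _save(self.cox_multivariable, "cox_multivariable.csv")
        log_path = outdir / "run_log.txt"
        chi2, df_, p = self.logrank
        lines = self.run_log + [f"log-rank chi-square={chi2:.2f} df={df_} p={p:.3g}"]
        log_path.write_text("\n".join(lines) + "\n")
        written.append(log_path)
        return written


def _diagnostics_frame(tables: Sequence[DiagnosticTable]) -> pd.DataFrame:
    """Score-comparison layout: one AUC row per score, then CCI cut-off rows."""
    rows = []
    for t in tables:
        rows.append(
            {
                "score": t.score_name,
                "row_type": "auc",
                "auc": round_half_away(t.auc, 2),
                "auc_se": round_half_away(t.auc_se, 2) if math.isfinite(t.auc_se) else "",
                "ci_low": round_half_away(t.ci_low, 2),
                "ci_high": round_half_away(t.ci_high, 2),
                "cutoff": "",
                "sensitivity": "",
                "specificity": "",
                "dor": "",
            }
        )
    for t in tables:
        for r in t.rows:
            rows.append(
                {
                    "score": t.score_name,
                    "row_type": "cutoff",
                    "auc": "",
                    "auc_se": "",
                    "ci_low": "",
                    "ci_high": "",
                    "cutoff": round_half_away(r.cutoff, 1),
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "dor": round_half_away(r.dor, 1) if math.isfinite(r.dor) else "inf",
                }
            )
    return pd.DataFrame(rows)


def expand_clinical_events(shorthand: pd.DataFrame) -> pd.DataFrame:
    """Expand a clinical-event shorthand table (patient_id, event_kind[, day]) to graded events."""
    rows = []
    for _, rec in shorthand.iterrows():
        for g in grade_clinical_event(rec["event_kind"]):
            rows.append(
                {
                    "patient_id": rec["patient_id"],
                    "grade": g.name,
                    "label": rec["event_kind"],
                    "day": rec.get("day"),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "grade", "label", "day"])


def read_cohort(events_path: Path, patients_path: Path) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Read and validate the events and patient tables.

    All schema violations are collected and reported together in one
    ValueError; soft inconsistencies (an event day beyond the recorded
    follow-up) come back as warning strings.
    """
    events = pd.read_csv(events_path, comment="#")
    patients = pd.read_csv(patients_path, comment="#")
    errors: list[str] = []
    warnings: list[str] = []

    for col in ("patient_id", "grade"):
        if col not in events.columns:
            errors.append(f"events file: missing column {col!r}")
    required = ("patient_id", "time_days", "graft_loss")
    for col in required:
        if col not in patients.columns:
            errors.append(f"patient file: missing column {col!r}")
    if errors:
        raise ValueError("cohort files invalid:\n" + "\n".join(errors))

    valid_grades = {g.name for g in ClavienDindoGrade}
    for i, g in enumerate(events["grade"]):
        if str(g) not in valid_grades:
            errors.append(f"events file row {i}: unknown grade {g!r}")
    if "day" in events.columns:
        bad = events.index[pd.to_numeric(events["day"], errors="coerce").fillna(0) < 0]
        errors.extend(f"events file row {i}: negative day" for i in bad)

    dup = patients["patient_id"][patients["patient_id"].duplicated()]
    errors.extend(f"patient file: duplicate patient_id {pid!r}" for pid in dup.unique())
    bad_time = patients.index[pd.to_numeric(patients["time_days"], errors="coerce").fillna(-1) <= 0]
    errors.extend(f"patient file row {i}: non-positive time_days" for i in bad_time)
    bad_loss = patients.index[~patients["graft_loss"].isin([0, 1])]
    errors.extend(f"patient file row {i}: graft_loss must be 0/1" for i in bad_loss)

    if errors:
        raise ValueError("cohort files invalid:\n" + "\n".join(errors))

    if "day" in events.columns:
        fu = patients.set_index("patient_id")["time_days"]
        merged = events.dropna(subset=["day"]).join(fu, on="patient_id")
        late = merged[merged["day"] > merged["time_days"]]
        warnings.extend(
            f"event on day {int(r.day)} after follow-up end ({r.time_days:g}) for {r.patient_id!r}"
            for r in late.itertuples()
        )
    return events, patients, warnings


def score_events(
    events: pd.DataFrame,
    patient_ids: Sequence[str],
    day_cutoff: Optional[int] = None,
) -> pd.DataFrame:
    """Compute the CCI for every patient id (0 for patients without events)."""
    by_patient: dict[str, list[ComplicationEvent]] = {str(p): [] for p in patient_ids}
    for rec in events.itertuples():
        pid = str(rec.patient_id)
        day = None
        if hasattr(rec, "day") and rec.day is not None and not pd.isna(rec.day):
            day = int(rec.day)
        label = getattr(rec, "label", None)
        by_patient.setdefault(pid, []).append(
            ComplicationEvent(pid, ClavienDindoGrade.from_string(str(rec.grade)), label=label, day=day)
        )
    rows = []
    for pid in (str(p) for p in patient_ids):
        s = compute_cci(by_patient[pid], day_cutoff=day_cutoff)
        rows.append({"patient_id": pid, "cci": s.value, "cci_display": round_half_away(s.value, 1), "n_events": s.n_events})
    return pd.DataFrame(rows)


def _survival_records(patients: pd.DataFrame, covariates: Sequence[str]) -> list[SurvivalRecord]:
    recs = []
    for rec in patients.itertuples():
        recs.append(
            SurvivalRecord(
                patient_id=str(rec.patient_id),
                time=float(rec.time_days),
                event=bool(rec.graft_loss),
                covariates={c: float(getattr(rec, c)) for c in covariates},
            )
        )
    return recs


def evaluate_diagnostics(
    patients: pd.DataFrame,
    horizon: float,
    cutoff_probs: Sequence[float],
    *,
    positive_if_equal: bool = False,
    log: Optional[list[str]] = None,
) -> list[DiagnosticTable]:
    """Per-score DiagnosticTables (CCI with quantile cut-off rows) at one horizon."""
    sets = {
        name: dichotomize_graft_loss(
            patients["time_days"],
            patients["graft_loss"].astype(bool),
            horizon,
            patient_ids=patients["patient_id"],
            scores=patients[name],
        )
        for name in SCORE_COLUMNS
        if name in patients.columns
    }
    if log is not None and sets:
        first = next(iter(sets.values()))
        log.append(
            f"horizon {horizon:g} d: {first.n_events} events, {first.n_nonevents} non-events, "
            f"{first.n_excluded} censored before horizon excluded"
        )
    cci_cuts = quantile_cutoffs(patients["cci"], cutoff_probs)
    return compare_scores(sets, cutoffs_by_score={"cci": cci_cuts})


def _cox_summary_frame(fits: Mapping[str, object]) -> pd.DataFrame:
    rows = []
    for name, fit in fits.items():
        e = fit.effect(name) if hasattr(fit, "effect") else None
        rows.append(
            {
                "covariate": name,
                "beta": round_half_away(e.beta, 4),
                "se": round_half_away(e.se, 4) if math.isfinite(e.se) else "",
                "hr": round_half_away(e.hr, 2),
                "ci_low": round_half_away(e.ci_low, 2) if math.isfinite(e.ci_low) else "",
                "ci_high": round_half_away(e.ci_high, 2) if math.isfinite(e.ci_high) else "",
                "p_value": e.p_value,
            }
        )
    return pd.DataFrame(rows)


def _selection_frame(selections: Mapping[str, SelectionResult]) -> pd.DataFrame:
    rows = []
    for model_name, sel in selections.items():
        if sel.final is None:
            rows.append({"model": model_name, "covariate": "(none retained)"})
            continue
        for name in sel.retained:
            e = sel.final.effect(name)
            rows.append(
                {
                    "model": model_name,
                    "covariate": name,
                    "beta": round_half_away(e.beta, 4),
                    "se": round_half_away(e.se, 4),
                    "wald": round_half_away(e.wald, 2),
                    "hr": round_half_away(e.hr, 2),
                    "ci_low": round_half_away(e.ci_low, 2),
                    "ci_high": round_half_away(e.ci_high, 2),
                    "p_value": e.p_value,
                    "minus_2_loglik": round_half_away(sel.final.minus_2_log_likelihood, 2),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run score -> diagnostics -> survival and return the report bundle.

    The bundle is also written under ``config.outdir``. Reports are
    deterministic for identical config + seed.
    """
    from cci_lt import __version__  # deferred: avoids a circular import at package init

    log: list[str] = [f"cci-lt {__version__}", f"seed {config.seed}"]

    if config.preset_label is not None:
        cohort = generate_cohort(preset(config.preset_label, config.n_patients), config.seed)
        events, patients = cohort.events, cohort.patients.drop(columns=["cci"])
        log.append(f"synthetic cohort: preset {config.preset_label}, n={config.n_patients}")
        warnings: list[str] = []
    else:
        events, patients, warnings = read_cohort(config.events_path, config.patients_path)
        log.append(f"cohort files: {config.events_path}, {config.patients_path}")
    log.extend(f"warning: {w}" for w in warnings)

    # single scoring path: CCI always comes from cci_core.compute_cci, even if
    # the input table carried a cci column
    scores = score_events(events, patients["patient_id"], day_cutoff=config.day_cutoff)
    patients = patients.drop(columns=["cci"], errors="ignore").merge(
        scores[["patient_id", "cci"]], on="patient_id", how="left"
    )

    diagnostics = {
        h: evaluate_diagnostics(
            patients, h, config.cutoff_probs, positive_if_equal=config.positive_if_equal, log=log
        )
        for h in config.horizons
    }

    subgroup_diagnostics: dict[float, list[DiagnosticTable]] = {}
    if config.subgroup:
        sub = patients.query(config.subgroup)
        if sub.empty:
            raise ValueError(f"empty subgroup: no patient matches {config.subgroup!r}")
        log.append(f"subgroup {config.subgroup!r}: n={len(sub)}")
        subgroup_diagnostics = {
            h: evaluate_diagnostics(sub, h, config.cutoff_probs, positive_if_equal=config.positive_if_equal, log=log)
            for h in config.horizons
        }

    # survival by CCI stratum
    covs = [c for c in COX_COVARIATES if c in patients.columns]
    records = _survival_records(patients, covs)
    strata = cci_strata(patients["cci"].tolist())
    groups: dict[int, list[SurvivalRecord]] = {}
    for rec, s in zip(records, strata):
        groups.setdefault(s, []).append(rec)
    km_rows = []
    for s in sorted(groups):
        curve = km_fit(groups[s])
        km_rows.append(
            {
                "stratum": s,
                "cci_band": CCI_STRATUM_LABELS[s - 1],
                "n": len(groups[s]),
                "events": int(sum(r.event for r in groups[s])),
                "surv_90d_pct": round_half_away(100 * curve.survival_at(90.0), 1),
                "surv_1y_pct": round_half_away(100 * curve.survival_at(365.0), 1),
            }
        )
    km_strata_df = pd.DataFrame(km_rows)
    logrank = logrank_test([groups[s] for s in sorted(groups)]) if len(groups) > 1 else (0.0, 0, 1.0)

    # Cox: univariable screen then two parallel backward-Wald models.
    # Covariates whose univariable fit is degenerate (e.g. separation in a
    # tiny cohort) are dropped from the screen with a logged note.
    usable = []
    for c in covs:
        try:
            cox_fit(records, [c])
            usable.append(c)
        except (ValueError, OverflowError, np.linalg.LinAlgError) as exc:
            log.append(f"univariable fit failed for {c!r}: {exc}")
    uni_fits, kept = univariable_screen(records, usable)
    log.append(f"univariable screen (p < 0.20) kept: {', '.join(kept) or '(none)'}")
    selections = {}
    if kept:
        try:
            selections["with_d_meld"] = backward_wald_select(records, kept, drop_from_pair="first")
            selections["with_meld"] = backward_wald_select(records, kept, drop_from_pair="second")
        except (ValueError, OverflowError, np.linalg.LinAlgError) as exc:
            log.append(f"multivariable selection failed: {exc}")
            selections = {}

    bundle = ReportBundle(
        scores=scores,
        diagnostics=diagnostics,
        subgroup_diagnostics=subgroup_diagnostics,
        km_strata=km_strata_df,
        logrank=logrank,
        cox_univariable=_cox_summary_frame(uni_fits),
        cox_multivariable=_selection_frame(selections),
        run_log=log,
    )
    bundle.write(config.outdir)
    return bundle
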