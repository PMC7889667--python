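#!/usr/bin/env python
"""Evaluate CCI vs MELD, D-MELD, BAR and EAD for 90-day and 1-year graft loss.

The CCI cut-offs (first quartile, median, third quartile, ninth decile) are
derived on the training-like cohort and then applied unchanged to the
validation-like cohort, mirroring a derive-then-validate design. For each
cohort and horizon the script writes a score-comparison table (AUC with
DeLong SE and 95% CI, plus sensitivity/specificity/DOR per CCI cut-off) and
prints the AUC ranking.
"""

import argparse
from pathlib import Path

from cci_lt.diagnostics import compare_scores, dichotomize_graft_loss, quantile_cutoffs
from cci_lt.pipeline import SCORE_COLUMNS, _diagnostics_frame, read_cohort, score_events


def load_scored(cdir: Path):
    events, patients, _ = read_cohort(cdir / "events.csv", cdir / "patients.csv")
    scores = score_events(events, patients["patient_id"])
    return patients.drop(columns=["cci"], errors="ignore").merge(
        scores[["patient_id", "cci"]], on="patient_id"
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--outdir", type=Path, default=Path("results/diagnostics"))
    args = ap.parse_args()

    cohorts = {
        label: load_scored(args.cohorts / label)
        for label in ("training_like", "validation_like")
    }
    # cut-offs derived once, on the training-like cohort
    cutoffs = quantile_cutoffs(cohorts["training_like"]["cci"], (0.25, 0.50, 0.75, 0.90))
    print("CCI cut-offs from the training-like cohort (25th/50th/75th/90th): "
          + ", ".join(f"{c:.1f}" for c in cutoffs))

    args.outdir.mkdir(parents=True, exist_ok=True)
    for label, patients in cohorts.items():
        for horizon in (90.0, 365.0):
            sets = {
                name: dichotomize_graft_loss(
                    patients["time_days"], patients["graft_loss"].astype(bool), horizon,
                    patient_ids=patients["patient_id"], scores=patients[name],
                )
                for name in SCORE_COLUMNS
            }
            tables = compare_scores(sets, cutoffs_by_score={"cci": cutoffs})
            out = args.outdir / f"{label}_{int(horizon)}d.csv"
            _diagnostics_frame(tables).to_csv(out, index=False)
            ranking = ", ".join(f"{t.score_name} {t.auc:.2f}" for t in tables)
            excluded = next(iter(sets.values())).n_excluded
            print(f"{label} @ {int(horizon)} d: AUC ranking {ranking} "
                  f"({excluded} censored-early excluded) -> {out}")


if __name__ == "__main__":
    main()
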