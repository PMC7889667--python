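#!/usr/bin/env python
"""Re-run the diagnostic comparison on transplants from aged (>= 70 y) donors.

Repeats the score-comparison analysis restricted to the donor-age >= 70
subgroup of each cohort, the setting where a discharge-time morbidity score
is most likely to matter for follow-up planning.
"""

import argparse
from pathlib import Path

from cci_lt.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--outdir", type=Path, default=Path("results/aged_donor"))
    args = ap.parse_args()

    for label in ("training_like", "validation_like"):
        cdir = args.cohorts / label
        cfg = RunConfig(
            events_path=cdir / "events.csv",
            patients_path=cdir / "patients.csv",
            subgroup="donor_age >= 70",
            outdir=args.outdir / label,
        )
        bundle = run_pipeline(cfg)
        print(f"{label} (donor age >= 70):")
        for horizon, tables in bundle.subgroup_diagnostics.items():
            ranking = ", ".join(f"{t.score_name} {t.auc:.2f}" for t in tables)
            print(f"  {int(horizon)} d AUC ranking: {ranking}")
        print(f"  reports under {args.outdir / label}")


if __name__ == "__main__":
    main()
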