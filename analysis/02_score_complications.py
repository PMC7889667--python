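#!/usr/bin/env python
"""Score every patient's complication course with the CCI.

Reads the cohort tables written by 01_simulate_cohorts.py, computes the CCI
per patient through the package's single scoring path, and summarises the
score distribution (median, IQR, fraction complication-free, fraction at
100) for each cohort.
"""

import argparse
from pathlib import Path

import numpy as np

from cci_lt.pipeline import read_cohort, score_events


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--outdir", type=Path, default=Path("results/scores"))
    args = ap.parse_args()

    for label in ("training_like", "validation_like"):
        cdir = args.cohorts / label
        events, patients, warnings = read_cohort(cdir / "events.csv", cdir / "patients.csv")
        for w in warnings:
            print(f"  warning: {w}")
        scores = score_events(events, patients["patient_id"])
        args.outdir.mkdir(parents=True, exist_ok=True)
        out = args.outdir / f"{label}_cci.csv"
        scores.to_csv(out, index=False)

        cci = scores["cci"].to_numpy()
        q1, med, q3 = np.percentile(cci, [25, 50, 75])
        print(f"{label}: n={len(cci)}")
        print(f"  median CCI {med:.1f} (IQR {q1:.1f}-{q3:.1f})")
        print(f"  complication-free {100 * (cci == 0).mean():.1f}%, CCI=100 {100 * (cci == 100).mean():.1f}%")
        print(f"  wrote {out}")


if __name__ == "__main__":
    main()
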