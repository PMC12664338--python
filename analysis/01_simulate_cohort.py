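#!/usr/bin/env python
"""Simulate the raw accelerometer cohort.

Generates 10 s vertical-axis count streams for a small synthetic cohort
(45 persons x 7 days: daily wear between roughly 06:30 and 21:30 with
sedentary, light and active bouts, some persons with deliberately poor
wear) plus a one-shot survey with pain/fatigue/well-being scores on the
0-10 numeric rating scale. Raw streams go to scratch/ (they are large);
everything downstream reads from there.

Run: python analysis/01_simulate_cohort.py [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import actdsem as ad
from actdsem import io
from actdsem.cli import _random_epoch_spec

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--persons", type=int, default=45)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    out_dir = ROOT / "scratch" / "cohort"
    out_dir.mkdir(parents=True, exist_ok=True)

    series = []
    for i in range(args.persons):
        pid = f"p{i + 1:03d}"
        spec = _random_epoch_spec(pid, 7, rng)
        if i % 11 == 10:  # a few near-non-wearers, to exercise the protocol
            spec = ad.EpochSimSpec(
                n_days=7,
                wear_bouts=[[(600, 780, 200.0)] if d < 3 else [] for d in range(7)],
                seed=int(rng.integers(2**31)),
                person_id=pid,
            )
        stream, _ = ad.simulate_epoch_stream(spec)
        series.append(stream)
    io.write_epochs(series, out_dir / "epochs.csv")

    survey = pd.DataFrame(
        {
            "person_id": [s.person_id for s in series],
            "pain": np.clip(rng.normal(1.9, 2.4, args.persons), 0, 10).round(1),
            "fatigue": np.clip(rng.normal(3.5, 3.4, args.persons), 0, 10).round(1),
            "wellbeing": np.clip(rng.normal(6.4, 2.4, args.persons), 0, 10).round(1),
        }
    )
    survey.to_csv(out_dir / "survey.csv", index=False)
    print(f"wrote {len(series)} epoch streams and survey to {out_dir}")


if __name__ == "__main__":
    main()
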