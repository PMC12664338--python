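#!/usr/bin/env python
"""Apply the wear protocol and build the day-level panel.

Collapses the 10 s streams to counts per minute, flags non-wear
(>= 60 min of zeros with a 2-min sub-100-cpm allowance), classifies
minutes at the 100 cpm cut-point, applies the inclusion rule (>= 500
wear-min days, >= 4 valid days incl. one weekend day), and joins the
survey. Writes the panel and the day-wise descriptives table (mean +- SD
of wear/SB/PA, SB share, day-wise SB-PA Spearman correlations).

Run after 01: python analysis/02_preprocess.py
"""

from pathlib import Path

import pandas as pd

import actdsem as ad
from actdsem import io
from actdsem.prep import build_panel, process_person

ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort = ROOT / "scratch" / "cohort"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    records = []
    for stream in io.read_epochs(cohort / "epochs.csv"):
        records.extend(process_person(stream))
    survey = pd.read_csv(cohort / "survey.csv")
    panel, validities = build_panel(records, survey)

    io.write_panel(panel, results / "panel.csv")
    desc = ad.descriptives(panel)
    desc.to_csv(results / "descriptives.csv", index=False, float_format="%.4g")

    included = sum(v.included for v in validities)
    print(f"{included}/{len(validities)} participants meet the wear protocol")
    for v in validities:
        if not v.included:
            print(
                f"  excluded {v.person_id}: {v.n_valid_days} valid days, "
                f"{v.n_valid_weekend_days} on weekends"
            )
    with pd.option_context("display.width", 120):
        print(desc[["day_index", "n", "wear_min_mean", "sb_min_mean",
                    "pa_min_mean", "sb_share_ratio_of_means", "spearman_r",
                    "spearman_p"]].round(3))


if __name__ == "__main__":
    main()
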