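#!/usr/bin/env python
"""Fit the three DSEM models (pain, fatigue, well-being as moderator).

Each model is the same bivariate multilevel VAR(1): person-specific
means, autoregressions, cross-lags and log innovation variances, all
random at the between level and regressed on one grand-mean-centered
symptom score. Writes a full summary table per model (unstandardized
fixed effects, random-effect variances, standardized within/between
blocks, R^2) plus draws and convergence diagnostics.

Run after 02: python analysis/03_fit_models.py [--iterations 50000 --thin 10]
"""

import argparse
from pathlib import Path

import actdsem as ad
from actdsem import io

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--iterations", type=int, default=10_000)
    parser.add_argument("--thin", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    results = ROOT / "results"
    panel = io.read_panel(results / "panel.csv")

    for k, predictor in enumerate(("pain", "fatigue", "wellbeing")):
        model_panel = panel.select_predictor(predictor)
        config = ad.FitConfig(
            iterations=args.iterations, thin=args.thin, n_chains=2,
            seed=args.seed + k,
        )
        draws = ad.fit(model_panel, config)
        table = ad.make_summary_table(draws, model_panel)
        io.write_summary(table, results / f"model_{predictor}_summary.csv")
        io.write_draws(draws, results / f"model_{predictor}_draws.csv")
        psr = ad.psr(draws)
        dic_val, pd_val = ad.dic(draws, model_panel)
        io.write_manifest(
            {
                "predictor": predictor,
                "iterations": args.iterations,
                "thin": args.thin,
                "seed": args.seed + k,
                "dic": dic_val,
                "pd": pd_val,
                "psr_max": max(psr.values()),
                "antipersistence_share": table.attrs["antipersistence_share"],
                "coefficient_ranges": table.attrs["coefficient_ranges"],
            },
            results / f"model_{predictor}_manifest.json",
        )
        fixed = table[table["block"] == "fixed"].set_index("parameter")
        print(f"\n=== model: {predictor} ===")
        print(f"DIC = {dic_val:.2f}, pD = {pd_val:.2f}, PSR max = {max(psr.values()):.3f}")
        for name in ("phi_sb", "phi_pa", "beta_sb", "beta_pa"):
            row = fixed.loc[name]
            print(
                f"  {name:8s} {row['estimate']:+.3f} "
                f"[{row['ci_2.5']:+.3f}, {row['ci_97.5']:+.3f}]"
            )


if __name__ == "__main__":
    main()
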