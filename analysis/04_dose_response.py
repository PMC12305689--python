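#!/usr/bin/env python
"""Dose-response regression and hemisphere comparison.

Reads results/slices.csv, fits mean ROI GFAP+ fraction against
prescription dose for both hemispheres (OLS with a two-sided Wald t-test
of slope = 0), summarizes per-dose-level means +/- SD, writes
results/dose_response.json and results/per_level_summary.csv, and plots
the fraction-versus-dose figure with the fitted lines.

    python analysis/04_dose_response.py
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gfapquant.stats import fit_dose_response, summarize_hemispheres


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    df = pd.read_csv(args.results / "slices.csv")
    summary = summarize_hemispheres(df)
    fits = {
        side: fit_dose_response(df["prescription_dose_Gy"], df[f"{side}_fraction"])
        for side in ("right", "left")
    }

    for side, fit in fits.items():
        verdict = "significant" if fit.significant else "not significant"
        print(
            f"{side} ROI: slope {fit.slope:.3e} /Gy (SE {fit.slope_se:.1e}), "
            f"p = {fit.p_value:.3g} -> {verdict} at 0.05"
        )
    print("\nper-level summary:")
    print(summary.per_level.to_string(index=False))

    report = {f"{side}_roi_fit": fit.to_dict() for side, fit in fits.items()}
    (args.results / "dose_response.json").write_text(json.dumps(report, indent=2))
    summary.per_level.to_csv(args.results / "per_level_summary.csv", index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    lvl = summary.per_level
    ax.errorbar(lvl.prescription_dose_Gy, lvl.right_mean, yerr=lvl.right_sd,
                fmt="o", capsize=4, label="right ROI (irradiated)")
    ax.errorbar(lvl.prescription_dose_Gy, lvl.left_mean, yerr=lvl.left_sd,
                fmt="s", capsize=4, label="left ROI (contralateral)")
    x = np.linspace(0, df.prescription_dose_Gy.max(), 50)
    for side, style in (("right", "--"), ("left", ":")):
        fit = fits[side]
        ax.plot(x, fit.intercept + fit.slope * x, style, alpha=0.7)
    ax.set_xlabel("prescription dose (Gy)")
    ax.set_ylabel("mean GFAP+ area fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(args.results / "fig_dose_response.png", dpi=150)
    print(f"\nfigure and tables written to {args.results}/")


if __name__ == "__main__":
    main()
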