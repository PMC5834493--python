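#!/usr/bin/env python
"""Summarize the cohort run: envelope plots and a recovery report.

Reads the tables written by 02_run_cohort.py and produces per-canal
envelope figures (mean, quartile band, min-max band, reduced-sample
shading) under results/figures/, in the style of per-position profile
plots: cross-sectional areas, bony-membranous distances and area ratios
against percent centerline length (0% = end opposing the ampulla).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"
FIG = ROOT / "figures"

QUANTITIES = [("area_endo_mm2", "endolymph area (mm$^2$)"),
              ("area_peri_mm2", "perilymph area (mm$^2$)"),
              ("distance_mm", "bony-membranous distance (mm)"),
              ("ratio", "endolymph / bony area ratio")]
STRUCTURES = ["posterior", "superior", "lateral", "common_crus"]


def plot_envelope(ax, df, label):
    ax.fill_between(df.percent, df["min"], df["max"], color="0.85",
                    label="min-max")
    ax.fill_between(df.percent, df.q1, df.q3, color="0.65",
                    label="Q1-Q3")
    ax.plot(df.percent, df["mean"], color="crimson", lw=2, label="mean")
    for lo, hi in _runs(df.percent[df.reduced_n]):
        ax.axvspan(lo, hi, color="red", alpha=0.12, hatch="//", lw=0)
    ax.set_xlabel("% centerline length (toward ampulla)")
    ax.set_ylabel(label)
    ax.set_xlim(0, 100)


def _runs(vals):
    vals = sorted(vals)
    if not vals:
        return []
    out, start, prev = [], vals[0], vals[0]
    for v in vals[1:]:
        if v - prev > 1.5:
            out.append((start, prev))
            start = v
        prev = v
    out.append((start, prev))
    return out


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    for qty, label in QUANTITIES:
        fig, axes = plt.subplots(2, 2, figsize=(10, 7), constrained_layout=True)
        for ax, structure in zip(axes.ravel(), STRUCTURES):
            path = ROOT / "cohort" / f"envelope_{structure}_{qty}.csv"
            if not path.exists():
                ax.set_visible(False)
                continue
            plot_envelope(ax, pd.read_csv(path), label)
            ax.set_title(structure.replace("_", " "))
        axes[0, 0].legend(loc="best", fontsize=8)
        out = FIG / f"envelope_{qty}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        print(f"wrote {out}")

    lengths = pd.read_csv(ROOT / "cohort" / "length_table.csv", index_col=[0, 1])
    print("\nCohort centerline length summary (mm):")
    print(lengths.round(3).to_string())


if __name__ == "__main__":
    main()
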