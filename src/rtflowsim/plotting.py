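"""Figures for the workflow-control sweep (box-plot style summaries)."""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_KPIS = {
    "mean_wt": "Average waiting time (days)",
    "breaches": "Patients breaching WT target / year",
    "rebooks": "First fraction rebooks / year",
}


def plot_sweep(df, outdir) -> list:
    """One figure per KPI: mean with 95% CI band and min/max whiskers
    against the realised pull fraction."""
    outdir = pathlib.Path(outdir)
    paths = []
    x = df["pull_fraction"] * 100.0
    for col, label in _KPIS.items():
        if col not in df:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(x, df[col], "o-", color="black", lw=1)
        lo, hi = f"{col}_ci_low", f"{col}_ci_high"
        if lo in df and hi in df:
            ax.fill_between(x, df[lo], df[hi], color="grey", alpha=0.5,
                            label="95% CI")
        mn, mx = f"{col}_min", f"{col}_max"
        if mn in df and mx in df:
            ax.vlines(x, df[mn], df[mx], color="grey", lw=0.8)
        ax.set_xlabel("Pull patients (%)")
        ax.set_ylabel(label)
        if ax.get_legend_handles_labels()[0]:
            ax.legend(loc="best")
        fig.tight_layout()
        path = outdir / f"sweep_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
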