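"""Basic figures: endotype mean-trend bands and a Fine-Gray forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trend_bands", "plot_forest"]

_COLORS = {
    "Non-improvers": "tab:red",
    "Decliners": "goldenrod",
    "Improvers": "navy",
    "High expressors": "deepskyblue",
}


def plot_trend_bands(bands, path=None, reference_interval=None):
    """Mean mHLA-DR trend per endotype with 95% confidence bands.

    ``bands`` maps endotype -> TrendBand (or a dict with times/mean/lo95/hi95).
    ``reference_interval`` optionally shades a healthy-volunteer band (lo, hi)
    in AB/C; no default is built in.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if reference_interval is not None:
        ax.axhspan(*reference_interval, color="palegreen", alpha=0.4, zorder=0)
    for name, band in bands.items():
        times = np.asarray(band["times"] if isinstance(band, dict) else band.times)
        mean = np.asarray(band["mean"] if isinstance(band, dict) else band.mean)
        lo = np.asarray(band["lo95"] if isinstance(band, dict) else band.lo95)
        hi = np.asarray(band["hi95"] if isinstance(band, dict) else band.hi95)
        color = _COLORS.get(name)
        ax.plot(times, mean, label=name, color=color)
        ax.fill_between(times, lo, hi, alpha=0.25, color=color)
    ax.set_xlabel("Day after inclusion")
    ax.set_ylabel("mHLA-DR (AB/C)")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_forest(shr_table, path=None, reference="Non-improvers"):
    """Forest plot of subdistribution hazard ratios vs the reference endotype.

    ``shr_table`` is the DataFrame produced by ``outcome_report`` (columns
    event, endotype, shr, ci_lo, ci_hi, p, separation).
    """
    rows = shr_table.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(rows), 2) + 1))
    ylabels = []
    for i, row in rows.iterrows():
        y = len(rows) - 1 - i
        ylabels.append(f"{row.event}: {row.endotype}")
        if row.separation or not np.isfinite(row.shr) or row.shr <= 0:
            ax.annotate("sHR 0 (no events)", (0.02, y), fontsize=8, va="center")
            continue
        ax.plot([row.ci_lo, row.ci_hi], [y, y], color="black", lw=1)
        ax.plot(row.shr, y, "o", color="black", ms=4)
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(reversed(ylabels), fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel(f"sHR vs {reference} (log scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
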