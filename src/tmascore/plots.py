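"""Plot helpers: Bland–Altman plots and IHC score histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .agreement import BlandAltmanResult

__all__ = ["plot_bland_altman", "plot_score_histograms"]


def plot_bland_altman(result: BlandAltmanResult, path, title: str = "") -> None:
    """Scatter of per-spot (mean, difference) with bias and 95% limits."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, color="black")
    for y, style in ((result.bias, "-"), (result.loa_lower, "--"), (result.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="grey")
    ax.set_xlabel("mean of the two measurements (% positive)")
    ax.set_ylabel("difference (% positive)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)


def plot_score_histograms(hist: pd.DataFrame, path, score: str = "allred_total") -> None:
    """Grouped bar chart of score totals per mask source."""
    sub = hist[hist["score"] == score]
    fig, ax = plt.subplots(figsize=(6, 4))
    sources = sorted(sub["source"].unique())
    totals = sorted(sub["total"].unique())
    width = 0.8 / max(len(sources), 1)
    for j, source in enumerate(sources):
        s = sub[sub["source"] == source].set_index("total")["count"]
        ax.bar(
            [t + j * width for t in totals],
            [s.get(t, 0) for t in totals],
            width=width,
            label=source,
        )
    ax.set_xlabel(score.replace("_", " "))
    ax.set_ylabel("number of spots")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path))
    plt.close(fig)
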