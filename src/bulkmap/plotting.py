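"""Manhattan-style window plots for the bulked-segregant scan."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def manhattan(windows, thresholds=None, path=None, figsize=(10, 5)):
    """Two stacked tracks: window-mean delta(SNP-index) and ED^2.

    Windows are laid out on a concatenated genome axis with alternating
    chromosome shading; horizontal lines mark the 95% and 99% thresholds
    (medians when thresholds are per-window).
    """
    win = windows.dropna(subset=["mean_delta"]).copy()
    chroms = list(dict.fromkeys(windows["chrom"]))
    offsets, offset = {}, 0
    for chrom in chroms:
        offsets[chrom] = offset
        sub = windows[windows["chrom"] == chrom]
        offset += int(sub["end"].max()) if len(sub) else 0
    mid = win["start"].to_numpy() + (win["end"] - win["start"]).to_numpy() / 2
    x = mid + np.array([offsets[c] for c in win["chrom"]])
    colors = np.array(["#1f77b4", "#ff7f0e"])[
        [chroms.index(c) % 2 for c in win["chrom"]]]

    fig, axes = plt.subplots(2, 1, figsize=figsize, sharex=True)
    axes[0].scatter(x, win["mean_delta"], s=6, c=colors)
    axes[0].set_ylabel(r"window mean $\Delta$(SNP-index)")
    axes[1].scatter(x, win["mean_ed2"], s=6, c=colors)
    axes[1].set_ylabel(r"window mean ED$^2$")
    if thresholds is not None:
        for q, style in (("thr95", "--"), ("thr99", "-")):
            thr = np.asarray(thresholds[q], dtype=float)
            level = float(thr) if thr.ndim == 0 else float(np.nanmedian(thr))
            axes[0].axhline(level, ls=style, lw=0.8, color="k")
    ticks = [offsets[c] + windows[windows["chrom"] == c]["end"].max() / 2
             for c in chroms]
    axes[1].set_xticks(ticks)
    axes[1].set_xticklabels(chroms, rotation=45, fontsize=8)
    axes[1].set_xlabel("genome position")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
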