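"""Optional figures: coverage-ratio tracks and expression-ratio boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import RatioTrack


def plot_ratio_track(track: RatioTrack, path: str | Path,
                     classes: pd.DataFrame | None = None) -> Path:
    """Per-chromosome male:female log2 coverage ratio with its LOESS curve."""
    windows = track.windows
    chroms = list(dict.fromkeys(windows["chrom"]))
    ncol = min(5, len(chroms))
    nrow = int(np.ceil(len(chroms) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             sharey=True, squeeze=False)
    labels = {} if classes is None else dict(zip(classes["chrom"], classes["label"]))
    for ax, chrom in zip(axes.flat, chroms):
        grp = windows[windows["chrom"] == chrom].sort_values("midpoint")
        ax.scatter(grp["midpoint"] / 1e6, grp["log2_ratio"], s=3, alpha=0.4)
        if "smoothed_log2" in grp:
            ax.plot(grp["midpoint"] / 1e6, grp["smoothed_log2"], color="crimson", lw=1.5)
        ax.axhline(0, color="gray", lw=0.5)
        ax.axhline(-1, color="gray", lw=0.5, ls="--")
        title = chrom if chrom not in labels else f"{chrom} ({labels[chrom]})"
        ax.set_title(title, fontsize=8)
    for ax in axes.flat[len(chroms):]:
        ax.axis("off")
    fig.supxlabel("position (Mb)")
    fig.supylabel("log2 M:F coverage ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_fm_boxplots(ratios_by_tissue: dict[str, pd.DataFrame],
                     path: str | Path) -> Path:
    """Boxplots of per-gene log2 F:M ratios on autosomes vs the X, per tissue."""
    tissues = list(ratios_by_tissue)
    fig, axes = plt.subplots(1, len(tissues), figsize=(2.4 * len(tissues), 3.2),
                             sharey=True, squeeze=False)
    for ax, tissue in zip(axes.flat, tissues):
        df = ratios_by_tissue[tissue]
        data = [
            np.log2(df.loc[df["chrom_class"] == "autosome", "fm_ratio"]),
            np.log2(df.loc[df["chrom_class"] == "X", "fm_ratio"]),
        ]
        ax.boxplot(data, tick_labels=["A", "X"], showfliers=False)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_title(tissue, fontsize=9)
    axes.flat[0].set_ylabel("log2 F:M expression ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
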