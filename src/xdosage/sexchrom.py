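"""X-chromosome identification from male:female windowed coverage ratios.

In an XX/XO species the male carries one X copy, so at matched sequencing
effort the male:female depth ratio sits near 0.5 on the X and near 1 on
autosomes. Chromosomes are classified by the median of their per-window
ratios falling in configurable bands around those two values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import ConfigError, ValidationError, logger
from .containers import RatioTrack, validate_coverage

X_BAND_DEFAULT = (0.35, 0.65)
AUTO_BAND_DEFAULT = (0.8, 1.2)


def compute_window_ratios(
    coverage: pd.DataFrame,
    min_depth: float = 5.0,
    normalize_libsize: bool = False,
) -> RatioTrack:
    """Per-window male/female depth ratios with depth filtering.

    Windows with female depth below ``min_depth`` or male depth of zero are
    dropped (and counted). With ``normalize_libsize`` the provisional ratios
    are divided by their genome-wide median, so unequal total sequencing
    depth between the sexes does not shift the classification bands; the
    divisor is recorded as ``scale_factor``.
    """
    cov = validate_coverage(coverage)
    keep = (cov["depth_female"] >= min_depth) & (cov["depth_male"] > 0)
    n_dropped = int((~keep).sum())
    cov = cov[keep]
    if cov.empty:
        raise ValidationError("no informative windows after depth filtering")

    ratio = cov["depth_male"].to_numpy() / cov["depth_female"].to_numpy()
    scale = 1.0
    if normalize_libsize:
        scale = float(np.median(ratio))
        if scale <= 0:
            raise ValidationError("cannot scale: median window ratio is not positive")
        ratio = ratio / scale

    windows = pd.DataFrame(
        {
            "chrom": cov["chrom"].to_numpy(),
            "midpoint": (cov["start"].to_numpy() + cov["end"].to_numpy()) / 2.0,
            "depth_male": cov["depth_male"].to_numpy(),
            "depth_female": cov["depth_female"].to_numpy(),
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
        }
    )
    return RatioTrack(windows=windows, n_dropped=n_dropped, scale_factor=scale)


def _loess_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local linear regression with tricube weights over span-nearest points.

    Degree 1, no robustness iterations. At each target point the bandwidth
    is the distance to the k-th nearest neighbour, k = ceil(span * n).
    """
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            fitted[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            fitted[i] = ym
            continue
        beta = (w * (x - xm) * (y - ym)).sum() / sxx
        fitted[i] = ym + beta * (x[i] - xm)
    return fitted


def loess_smooth(track: RatioTrack, span: float = 0.3) -> RatioTrack:
    """Add a smoothed_log2 column, smoothing each chromosome independently.

    Chromosomes with fewer than 3 retained windows copy the raw log2 ratio,
    with a warning. Smoothing is for visualization only and never feeds the
    classifier.
    """
    if not 0.0 < span <= 1.0:
        raise ConfigError("span must be in (0, 1]")
    windows = track.windows.copy()
    smoothed = np.empty(len(windows))
    for chrom, grp in windows.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(grp) < 3:
            warnings.warn(f"chromosome {chrom} has < 3 windows; smoothing skipped")
            smoothed[windows.index.get_indexer(idx)] = grp["log2_ratio"].to_numpy()
            continue
        order = np.argsort(grp["midpoint"].to_numpy(), kind="mergesort")
        x = grp["midpoint"].to_numpy()[order]
        y = grp["log2_ratio"].to_numpy()[order]
        vals = _loess_fit(x, y, span)
        fit = np.empty_like(vals)
        fit[order] = vals
        smoothed[windows.index.get_indexer(idx)] = fit
    windows["smoothed_log2"] = smoothed
    return RatioTrack(
        windows=windows, n_dropped=track.n_dropped, scale_factor=track.scale_factor
    )


def classify_chromosomes(
    track: RatioTrack,
    x_band: tuple[float, float] = X_BAND_DEFAULT,
    auto_band: tuple[float, float] = AUTO_BAND_DEFAULT,
    min_windows: int = 5,
) -> pd.DataFrame:
    """Label chromosomes X / autosome / unassigned by median window ratio.

    A chromosome is X if its median ratio falls in ``x_band``, autosome if
    in ``auto_band``, else unassigned; chromosomes with fewer than
    ``min_windows`` retained windows are unassigned regardless.
    """
    if max(x_band[0], auto_band[0]) <= min(x_band[1], auto_band[1]):
        raise ConfigError("x_band and auto_band must be disjoint")
    rows = []
    for chrom, grp in track.windows.groupby("chrom", sort=False):
        med = float(grp["ratio"].median())
        n = len(grp)
        if n < min_windows:
            label = "unassigned"
        elif x_band[0] <= med <= x_band[1]:
            label = "X"
        elif auto_band[0] <= med <= auto_band[1]:
            label = "autosome"
        else:
            label = "unassigned"
        rows.append((chrom, n, med, label))
    out = pd.DataFrame(rows, columns=["chrom", "n_windows_used", "median_ratio", "label"])
    n_x = (out["label"] == "X").sum()
    logger.info("classified %d chromosomes: %d X, %d autosome, %d unassigned",
                len(out), n_x, (out["label"] == "autosome").sum(),
                (out["label"] == "unassigned").sum())
    return out


def class_map(classification: pd.DataFrame) -> pd.Series:
    """chrom -> label Series from a classification table."""
    return classification.set_index("chrom")["label"]
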