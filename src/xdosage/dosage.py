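"""Dosage-compensation statistics.

Per tissue: Wilcoxon rank-sum comparisons of log2(FPKM) between the X and
autosomes within each sex and between the sexes within each chromosome
class; X:A ratios (median X expression over median autosomal expression per
sex); the distribution of per-gene F:M expression ratios per class; and a
qualitative compensation-status call.

The "median F:M ratio" is the median of per-gene ratios (a distribution
that supports a rank test), not the ratio of medians; the latter is also
emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigError, ValidationError
from .containers import TissueExpression
from .norm import FPKM_FLOOR_DEFAULT, log_fpkm

STATUSES = ("complete_with_balance", "complete_unbalanced", "partial", "absent")


def wilcoxon_rank_sum(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    mode "auto" uses exact enumeration when min(n_x, n_y) <= 8 and the data
    are tie-free, otherwise the normal approximation with tie-corrected
    variance and continuity correction. Symmetric in group swap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ConfigError(f"unknown mode: {mode!r}")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def xa_ratio(
    tissue_expr: TissueExpression, gene_labels: pd.Series, sex: str
) -> float:
    """Median FPKM of retained X genes over median of retained autosomal genes.

    ``gene_labels`` maps gene_id to chromosome class ("X" / "autosome" /
    "unassigned"); unassigned genes enter neither median.
    """
    if sex not in ("F", "M"):
        raise ConfigError("sex must be F or M")
    frame = tissue_expr.retained()
    labels = gene_labels.reindex(frame.index).fillna("unassigned")
    ratio = xa_ratio_from_frame(frame, labels, sex)
    if np.isnan(ratio):
        warnings.warn(f"tissue {tissue_expr.tissue}: empty X or autosome class")
    return ratio


def gene_class_labels(gene_chrom: pd.Series, classification: pd.Series) -> pd.Series:
    """Compose gene -> chrom and chrom -> label into gene -> class label."""
    return gene_chrom.map(classification).fillna("unassigned")


@dataclass
class FMRatios:
    """Per-gene F:M expression ratios split by chromosome class."""

    ratios: pd.DataFrame  # index gene_id; columns fm_ratio, chrom_class
    median_x: float
    median_autosome: float
    wilcoxon_p: float  # X vs autosome ratio distributions


def fm_ratio_distribution(
    tissue_expr: TissueExpression,
    gene_labels: pd.Series,
    floor: float = FPKM_FLOOR_DEFAULT,
) -> FMRatios:
    """Per-gene female:male FPKM ratios and their class medians.

    Zeros are floored at the pseudo-FPKM floor so ratios stay finite; the
    X and autosome ratio distributions are compared by Wilcoxon rank-sum.
    """
    frame = tissue_expr.retained()
    labels = gene_labels.reindex(frame.index).fillna("unassigned")
    f = np.maximum(frame["mean_F"].to_numpy(dtype=float), floor)
    m = np.maximum(frame["mean_M"].to_numpy(dtype=float), floor)
    ratios = pd.DataFrame(
        {"fm_ratio": f / m, "chrom_class": labels.to_numpy()}, index=frame.index
    )
    x = ratios.loc[ratios["chrom_class"] == "X", "fm_ratio"]
    a = ratios.loc[ratios["chrom_class"] == "autosome", "fm_ratio"]
    if len(x) == 0 or len(a) == 0:
        warnings.warn(f"tissue {tissue_expr.tissue}: empty class in F:M comparison")
        return FMRatios(ratios, float(np.median(x)) if len(x) else np.nan,
                        float(np.median(a)) if len(a) else np.nan, np.nan)
    _, p = wilcoxon_rank_sum(x, a)
    return FMRatios(ratios, float(np.median(x)), float(np.median(a)), p)


def classify_status(
    fm_x_median: float,
    male_xa: float,
    delta: float = 0.15,
    eps: float = 0.15,
) -> str:
    """Qualitative compensation status from the two headline ratios.

    complete_with_balance: F:M on X within delta of 1 and male X:A within
    eps of 1; complete_unbalanced: F:M balanced but male X:A outside its
    band; absent: F:M on X at or above 2 - delta (the uncompensated
    two-copy:one-copy expectation); partial: everything else.
    """
    if np.isnan(fm_x_median) or np.isnan(male_xa):
        return "partial"
    if 1 - delta <= fm_x_median <= 1 + delta:
        if 1 - eps <= male_xa <= 1 + eps:
            return "complete_with_balance"
        return "complete_unbalanced"
    if fm_x_median >= 2 - delta:
        return "absent"
    return "partial"


def dosage_report(
    tissue_exprs: dict[str, TissueExpression],
    gene_labels: pd.Series,
    delta: float = 0.15,
    eps: float = 0.15,
    floor: float = FPKM_FLOOR_DEFAULT,
) -> pd.DataFrame:
    """Assemble the per-tissue dosage-compensation report.

    One row per tissue with gene counts, Wilcoxon p-values for X-vs-A
    within each sex (on log2 FPKM) and F-vs-M within each class, X:A ratios
    per sex, F:M ratio medians per class (median of per-gene ratios, plus
    the ratio-of-medians variant), and the status call.
    """
    rows = []
    for tissue, texpr in tissue_exprs.items():
        frame = texpr.retained()
        if frame["mean_F"].isna().all() or frame["mean_M"].isna().all():
            warnings.warn(f"tissue {tissue} lacks one sex; skipped")
            continue
        labels = gene_labels.reindex(frame.index).fillna("unassigned")
        on_x = labels == "X"
        on_a = labels == "autosome"
        if not on_x.any() or not on_a.any():
            warnings.warn(f"tissue {tissue}: empty X or autosome class; skipped")
            continue
        lf = {cls: log_fpkm(frame.loc[mask, "mean_F"], floor)
              for cls, mask in (("X", on_x), ("A", on_a))}
        lm = {cls: log_fpkm(frame.loc[mask, "mean_M"], floor)
              for cls, mask in (("X", on_x), ("A", on_a))}

        _, p_xa_f = wilcoxon_rank_sum(lf["X"], lf["A"])
        _, p_xa_m = wilcoxon_rank_sum(lm["X"], lm["A"])
        _, p_fm_x = wilcoxon_rank_sum(lf["X"], lm["X"])
        _, p_fm_a = wilcoxon_rank_sum(lf["A"], lm["A"])

        xa_f = xa_ratio_from_frame(frame, labels, "F")
        xa_m = xa_ratio_from_frame(frame, labels, "M")
        fm = fm_ratio_distribution(texpr, gene_labels, floor)

        # ratio-of-medians variant of the F:M summary, for transparency
        med = lambda s: float(np.median(np.maximum(s.to_numpy(dtype=float), floor)))
        fm_x_rom = med(frame.loc[on_x, "mean_F"]) / med(frame.loc[on_x, "mean_M"])
        fm_a_rom = med(frame.loc[on_a, "mean_F"]) / med(frame.loc[on_a, "mean_M"])

        status = classify_status(fm.median_x, xa_m, delta=delta, eps=eps)
        rows.append({
            "tissue": tissue,
            "n_genes_x": int(on_x.sum()),
            "n_genes_autosome": int(on_a.sum()),
            "p_x_vs_a_female": p_xa_f,
            "p_x_vs_a_male": p_xa_m,
            "p_f_vs_m_x": p_fm_x,
            "p_f_vs_m_autosome": p_fm_a,
            "xa_ratio_female": xa_f,
            "xa_ratio_male": xa_m,
            "fm_median_x": fm.median_x,
            "fm_median_autosome": fm.median_autosome,
            "fm_median_x_ratio_of_medians": fm_x_rom,
            "fm_median_autosome_ratio_of_medians": fm_a_rom,
            "p_fm_x_vs_autosome": fm.wilcoxon_p,
            "status": status,
        })
    if not rows:
        raise ValidationError("no tissue with both sexes and both chromosome classes")
    return pd.DataFrame(rows)


def xa_ratio_from_frame(frame: pd.DataFrame, labels: pd.Series, sex: str) -> float:
    col = f"mean_{sex}"
    x_vals = frame.loc[labels == "X", col]
    a_vals = frame.loc[labels == "autosome", col]
    if len(x_vals) == 0 or len(a_vals) == 0:
        return float("nan")
    return float(np.median(x_vals) / np.median(a_vals))
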