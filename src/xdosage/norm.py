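"""Expression normalization: TMM scaling, FPKM, replicate averaging and QC.

The dosage statistics consume a TMM-scaled FPKM matrix filtered to genes
expressed (mean FPKM >= 1) in at least one sex per tissue. TMM follows the
published trimmed-mean-of-M-values definition: a reference sample chosen by
upper-quartile count fraction, log-ratio (M) and abundance (A) double
trimming, and a precision-weighted mean of the surviving M values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigError, ValidationError, logger
from .containers import CountMatrix, TissueExpression

FPKM_FLOOR_DEFAULT = 0.01


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to product 1.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean of those fractions. For each sample, genes with a
    zero count in either the sample or the reference are excluded; the top
    and bottom ``trim_m`` of M values and ``trim_a`` of A values are
    trimmed; the factor is 2 to the precision-weighted mean of the
    remaining M values.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    y = mat.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    frac = y / lib
    f75 = np.array([np.quantile(frac[:, j][y[:, j] > 0], 0.75) if (y[:, j] > 0).any()
                    else 0.0 for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(y.shape[1])
    yr, lr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, lj = y[:, j], lib[j]
        use = (yj > 0) & (yr > 0)
        if not use.any():
            warnings.warn(
                f"sample {mat.columns[j]} shares no expressed genes with the "
                "TMM reference; factor set to 1"
            )
            continue
        pj, pr = yj[use] / lj, yr[use] / lr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic (binomial) variance of M: precision weights
        v = (lj - yj[use]) / (lj * yj[use]) + (lr - yr[use]) / (lr * yr[use])

        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        with np.errstate(divide="ignore"):
            w = 1.0 / v[keep]
        log_factors[j] = float((w * m[keep]).sum() / w.sum())

    log_factors -= log_factors.mean()  # product of factors = 1
    return pd.Series(2.0 ** log_factors, index=mat.columns, name="tmm_factor")


@dataclass
class ExpressionMatrix:
    """FPKM matrix with the TMM factors and effective library sizes behind it."""

    fpkm: pd.DataFrame
    tmm_factors: pd.Series
    effective_libsizes: pd.Series
    samples: pd.DataFrame


def compute_fpkm(counts: CountMatrix, tmm: bool = True) -> ExpressionMatrix:
    """FPKM_gs = count_gs / (exonic_length_g/1e3 * L_s/1e6).

    With ``tmm`` the raw column sum L_s is replaced by the TMM-effective
    library size (column sum x TMM factor).
    """
    counts.validate()
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    if tmm:
        factors = tmm_factors(counts)
    else:
        factors = pd.Series(1.0, index=counts.counts.columns, name="tmm_factor")
    eff = lib * factors
    len_kb = counts.gene_lengths.to_numpy(dtype=float) / 1e3
    fpkm = counts.counts.to_numpy(dtype=float) / (
        len_kb[:, None] * (eff.to_numpy() / 1e6)[None, :]
    )
    return ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns),
        tmm_factors=factors,
        effective_libsizes=eff.rename("effective_libsize"),
        samples=counts.samples,
    )


def average_replicates(expr: ExpressionMatrix) -> dict[str, TissueExpression]:
    """Arithmetic mean FPKM over replicates within each (tissue, sex).

    Returns one TissueExpression per tissue with mean_F / mean_M columns;
    tissues lacking a sex get NaN for that column.
    """
    out: dict[str, TissueExpression] = {}
    meta = expr.samples
    for tissue, tgroup in meta.groupby("tissue", sort=False):
        frame = pd.DataFrame(index=expr.fpkm.index)
        for sex in ("F", "M"):
            cols = tgroup.loc[tgroup["sex"] == sex, "sample_id"].tolist()
            frame[f"mean_{sex}"] = expr.fpkm[cols].mean(axis=1) if cols else np.nan
        frame["retained"] = True
        out[tissue] = TissueExpression(tissue=tissue, frame=frame)
    return out


def filter_expressed(
    tissue_expr: TissueExpression,
    threshold: float = 1.0,
    rule: str = "both_below",
) -> TissueExpression:
    """Flag lowly expressed genes per tissue.

    ``both_below`` (default) removes a gene only when its mean FPKM is below
    the threshold in both sexes, keeping genes expressed in at least one
    sex; ``either_below`` removes it when either sex is below.
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    if rule not in ("both_below", "either_below"):
        raise ConfigError(f"unknown filter rule: {rule!r}")
    frame = tissue_expr.frame.copy()
    below_f = frame["mean_F"] < threshold
    below_m = frame["mean_M"] < threshold
    removed = (below_f & below_m) if rule == "both_below" else (below_f | below_m)
    frame["retained"] = ~removed
    logger.info("tissue %s: %d/%d genes retained by FPKM filter",
                tissue_expr.tissue, int(frame["retained"].sum()), len(frame))
    return TissueExpression(
        tissue=tissue_expr.tissue, frame=frame,
        filter_threshold=threshold, filter_rule=rule,
    )


def log_fpkm(values: np.ndarray | pd.Series, floor: float = FPKM_FLOOR_DEFAULT) -> np.ndarray:
    """log2(FPKM) with a pseudo-FPKM floor so zeros stay finite."""
    v = np.asarray(values, dtype=float)
    return np.log2(np.maximum(v, floor))


def spearman_replicates(counts: CountMatrix) -> pd.DataFrame:
    """Spearman rank correlation between replicate pairs within (tissue, sex).

    Computed on raw counts with average ranks for ties; a constant column
    makes the correlation undefined and is reported as NaN with a warning.
    """
    rows = []
    meta = counts.samples
    for (tissue, sex), grp in meta.groupby(["tissue", "sex"], sort=False):
        ids = grp["sample_id"].tolist()
        for a, b in itertools.combinations(ids, 2):
            xa, xb = counts.counts[a], counts.counts[b]
            if xa.nunique() == 1 or xb.nunique() == 1:
                warnings.warn(f"constant counts in {a} or {b}; Spearman undefined")
                rho = np.nan
            else:
                rho = float(stats.spearmanr(xa, xb).statistic)
            rows.append((tissue, sex, a, b, rho))
    return pd.DataFrame(rows, columns=["tissue", "sex", "sample_a", "sample_b", "rho"])
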