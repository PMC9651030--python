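"""Sex-biased gene calling and X-vs-autosome enrichment.

Counts are compared female vs male per tissue under a negative-binomial
model. Replicated designs use per-gene moment dispersion estimates shrunk
toward the common dispersion and a likelihood-ratio test of a one-
coefficient log-linear model with library-size offsets; unreplicated
designs fix the dispersion at BCV^2 = 0.2^2 and use the exact conditional
NB test. Genes with |log2 FC| > 2 (female over male) at FDR < 0.05 are
called sex-biased, and their chromosomal distribution is tested with
Fisher's exact test on a biased/unbiased x X/autosome contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._utils import ConfigError, ValidationError, logger
from .containers import CountMatrix

BCV_DEFAULT = 0.2
DISPERSION_FLOOR = 1e-4
PRIOR_DF = 10.0  # prior degrees of freedom for dispersion shrinkage
PRIOR_COUNT = 0.5  # logFC prior count, scaled by relative library size


# ---------------------------------------------------------------------------
# CPM and filtering

def cpm(counts: CountMatrix | pd.DataFrame,
        tmm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / (library size * TMM factor)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    if tmm_factors is not None:
        lib = lib * tmm_factors.reindex(mat.columns)
    return mat / lib * 1e6


def cpm_filter(
    cpm_mat: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = 1.0,
    design: str = "replicated",
) -> pd.Series:
    """Boolean retention mask from the CPM expression filter.

    Replicated design: keep a gene when CPM exceeds the threshold in every
    replicate of at least one sex. Unreplicated design: keep when CPM
    exceeds the threshold in at least one of the two samples (requiring
    both would discard sex-limited genes).
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    if design not in ("replicated", "unreplicated"):
        raise ConfigError(f"unknown design: {design!r}")
    if design == "replicated":
        keep = pd.Series(False, index=cpm_mat.index)
        for sex in ("F", "M"):
            cols = samples.loc[samples["sex"] == sex, "sample_id"].tolist()
            if cols:
                keep |= (cpm_mat[cols] > threshold).all(axis=1)
        return keep
    return (cpm_mat > threshold).any(axis=1)


# ---------------------------------------------------------------------------
# dispersion

def estimate_dispersion(
    counts: CountMatrix,
    design: str = "replicated",
    bcv: float = BCV_DEFAULT,
    prior_df: float = PRIOR_DF,
) -> pd.Series:
    """Per-gene NB dispersion.

    Unreplicated: fixed at bcv^2 for every gene. Replicated: method-of-
    moments on counts scaled to a common library size within each sex,
    pooled across sexes, then shrunk toward the median (common) dispersion
    with weight n / (n + prior_df) where n is the residual degrees of
    freedom; floored at 1e-4.
    """
    mat = counts.counts
    if design == "unreplicated":
        return pd.Series(bcv ** 2, index=mat.index, name="dispersion")
    if design != "replicated":
        raise ConfigError(f"unknown design: {design!r}")

    meta = counts.samples
    groups = []
    for sex in ("F", "M"):
        cols = meta.loc[meta["sex"] == sex, "sample_id"].tolist()
        if len(cols) >= 2:
            groups.append(cols)
    if not groups:
        warnings.warn("replicated design without replicated groups; using fixed BCV")
        return pd.Series(bcv ** 2, index=mat.index, name="dispersion")

    lib = mat.sum(axis=0).astype(float)
    lbar = float(lib.mean())
    num = np.zeros(len(mat))
    df = 0
    for cols in groups:
        z = mat[cols].to_numpy(dtype=float) * (lbar / lib[cols].to_numpy())[None, :]
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / m ** 2, 0.0)
        num += phi * (len(cols) - 1)
        df += len(cols) - 1
    phi_raw = num / df
    common = float(np.median(phi_raw))
    w = df / (df + prior_df)
    phi_shrunk = w * phi_raw + (1 - w) * common
    return pd.Series(np.maximum(phi_shrunk, DISPERSION_FLOOR),
                     index=mat.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB two-group tests

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson limit at phi == 0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mu.shape)
    out = np.empty(mu.shape)
    poisson = phi <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            poisson,
            y * np.log(np.maximum(mu, 1e-300)) - mu - special.gammaln(y + 1),
            0.0,
        )
        r = 1.0 / np.maximum(phi, 1e-300)
        nb = (
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(np.maximum(mu, 1e-300) / (r + mu))
        )
        out = np.where(poisson, out, nb)
    return out.sum(axis=1)


def _fit_nb_mean(y: np.ndarray, lib: np.ndarray, phi: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Per-gene MLE of the rate m in mean_gs = m_g * L_s at fixed dispersion.

    Fisher scoring on beta = log m, vectorized over genes. Genes with all
    zero counts get m = 0.
    """
    y = np.asarray(y, dtype=float)
    lib = np.asarray(lib, dtype=float)
    total = y.sum(axis=1)
    nonzero = total > 0
    m = np.where(nonzero, total / lib.sum(), 0.0)
    beta = np.log(np.where(nonzero, m, 1.0))
    phi_col = np.asarray(phi, dtype=float)[:, None]
    for _ in range(max_iter):
        mu = np.exp(beta)[:, None] * lib[None, :]
        denom = 1.0 + phi_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(nonzero & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return np.where(nonzero, np.exp(beta), 0.0)


def _log_fold_change(yf: np.ndarray, ym: np.ndarray, lib_f: np.ndarray,
                     lib_m: np.ndarray, prior_count: float = PRIOR_COUNT) -> np.ndarray:
    """log2 mean CPM_F / mean CPM_M with library-size-scaled prior counts."""
    all_lib = np.concatenate([lib_f, lib_m])
    prior = prior_count * all_lib / all_lib.mean()
    pf, pm = prior[: len(lib_f)], prior[len(lib_f):]
    cpm_f = (yf + pf[None, :]) / (lib_f + 2 * pf)[None, :] * 1e6
    cpm_m = (ym + pm[None, :]) / (lib_m + 2 * pm)[None, :] * 1e6
    return np.log2(cpm_f.mean(axis=1) / cpm_m.mean(axis=1))


def _exact_conditional_p(sa: int, t: int, r_a: float, r_b: float) -> float:
    """Two-sided exact conditional NB p-value.

    Conditional on the total t, the group-A sum follows a negative
    hypergeometric law with shape parameters r_a = n_a/phi and r_b = n_b/phi
    (binomial in the Poisson limit). Two-sided p sums the probabilities of
    all outcomes no more likely than the observed one.
    """
    a = np.arange(t + 1)
    if not np.isfinite(r_a) or not np.isfinite(r_b):
        logp = stats.binom.logpmf(a, t, 0.5)
    else:
        logp = (
            special.gammaln(a + r_a) - special.gammaln(a + 1) - special.gammaln(r_a)
            + special.gammaln(t - a + r_b) - special.gammaln(t - a + 1)
            - special.gammaln(r_b)
        )
        logp -= special.logsumexp(logp)
    p_obs = logp[sa]
    return float(min(np.exp(special.logsumexp(logp[logp <= p_obs + 1e-10])), 1.0))


def nb_two_group_test(
    counts_f: pd.DataFrame,
    counts_m: pd.DataFrame,
    libsizes: pd.Series,
    dispersion: pd.Series,
    method: str = "lrt",
) -> pd.DataFrame:
    """Female-vs-male NB test per gene at fixed dispersion.

    method "lrt": NB means fitted per sex by maximum likelihood with log
    link and library-size offsets; likelihood-ratio statistic against the
    equal-mean null referred to chi-square(1). method "exact": counts are
    moment-scaled to the mean library size and the conditional NB exact
    two-sided p computed given the total. logFC is log2 of prior-count-
    adjusted mean CPM_F over mean CPM_M in both cases.
    """
    if method not in ("lrt", "exact"):
        raise ConfigError(f"unknown method: {method!r}")
    if not counts_f.index.equals(counts_m.index):
        raise ValidationError("female and male count tables must share gene index")
    yf = counts_f.to_numpy(dtype=float)
    ym = counts_m.to_numpy(dtype=float)
    lib_f = libsizes.reindex(counts_f.columns).to_numpy(dtype=float)
    lib_m = libsizes.reindex(counts_m.columns).to_numpy(dtype=float)
    phi = dispersion.reindex(counts_f.index).to_numpy(dtype=float)
    if (phi < 0).any():
        raise ValidationError("dispersion must be >= 0")

    logfc = _log_fold_change(yf, ym, lib_f, lib_m)
    all_zero = (yf.sum(axis=1) + ym.sum(axis=1)) == 0
    logfc[all_zero] = 0.0

    if method == "lrt":
        y_all = np.concatenate([yf, ym], axis=1)
        lib_all = np.concatenate([lib_f, lib_m])
        m0 = _fit_nb_mean(y_all, lib_all, phi)
        mf = _fit_nb_mean(yf, lib_f, phi)
        mm = _fit_nb_mean(ym, lib_m, phi)
        ll0 = _nb_loglik(y_all, np.maximum(m0[:, None] * lib_all[None, :], 1e-300), phi)
        ll1 = (
            _nb_loglik(yf, np.maximum(mf[:, None] * lib_f[None, :], 1e-300), phi)
            + _nb_loglik(ym, np.maximum(mm[:, None] * lib_m[None, :], 1e-300), phi)
        )
        lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
        p = stats.chi2.sf(lr, df=1)
        p[all_zero] = 1.0
    else:
        lbar = float(np.concatenate([lib_f, lib_m]).mean())
        zf = yf * (lbar / lib_f)[None, :]
        zm = ym * (lbar / lib_m)[None, :]
        n_f, n_m = yf.shape[1], ym.shape[1]
        p = np.ones(len(yf))
        for g in range(len(yf)):
            if all_zero[g]:
                continue
            sa = int(round(zf[g].sum()))
            t = sa + int(round(zm[g].sum()))
            if t == 0:
                continue
            if phi[g] <= 0:
                r_a = r_b = np.inf
                # Poisson limit with unequal group sizes: binomial(t, n_f/(n_f+n_m))
                a = np.arange(t + 1)
                logp = stats.binom.logpmf(a, t, n_f / (n_f + n_m))
                p_obs = logp[min(sa, t)]
                p[g] = float(min(np.exp(
                    special.logsumexp(logp[logp <= p_obs + 1e-10])), 1.0))
            else:
                p[g] = _exact_conditional_p(
                    min(sa, t), t, n_f / phi[g], n_m / phi[g]
                )
    return pd.DataFrame({"logFC": logfc, "p": p}, index=counts_f.index)


# ---------------------------------------------------------------------------
# multiple testing and bias calls

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_sex_biased(
    results: pd.DataFrame,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Label genes female_biased / male_biased / unbiased.

    Strict inequalities: female_biased iff logFC > lfc_threshold and FDR <
    fdr_threshold; male_biased iff logFC < -lfc_threshold and FDR <
    fdr_threshold.
    """
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ConfigError("thresholds must be > 0")
    out = results.copy()
    if "FDR" not in out.columns:
        out["FDR"] = bh_adjust(out["p"].to_numpy())
    sig = out["FDR"] < fdr_threshold
    label = np.where(sig & (out["logFC"] > lfc_threshold), "female_biased",
             np.where(sig & (out["logFC"] < -lfc_threshold), "male_biased", "unbiased"))
    out["label"] = label
    return out


# ---------------------------------------------------------------------------
# enrichment

@dataclass
class EnrichmentResult:
    """2x2 Fisher test of biased/unbiased genes on X vs autosomes.

    table rows = (biased, unbiased), columns = (X, autosome); an odds ratio
    above 1 means the biased class is over-represented on the X.
    """

    direction: str
    table: np.ndarray
    odds_ratio: float
    p: float
    enriched_on: str


def fisher_enrichment(
    bias_table: pd.DataFrame,
    gene_labels: pd.Series,
    direction: str = "female",
) -> EnrichmentResult | None:
    """Fisher's exact test for enrichment of one bias direction on the X.

    Genes labeled "filtered" or on unassigned chromosomes are excluded.
    Returns None (with a warning) when a table margin is empty.
    """
    if direction not in ("female", "male"):
        raise ConfigError("direction must be 'female' or 'male'")
    target = f"{direction}_biased"
    labels = gene_labels.reindex(bias_table.index).fillna("unassigned")
    use = bias_table["label"].ne("filtered") & labels.isin(["X", "autosome"])
    sub = bias_table[use]
    on_x = labels[use] == "X"
    biased = sub["label"] == target
    a = int((biased & on_x).sum())          # biased on X
    b = int((biased & ~on_x).sum())         # biased on autosome
    c = int((~biased & on_x).sum())         # unbiased on X
    d = int((~biased & ~on_x).sum())        # unbiased on autosome
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn(f"empty margin in {direction} enrichment table")
        return None
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    enriched_on = "X" if (a * d) > (b * c) else ("autosome" if (a * d) < (b * c) else "none")
    return EnrichmentResult(direction=direction, table=table,
                            odds_ratio=float(odds), p=float(p),
                            enriched_on=enriched_on)


# ---------------------------------------------------------------------------
# per-tissue orchestration

def sex_bias_analysis(
    counts: CountMatrix,
    tissue: str,
    gene_labels: pd.Series,
    design: str | None = None,
    bcv: float = BCV_DEFAULT,
    cpm_threshold: float = 1.0,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    method: str | None = None,
    tmm: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, EnrichmentResult | None]]:
    """Run the full bias-calling workflow for one tissue.

    Infers the design from the replicate structure when not given: the LRT
    is the default test for replicated designs, the exact conditional test
    for unreplicated fixed-BCV designs. Returns the BiasTable (including
    filtered genes, labeled "filtered") and the female/male enrichment
    results.
    """
    meta = counts.samples
    sub_ids = meta.loc[meta["tissue"] == tissue, "sample_id"].tolist()
    if not sub_ids:
        raise ValidationError(f"no samples for tissue {tissue!r}")
    sub = counts.subset_samples(sub_ids)
    smeta = sub.samples
    n_f = (smeta["sex"] == "F").sum()
    n_m = (smeta["sex"] == "M").sum()
    if n_f == 0 or n_m == 0:
        raise ValidationError(f"tissue {tissue!r} lacks one sex")
    if design is None:
        design = "replicated" if min(n_f, n_m) >= 2 else "unreplicated"
    if method is None:
        method = "lrt" if design == "replicated" else "exact"

    cpm_mat = cpm(sub, tmm_factors=tmm)
    keep = cpm_filter(cpm_mat, smeta, threshold=cpm_threshold, design=design)
    logger.info("tissue %s: %d/%d genes pass CPM filter", tissue,
                int(keep.sum()), len(keep))

    kept = CountMatrix(
        counts=sub.counts[keep], samples=smeta,
        gene_lengths=sub.gene_lengths[keep],
    ).validate()
    phi = estimate_dispersion(kept, design=design, bcv=bcv)
    cols_f = smeta.loc[smeta["sex"] == "F", "sample_id"].tolist()
    cols_m = smeta.loc[smeta["sex"] == "M", "sample_id"].tolist()
    res = nb_two_group_test(
        kept.counts[cols_f], kept.counts[cols_m],
        libsizes=sub.library_sizes, dispersion=phi, method=method,
    )
    res["FDR"] = bh_adjust(res["p"].to_numpy())
    res = call_sex_biased(res, lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold)

    mean_cpm = {
        "mean_cpm_F": cpm_mat[cols_f].mean(axis=1),
        "mean_cpm_M": cpm_mat[cols_m].mean(axis=1),
    }
    full = pd.DataFrame(mean_cpm, index=sub.counts.index)
    full["chrom_class"] = gene_labels.reindex(full.index).fillna("unassigned")
    for col in ("logFC", "p", "FDR"):
        full[col] = res[col]
    full["label"] = res["label"].reindex(full.index).fillna("filtered")
    full["tissue"] = tissue

    enrich = {
        d: fisher_enrichment(full[full["label"] != "filtered"],
                             gene_labels, direction=d)
        for d in ("female", "male")
    }
    return full, enrich
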