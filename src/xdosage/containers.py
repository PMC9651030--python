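"""In-memory containers shared across the pipeline.

Coordinate conventions: gene tables are 1-based inclusive (GFF3 style),
coverage windows are 0-based half-open (BED style). Conversions happen only
at I/O boundaries; in memory each table keeps its native convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "exonic_length"]
COVERAGE_COLUMNS = ["chrom", "start", "end", "depth_male", "depth_female"]
SAMPLE_COLUMNS = ["sample_id", "tissue", "sex", "replicate"]


@dataclass
class GenomeModel:
    """Chromosome and gene annotation with ground-truth chromosome classes.

    chromosomes: DataFrame(name, length, true_class) where true_class is
    "X" or "autosome"; genes: DataFrame(gene_id, chrom, start, end,
    exonic_length) with 1-based inclusive spans.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame

    def validate(self) -> "GenomeModel":
        if (self.chromosomes["true_class"] == "X").sum() > 1:
            raise ValidationError("more than one chromosome labeled X")
        lengths = self.chromosomes.set_index("name")["length"]
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id: {dup}")
        if (g["exonic_length"] < 1).any():
            raise ValidationError("exonic_length must be >= 1")
        if (g["start"] < 1).any() or (g["end"] < g["start"]).any():
            raise ValidationError("gene spans must satisfy 1 <= start <= end")
        chrom_len = g["chrom"].map(lengths)
        if chrom_len.isna().any():
            bad = g.loc[chrom_len.isna(), "chrom"].iloc[0]
            raise ValidationError(f"gene on unknown chromosome: {bad}")
        if (g["end"] > chrom_len).any():
            raise ValidationError("gene span extends beyond its chromosome")
        return self

    @property
    def x_chromosomes(self) -> list[str]:
        mask = self.chromosomes["true_class"] == "X"
        return self.chromosomes.loc[mask, "name"].tolist()


def validate_coverage(windows: pd.DataFrame) -> pd.DataFrame:
    """Sort and validate a coverage-window table (BED-style coordinates)."""
    missing = [c for c in COVERAGE_COLUMNS if c not in windows.columns]
    if missing:
        raise ValidationError(f"coverage table missing columns: {missing}")
    w = windows.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if (w["start"] >= w["end"]).any():
        raise ValidationError("coverage windows must have start < end")
    if (w[["depth_male", "depth_female"]] < 0).to_numpy().any():
        raise ValidationError("negative depth in coverage table")
    for chrom, grp in w.groupby("chrom", sort=False):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValidationError(f"overlapping windows on {chrom}")
    return w


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_sex = set(samples["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"sex must be F or M, got {sorted(bad_sex)}")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate index must be >= 1")
    return samples.reset_index(drop=True)


@dataclass
class CountMatrix:
    """Raw gene-level counts with sample metadata and gene lengths.

    counts: genes x samples, non-negative integers; samples: metadata with
    one row per count column; gene_lengths: exonic length in bp per gene;
    gene_chrom: chromosome per gene (may be absent for pure normalization).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series
    gene_chrom: pd.Series | None = None

    def validate(self) -> "CountMatrix":
        self.samples = validate_samples(self.samples)
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            extra = set(self.counts.columns) - set(self.samples["sample_id"])
            if extra:
                raise ValidationError(f"count columns without metadata: {sorted(extra)}")
            # metadata order is canonical
            self.counts = self.counts[list(self.samples["sample_id"])]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[bad[0]]}, "
                    f"sample {self.counts.columns[bad[1]]}"
                )
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene_id in count matrix")
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValidationError("gene lengths missing for some genes")
        return self

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        samples = self.samples[self.samples["sample_id"].isin(sample_ids)]
        return CountMatrix(
            counts=self.counts[list(samples["sample_id"])].copy(),
            samples=samples.reset_index(drop=True),
            gene_lengths=self.gene_lengths.copy(),
            gene_chrom=None if self.gene_chrom is None else self.gene_chrom.copy(),
        )

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)


@dataclass
class RatioTrack:
    """Per-window male:female coverage ratios after depth filtering."""

    windows: pd.DataFrame  # chrom, midpoint, depth_male, depth_female, ratio, log2_ratio[, smoothed_log2]
    n_dropped: int = 0
    scale_factor: float = 1.0  # library-size scale divided out of the ratios


@dataclass
class TissueExpression:
    """Replicate-averaged FPKM per sex for one tissue, with retention flags."""

    tissue: str
    frame: pd.DataFrame  # index gene_id; columns mean_F, mean_M, retained
    filter_threshold: float | None = None
    filter_rule: str | None = None

    def retained(self) -> pd.DataFrame:
        return self.frame[self.frame["retained"]]
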