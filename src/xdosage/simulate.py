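"""Synthetic genomes, coverage tracks and count matrices.

The generator emulates the statistical structure the analysis assumes for an
XX (female) / XO (male) species: a 15-chromosome karyotype (14 autosomes +
one X), Poisson windowed sequencing depth with the male X at half copy
number, and negative-binomial RNA-seq counts under named dosage-compensation
regimes with a configurable fraction of sex-biased genes.

Every operation draws from its own named RNG stream derived from a single
global seed, so identical seeds give bitwise-identical outputs and adding a
simulator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ConfigError, stream_rng
from .containers import CountMatrix, GenomeModel, validate_coverage

REGIMES = ("complete_compensation", "no_compensation", "female_downregulation")

#: multiplicative effect of each regime on (female X, male X) gene means.
#: complete_compensation: the single male X is upregulated to the female
#: level; no_compensation: the male X stays at half dose;
#: female_downregulation: both female copies are downregulated so the summed
#: female output matches the single (uncompensated) male copy.
_REGIME_X_FACTORS = {
    "complete_compensation": (1.0, 1.0),
    "no_compensation": (1.0, 0.5),
    "female_downregulation": (0.5, 0.5),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for all simulators.

    Defaults mirror the emulated study: 14 autosomes + 1 X, 100-kb coverage
    windows, and per-window female depth of 100 reads.
    """

    n_autosomes: int = 14
    n_genes_per_chrom: int = 1000
    n_windows_per_chrom: int = 120
    window_size: int = 100_000
    depth_female: float = 100.0
    regime: str = "complete_compensation"
    bias_fraction_female: float = 0.0
    bias_fraction_male: float = 0.0
    bias_fold: float = 8.0
    # fraction of female-biased genes forced onto the X (None = uniform)
    bias_x_concentration: float | None = None
    dispersion_true: float = 0.1
    libsize: float = 2_000_000.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_autosomes < 0:
            raise ConfigError("n_autosomes must be >= 0")
        if self.n_genes_per_chrom < 1:
            raise ConfigError("n_genes_per_chrom must be >= 1")
        if self.n_windows_per_chrom < 1:
            raise ConfigError("n_windows_per_chrom must be >= 1")
        if self.window_size <= 0:
            raise ConfigError("window_size must be > 0")
        if self.depth_female < 0:
            raise ConfigError("depth_female must be >= 0")
        if self.regime not in REGIMES:
            raise ConfigError(
                f"regime must be one of {REGIMES}, got {self.regime!r}"
            )
        for name in ("bias_fraction_female", "bias_fraction_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.bias_fold <= 1.0:
            raise ConfigError("bias_fold must be > 1")
        if self.bias_x_concentration is not None and not (
            0.0 <= self.bias_x_concentration <= 1.0
        ):
            raise ConfigError("bias_x_concentration must be in [0, 1]")
        if self.dispersion_true < 0:
            raise ConfigError("dispersion_true must be >= 0")
        if self.libsize <= 0:
            raise ConfigError("libsize must be > 0")
        return self


@dataclass(frozen=True)
class TissuePlan:
    """One tissue in the sampling design.

    regime overrides the config-level regime for this tissue (e.g. a
    compensated soma next to an uncompensated gonad in one experiment).
    """

    tissue: str
    n_replicates: int = 2
    sexes: tuple[str, ...] = ("F", "M")
    regime: str | None = None


def simulate_genome(config: SimulationConfig) -> GenomeModel:
    """Build a genome of ``n_autosomes`` autosomes plus one X.

    Chromosome length is ``n_windows_per_chrom * window_size``. Genes are
    tiled non-overlapping, one per equal-width slot, with a lognormal exonic
    length clipped to the gene span.
    """
    config.validate()
    rng = stream_rng(config.seed, "genome")
    chrom_len = config.n_windows_per_chrom * config.window_size

    names = [f"chr{i + 1}" for i in range(config.n_autosomes)] + ["chrX"]
    classes = ["autosome"] * config.n_autosomes + ["X"]
    chromosomes = pd.DataFrame(
        {"name": names, "length": chrom_len, "true_class": classes}
    )

    rows = []
    slot = chrom_len // config.n_genes_per_chrom
    for name in names:
        for i in range(config.n_genes_per_chrom):
            start = i * slot + 1
            span = max(int(0.6 * slot), 1)
            end = min(start + span - 1, chrom_len)
            span_len = end - start + 1
            exonic = int(np.clip(rng.lognormal(mean=7.3, sigma=0.6),
                                 min(200, span_len), span_len))
            rows.append((f"{name}_g{i + 1:04d}", name, start, end, exonic))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "exonic_length"])
    return GenomeModel(chromosomes=chromosomes, genes=genes).validate()


def tile_windows(length: int, window_size: int) -> np.ndarray:
    """0-based half-open window starts/ends tiling [0, length).

    A trailing partial window is kept only if it is at least half a window
    wide, to avoid high-variance tiny windows.
    """
    starts = np.arange(0, length, window_size)
    ends = np.minimum(starts + window_size, length)
    keep = (ends - starts) >= max(window_size // 2, 1)
    return np.column_stack([starts[keep], ends[keep]])


def simulate_dna_coverage(genome: GenomeModel, config: SimulationConfig) -> pd.DataFrame:
    """Poisson windowed read depth for a male and a female library.

    Female depth is Poisson(depth_female) everywhere; male depth is
    Poisson(depth_female) on autosomes and Poisson(depth_female / 2) on the
    X, reflecting the single male X copy at matched sequencing effort.
    """
    config.validate()
    shortest = int(genome.chromosomes["length"].min())
    if config.window_size > shortest:
        raise ConfigError(
            f"window_size {config.window_size} exceeds shortest chromosome ({shortest} bp)"
        )
    rng = stream_rng(config.seed, "dna-coverage")
    frames = []
    for _, chrom in genome.chromosomes.iterrows():
        win = tile_windows(int(chrom["length"]), config.window_size)
        n = len(win)
        frac = (win[:, 1] - win[:, 0]) / config.window_size  # partial windows
        lam_f = config.depth_female * frac
        half = 0.5 if chrom["true_class"] == "X" else 1.0
        lam_m = lam_f * half
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom["name"],
                    "start": win[:, 0],
                    "end": win[:, 1],
                    "depth_male": rng.poisson(lam_m).astype(float),
                    "depth_female": rng.poisson(lam_f).astype(float),
                }
            )
        )
    return validate_coverage(pd.concat(frames, ignore_index=True))


def _assign_bias_labels(genome: GenomeModel, config: SimulationConfig,
                        rng: np.random.Generator) -> pd.Series:
    """Draw per-gene bias labels (female_biased / male_biased / unbiased)."""
    genes = genome.genes
    n = len(genes)
    labels = pd.Series("unbiased", index=genes["gene_id"].to_numpy(), name="true_bias")
    n_f = int(round(config.bias_fraction_female * n))
    n_m = int(round(config.bias_fraction_male * n))
    x_set = set(genome.x_chromosomes)
    is_x = genes["chrom"].isin(x_set).to_numpy()
    order = rng.permutation(n)

    female_idx: list[int] = []
    if config.bias_x_concentration is not None and n_f > 0:
        n_on_x = int(round(config.bias_x_concentration * n_f))
        x_pool = [i for i in order if is_x[i]]
        a_pool = [i for i in order if not is_x[i]]
        female_idx = x_pool[:n_on_x] + a_pool[: n_f - n_on_x]
    else:
        female_idx = list(order[:n_f])
    remaining = [i for i in order if i not in set(female_idx)]
    male_idx = remaining[:n_m]

    labels.iloc[female_idx] = "female_biased"
    labels.iloc[male_idx] = "male_biased"
    return labels


def simulate_expression(
    genome: GenomeModel,
    config: SimulationConfig,
    tissue_plan: list[TissuePlan] | None = None,
    libsizes: dict[str, float] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts under a dosage-compensation regime.

    Baseline expression is drawn lognormal(meanlog 3, sdlog 1.5) on an
    FPKM-like scale and converted to expected counts through exonic length
    and library size; counts are NB(mean, dispersion_true) per sample.
    Returns the count matrix and a per-gene truth table (chromosome class
    and bias label) for recovery tests.

    libsizes optionally overrides the per-sample library size (keyed by
    sample_id) to emulate unequal sequencing depth.
    """
    config.validate()
    if tissue_plan is None:
        tissue_plan = [TissuePlan("tissue1")]
    for plan in tissue_plan:
        if plan.regime is not None and plan.regime not in REGIMES:
            raise ConfigError(f"regime must be one of {REGIMES}, got {plan.regime!r}")
        if plan.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    genes = genome.genes
    gene_ids = genes["gene_id"].to_numpy()
    rng = stream_rng(config.seed, "expression")
    baseline = rng.lognormal(mean=3.0, sigma=1.5, size=len(genes))
    labels = _assign_bias_labels(genome, config, stream_rng(config.seed, "bias"))

    x_set = set(genome.x_chromosomes)
    is_x = genes["chrom"].isin(x_set).to_numpy()
    len_kb = genes["exonic_length"].to_numpy() / 1e3
    bias_f = (labels == "female_biased").to_numpy()
    bias_m = (labels == "male_biased").to_numpy()

    meta_rows = []
    columns: dict[str, np.ndarray] = {}
    phi = config.dispersion_true
    for plan in tissue_plan:
        regime = plan.regime or config.regime
        fx, mx = _REGIME_X_FACTORS[regime]
        for sex in plan.sexes:
            sex_x = fx if sex == "F" else mx
            dose = np.where(is_x, sex_x, 1.0)
            fold = np.ones(len(genes))
            fold[bias_f] = config.bias_fold if sex == "F" else 1.0
            fold[bias_m] = config.bias_fold if sex == "M" else 1.0
            fpkm_mean = baseline * dose * fold
            for rep in range(1, plan.n_replicates + 1):
                sample_id = f"{plan.tissue}_{sex}_{rep}"
                lib = (libsizes or {}).get(sample_id, config.libsize)
                mu = fpkm_mean * len_kb * lib / 1e6
                if phi > 0:
                    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
                else:
                    counts = rng.poisson(mu)
                columns[sample_id] = counts.astype(np.int64)
                meta_rows.append((sample_id, plan.tissue, sex, rep))

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta_rows, columns=["sample_id", "tissue", "sex", "replicate"])
    cm = CountMatrix(
        counts=counts,
        samples=samples,
        gene_lengths=pd.Series(
            genes["exonic_length"].to_numpy(), index=counts.index, name="exonic_length"
        ),
        gene_chrom=pd.Series(genes["chrom"].to_numpy(), index=counts.index, name="chrom"),
    ).validate()

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": genes["chrom"].to_numpy(),
            "chrom_class": np.where(is_x, "X", "autosome"),
            "true_bias": labels.to_numpy(),
            "baseline_fpkm": baseline,
        }
    )
    return cm, truth
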