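"""End-to-end orchestration: simulate -> sexchrom -> normalize -> dosage ->
sexbias -> report, as one reproducible run driven by a YAML config.

Each stage writes its artifacts as TSVs under the run directory; the final
JSON report is assembled from those artifacts (never recomputed), so every
reported number is traceable to a stage file. A run with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from ._utils import ConfigError, logger
from . import io as xio
from . import dosage as xdos
from . import norm as xnorm
from . import sexbias as xbias
from . import sexchrom as xsex
from .containers import CountMatrix, TissueExpression
from .simulate import SimulationConfig, TissuePlan, simulate_dna_coverage, \
    simulate_expression, simulate_genome

STAGES = ("simulate", "sexchrom", "normalize", "dosage", "sexbias", "report")

DEFAULTS: dict = {
    "schema": 1,
    "seed": 0,
    "out_dir": "run",
    "inputs": {
        "gene_table": None,
        "gene_table_dialect": "tsv",
        "coverage": None,
        "counts": None,
        "samples": None,
    },
    "simulate": None,  # optional block of SimulationConfig fields + tissues
    "sexchrom": {
        "min_depth": 5.0,
        "normalize_libsize": False,
        "x_band": [0.35, 0.65],
        "auto_band": [0.8, 1.2],
        "min_windows": 5,
        "loess_span": 0.3,
    },
    "normalize": {
        "tmm": True,
        "filter_threshold": 1.0,
        "filter_rule": "both_below",
        "fpkm_floor": 0.01,
    },
    "dosage": {"delta": 0.15, "eps": 0.15},
    "sexbias": {
        "bcv": 0.2,
        "cpm_threshold": 1.0,
        "lfc_threshold": 2.0,
        "fdr_threshold": 0.05,
        "design": "auto",
    },
}

_SIMULATE_KEYS = {
    "n_autosomes", "n_genes_per_chrom", "n_windows_per_chrom", "window_size",
    "depth_female", "regime", "bias_fraction_female", "bias_fraction_male",
    "bias_fold", "bias_x_concentration", "dispersion_true", "libsize", "tissues",
}


def _merge_config(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key == "simulate":
            if value is not None:
                bad = set(value) - _SIMULATE_KEYS
                if bad:
                    raise ConfigError(f"unknown config key: simulate.{sorted(bad)[0]}")
            out["simulate"] = copy.deepcopy(value)
            continue
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_config(value, defaults[key], where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge_config(user, DEFAULTS)
    cfg["_config_dir"] = str(Path(path).resolve().parent)
    return cfg


def make_config(overrides: dict | None = None) -> dict:
    return _merge_config(overrides or {}, DEFAULTS)


def _resolve(cfg: dict, maybe_path: str | None) -> Path | None:
    if maybe_path is None:
        return None
    p = Path(maybe_path)
    base = Path(cfg.get("_config_dir", "."))
    return p if p.is_absolute() else base / p


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: dict, out: Path) -> None:
    block = dict(cfg["simulate"] or {})
    tissues = block.pop("tissues", None) or [
        {"tissue": "tissue1", "n_replicates": 2, "regime": None}
    ]
    sim_cfg = SimulationConfig(seed=cfg["seed"], **block)
    plan = [TissuePlan(**t) for t in tissues]
    genome = simulate_genome(sim_cfg)
    coverage = simulate_dna_coverage(genome, sim_cfg)
    counts, truth = simulate_expression(genome, sim_cfg, plan)
    fx = out / "fixtures"
    xio.write_fixture_set(genome, coverage, counts, fx, truth=truth)
    cfg["inputs"] = {
        "gene_table": str(fx / "genes.tsv"),
        "gene_table_dialect": "tsv",
        "coverage": str(fx / "coverage.tsv"),
        "counts": str(fx / "counts.tsv"),
        "samples": str(fx / "samples.tsv"),
    }
    cfg["_config_dir"] = "."


def _load_inputs(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame, CountMatrix]:
    inputs = cfg["inputs"]
    for key in ("gene_table", "coverage", "counts", "samples"):
        if inputs.get(key) is None:
            raise ConfigError(f"missing config key: inputs.{key}")
        if not _resolve(cfg, inputs[key]).exists():
            raise ConfigError(f"inputs.{key}: file not found: {inputs[key]}")
    genes = xio.read_gene_table(
        _resolve(cfg, inputs["gene_table"]), dialect=inputs["gene_table_dialect"]
    )
    coverage = xio.read_coverage(_resolve(cfg, inputs["coverage"]))
    counts = xio.read_counts(
        _resolve(cfg, inputs["counts"]), _resolve(cfg, inputs["samples"]),
        gene_table=genes,
    )
    return genes, coverage, counts


def _stage_sexchrom(cfg: dict, out: Path, coverage: pd.DataFrame) -> pd.DataFrame:
    sc = cfg["sexchrom"]
    track = xsex.compute_window_ratios(
        coverage, min_depth=sc["min_depth"], normalize_libsize=sc["normalize_libsize"]
    )
    track = xsex.loess_smooth(track, span=sc["loess_span"])
    classes = xsex.classify_chromosomes(
        track, x_band=tuple(sc["x_band"]), auto_band=tuple(sc["auto_band"]),
        min_windows=sc["min_windows"],
    )
    track.windows.to_csv(out / "ratio_track.tsv", sep="\t", index=False)
    classes.to_csv(out / "chrom_classes.tsv", sep="\t", index=False)
    return classes


def _stage_normalize(cfg: dict, out: Path, counts: CountMatrix) -> None:
    nm = cfg["normalize"]
    expr = xnorm.compute_fpkm(counts, tmm=nm["tmm"])
    expr.tmm_factors.to_frame().reset_index(names="sample_id").to_csv(
        out / "tmm_factors.tsv", sep="\t", index=False
    )
    expr.fpkm.reset_index(names="gene_id").to_csv(out / "fpkm.tsv", sep="\t", index=False)
    qc = xnorm.spearman_replicates(counts)
    qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)
    for tissue, texpr in xnorm.average_replicates(expr).items():
        filt = xnorm.filter_expressed(
            texpr, threshold=nm["filter_threshold"], rule=nm["filter_rule"]
        )
        filt.frame.reset_index(names="gene_id").to_csv(
            out / f"tissue_expr_{tissue}.tsv", sep="\t", index=False
        )


def _load_tissue_exprs(out: Path) -> dict[str, TissueExpression]:
    exprs = {}
    for path in sorted(out.glob("tissue_expr_*.tsv")):
        tissue = path.stem[len("tissue_expr_"):]
        frame = pd.read_csv(path, sep="\t").set_index("gene_id")
        exprs[tissue] = TissueExpression(tissue=tissue, frame=frame)
    if not exprs:
        raise ConfigError("no tissue expression artifacts; run the normalize stage first")
    return exprs


def _gene_labels(out: Path, genes: pd.DataFrame) -> pd.Series:
    classes = pd.read_csv(out / "chrom_classes.tsv", sep="\t")
    return xdos.gene_class_labels(
        genes.set_index("gene_id")["chrom"], xsex.class_map(classes)
    )


def _stage_dosage(cfg: dict, out: Path, genes: pd.DataFrame) -> pd.DataFrame:
    labels = _gene_labels(out, genes)
    exprs = _load_tissue_exprs(out)
    report = xdos.dosage_report(
        exprs, labels, delta=cfg["dosage"]["delta"], eps=cfg["dosage"]["eps"],
        floor=cfg["normalize"]["fpkm_floor"],
    )
    report.to_csv(out / "dosage_report.tsv", sep="\t", index=False)
    return report


def _stage_sexbias(cfg: dict, out: Path, genes: pd.DataFrame,
                   counts: CountMatrix) -> None:
    sb = cfg["sexbias"]
    labels = _gene_labels(out, genes)
    design = None if sb["design"] == "auto" else sb["design"]
    bias_frames, enrich_rows = [], []
    for tissue in counts.samples["tissue"].unique():
        smeta = counts.samples[counts.samples["tissue"] == tissue]
        if set(smeta["sex"]) != {"F", "M"}:
            logger.warning("tissue %s lacks one sex; sexbias skipped", tissue)
            continue
        table, enrich = xbias.sex_bias_analysis(
            counts, tissue, labels, design=design, bcv=sb["bcv"],
            cpm_threshold=sb["cpm_threshold"], lfc_threshold=sb["lfc_threshold"],
            fdr_threshold=sb["fdr_threshold"],
        )
        bias_frames.append(table.reset_index(names="gene_id"))
        for direction, res in enrich.items():
            if res is None:
                continue
            (a, b), (c, d) = res.table
            enrich_rows.append({
                "tissue": tissue, "direction": direction,
                "biased_x": a, "biased_autosome": b,
                "unbiased_x": c, "unbiased_autosome": d,
                "odds_ratio": res.odds_ratio, "p": res.p,
                "enriched_on": res.enriched_on,
            })
    if bias_frames:
        pd.concat(bias_frames, ignore_index=True).to_csv(
            out / "bias_table.tsv", sep="\t", index=False
        )
    enrich_cols = ["tissue", "direction", "biased_x", "biased_autosome",
                   "unbiased_x", "unbiased_autosome", "odds_ratio", "p",
                   "enriched_on"]
    pd.DataFrame(enrich_rows, columns=enrich_cols).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )


def _stage_report(cfg: dict, out: Path) -> dict:
    def _read(name: str) -> list[dict]:
        path = out / name
        if not path.exists() or path.stat().st_size == 0:
            return []
        df = pd.read_csv(path, sep="\t")
        return json.loads(df.to_json(orient="records"))

    bias_summary = []
    bias_path = out / "bias_table.tsv"
    if bias_path.exists():
        bias = pd.read_csv(bias_path, sep="\t")
        for tissue, grp in bias.groupby("tissue"):
            bias_summary.append({
                "tissue": tissue,
                "n_genes_tested": int((grp["label"] != "filtered").sum()),
                "n_female_biased": int((grp["label"] == "female_biased").sum()),
                "n_male_biased": int((grp["label"] == "male_biased").sum()),
            })

    report = {
        "schema": 1,
        "seed": cfg["seed"],
        "parameters": {k: cfg[k] for k in ("sexchrom", "normalize", "dosage", "sexbias")},
        "chromosome_classes": _read("chrom_classes.tsv"),
        "dosage": _read("dosage_report.tsv"),
        "sex_bias_summary": bias_summary,
        "enrichment": _read("enrichment.tsv"),
    }
    xio.write_report(report, out, name="report.json")
    return report


def run_pipeline(config: dict | str | Path, from_stage: str | None = None) -> dict:
    """Execute the pipeline, writing all artifacts under out_dir.

    ``from_stage`` resumes mid-pipeline from the artifacts already on disk
    (e.g. "dosage" reuses the coverage classification and normalized
    expression of a previous run).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else \
        _merge_config({k: v for k, v in config.items() if not k.startswith("_")},
                      DEFAULTS) | {k: v for k, v in config.items() if k.startswith("_")}
    if from_stage is not None and from_stage not in STAGES:
        raise ConfigError(f"unknown stage: {from_stage!r}")
    start = STAGES.index(from_stage) if from_stage else 0

    out = _resolve(cfg, cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run start: seed=%s out_dir=%s", cfg["seed"], out)
        if cfg["simulate"] is not None and start <= STAGES.index("simulate"):
            logger.info("stage simulate")
            _stage_simulate(cfg, out)
        elif cfg["simulate"] is not None:
            fx = out / "fixtures"
            cfg["inputs"] = {
                "gene_table": str(fx / "genes.tsv"), "gene_table_dialect": "tsv",
                "coverage": str(fx / "coverage.tsv"),
                "counts": str(fx / "counts.tsv"), "samples": str(fx / "samples.tsv"),
            }
            cfg["_config_dir"] = "."
        genes, coverage, counts = _load_inputs(cfg)
        if start <= STAGES.index("sexchrom"):
            logger.info("stage sexchrom")
            _stage_sexchrom(cfg, out, coverage)
        if start <= STAGES.index("normalize"):
            logger.info("stage normalize")
            _stage_normalize(cfg, out, counts)
        if start <= STAGES.index("dosage"):
            logger.info("stage dosage")
            _stage_dosage(cfg, out, genes)
        if start <= STAGES.index("sexbias"):
            logger.info("stage sexbias")
            _stage_sexbias(cfg, out, genes, counts)
        logger.info("stage report")
        report = _stage_report(cfg, out)
        logger.info("run complete")
        return report
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_demo(out_dir: str | Path, seed: int = 7) -> Path:
    """Emit a small synthetic dataset and a ready-to-run config.

    Three tissues mirror the qualitative finding the pipeline is built
    around: two compensated somatic tissues (one unreplicated, as public
    somatic data often is) and an uncompensated gonad with two replicates.
    Returns the path to the written config YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(
        n_autosomes=14, n_genes_per_chrom=300, n_windows_per_chrom=60,
        depth_female=60.0, bias_fraction_female=0.05, bias_fraction_male=0.05,
        bias_fold=8.0, dispersion_true=0.1, libsize=2e6, seed=seed,
    )
    plan = [
        TissuePlan("head", n_replicates=1, regime="complete_compensation"),
        TissuePlan("leg", n_replicates=1, regime="complete_compensation"),
        TissuePlan("gonad", n_replicates=2, regime="no_compensation"),
    ]
    genome = simulate_genome(sim)
    coverage = simulate_dna_coverage(genome, sim)
    counts, truth = simulate_expression(genome, sim, plan)
    fx = out / "fixtures"
    xio.write_fixture_set(genome, coverage, counts, fx, truth=truth)
    regimes = pd.DataFrame(
        [(p.tissue, p.regime or sim.regime) for p in plan],
        columns=["tissue", "regime"],
    )
    regimes.to_csv(fx / "tissue_regimes.tsv", sep="\t", index=False)

    # paths are written relative to the config file's directory
    cfg = {
        "schema": 1,
        "seed": seed,
        "out_dir": "run",
        "inputs": {
            "gene_table": "fixtures/genes.tsv",
            "gene_table_dialect": "tsv",
            "coverage": "fixtures/coverage.tsv",
            "counts": "fixtures/counts.tsv",
            "samples": "fixtures/samples.tsv",
        },
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
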