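"""Readers and writers for the pipeline's tabular formats.

All TSVs are tab-delimited UTF-8 with a mandatory header row. Gene tables
use 1-based inclusive coordinates (GFF3 convention); coverage windows use
0-based half-open coordinates (BED convention). Readers reject malformed
input rather than silently coercing it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger
from .containers import (
    COVERAGE_COLUMNS,
    GENE_COLUMNS,
    CountMatrix,
    GenomeModel,
    validate_coverage,
    validate_samples,
)


# ---------------------------------------------------------------------------
# gene tables

def read_gene_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a gene table (flat TSV or gene-feature GFF3).

    Returns a DataFrame with columns gene_id, chrom, start, end,
    exonic_length (1-based inclusive spans). For GFF3 input without exon
    features the span length is used as exonic length, with a warning.
    """
    path = Path(path)
    if dialect == "tsv":
        table = pd.read_csv(path, sep="\t")
        missing = [c for c in GENE_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        table = table[GENE_COLUMNS].copy()
    elif dialect == "gff3":
        table = _read_gff3_genes(path)
    else:
        raise ValidationError(f"unknown gene-table dialect: {dialect!r}")

    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id: {dup}")
    if (table["start"] < 1).any() or (table["end"] < table["start"]).any():
        raise ValidationError("gene spans must satisfy 1 <= start <= end")
    return table.reset_index(drop=True)


def _read_gff3_genes(path: Path) -> pd.DataFrame:
    genes: dict[str, dict] = {}
    exon_sums: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(f"malformed GFF3 line {lineno}: expected 9 fields")
            chrom, _source, ftype, start, end, _score, _strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"malformed GFF3 line {lineno}: bad coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gene_id = attr_map.get("ID")
                if gene_id is None:
                    raise ValidationError(f"GFF3 line {lineno}: gene without ID attribute")
                if gene_id in genes:
                    raise ValidationError(f"duplicate gene_id: {gene_id}")
                genes[gene_id] = {
                    "gene_id": gene_id, "chrom": chrom, "start": start_i, "end": end_i,
                }
            elif ftype == "exon":
                parent = attr_map.get("Parent")
                if parent is not None:
                    exon_sums[parent] = exon_sums.get(parent, 0) + (end_i - start_i + 1)
    if not exon_sums:
        if genes:
            logger.warning(
                "GFF3 %s has no exon features; using gene span as exonic length", path
            )
    rows = []
    for gene_id, rec in genes.items():
        span = rec["end"] - rec["start"] + 1
        rec["exonic_length"] = exon_sums.get(gene_id, span)
        rows.append(rec)
    return pd.DataFrame(rows, columns=GENE_COLUMNS) if rows else pd.DataFrame(
        columns=GENE_COLUMNS
    )


def write_gene_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_gene_table_gff3(table: pd.DataFrame, path: str | Path) -> None:
    """Write genes as GFF3 gene features plus one exon carrying the exonic length."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for _, row in table.iterrows():
            fh.write(
                f"{row['chrom']}\txdosage\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t+\t.\tID={row['gene_id']}\n"
            )
            exon_end = row["start"] + int(row["exonic_length"]) - 1
            fh.write(
                f"{row['chrom']}\txdosage\texon\t{row['start']}\t{exon_end}"
                f"\t.\t+\t.\tID={row['gene_id']}.e1;Parent={row['gene_id']}\n"
            )


# ---------------------------------------------------------------------------
# coverage

def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a BED-like coverage TSV (chrom, start, end, depth_male, depth_female)."""
    table = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in COVERAGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"coverage table missing columns: {missing}")
    return validate_coverage(table[COVERAGE_COLUMNS])


def write_coverage(windows: pd.DataFrame, path: str | Path) -> None:
    windows[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts

def read_counts(path: str | Path, metadata_path: str | Path,
                gene_table: pd.DataFrame | None = None) -> CountMatrix:
    """Read a count TSV (gene_id, length, then one column per sample).

    Sample columns must each have a metadata row; metadata rows for absent
    samples are ignored with a warning. Counts must be integers.
    """
    table = pd.read_csv(Path(path), sep="\t")
    if "gene_id" not in table.columns or "length" not in table.columns:
        raise ValidationError("count table must have gene_id and length columns")
    samples = validate_samples(pd.read_csv(Path(metadata_path), sep="\t"))
    sample_cols = [c for c in table.columns if c not in ("gene_id", "length")]
    known = set(samples["sample_id"])
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValidationError(f"count columns without metadata: {unknown}")
    extra = [s for s in samples["sample_id"] if s not in sample_cols]
    if extra:
        warnings.warn(f"metadata rows without count columns ignored: {extra}")
        samples = samples[samples["sample_id"].isin(sample_cols)].reset_index(drop=True)

    counts = table.set_index("gene_id")[sample_cols]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr != np.floor(arr)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count at gene {counts.index[g]}, sample {sample_cols[s]}"
            )
        counts = counts.astype(np.int64)
    lengths = table.set_index("gene_id")["length"]
    chrom = None
    if gene_table is not None:
        chrom = gene_table.set_index("gene_id")["chrom"].reindex(counts.index)
    return CountMatrix(
        counts=counts, samples=samples, gene_lengths=lengths, gene_chrom=chrom
    ).validate()


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 metadata_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_lengths)
    out.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        counts_path, sep="\t", index=False
    )
    cm.samples.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fixture bundles and reports

def write_fixture_set(
    genome: GenomeModel,
    coverage: pd.DataFrame,
    counts: CountMatrix,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> dict:
    """Write a complete synthetic fixture directory and its JSON manifest.

    Emits the gene table (GFF3 + TSV), chromosome table, coverage TSV,
    counts + sample metadata TSVs, optional truth labels, and a manifest
    listing every file with its row count. Round-trips losslessly through
    the readers in this module.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    def _record(name: str, n_rows: int) -> None:
        files[name] = {"path": name, "rows": int(n_rows)}

    write_gene_table_tsv(genome.genes, out / "genes.tsv")
    _record("genes.tsv", len(genome.genes))
    write_gene_table_gff3(genome.genes, out / "genes.gff3")
    _record("genes.gff3", len(genome.genes))
    genome.chromosomes.to_csv(out / "chromosomes.tsv", sep="\t", index=False)
    _record("chromosomes.tsv", len(genome.chromosomes))
    write_coverage(coverage, out / "coverage.tsv")
    _record("coverage.tsv", len(coverage))
    write_counts(counts, out / "counts.tsv", out / "samples.tsv")
    _record("counts.tsv", len(counts.counts))
    _record("samples.tsv", len(counts.samples))
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        _record("truth.tsv", len(truth))

    manifest = {"format": "xdosage-fixture", "schema": 1, "files": files}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_report(report: dict, out_dir: str | Path,
                 name: str = "report.json") -> Path:
    """Write the combined JSON report with stable key ordering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return path
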