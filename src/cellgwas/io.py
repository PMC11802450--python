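"""Readers and writers for the pipeline's on-disk formats.

Tabular files are TSV with header rows; counts are Matrix Market (MTX)
with genes.tsv / cells.tsv sidecars; the genotype panel is a plain
haplotype-by-SNP matrix with a SNP annotation TSV; SEG annotations are
written as BED (0-based half-open, converted from the internal 1-based
inclusive convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio, sparse


def write_gwas(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "CHR", "BP", "P", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    return df


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def write_panel(panel: np.ndarray, snps: pd.DataFrame, prefix) -> None:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".geno.tsv"), panel, fmt="%d", delimiter="\t")
    snps.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_panel(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    prefix = Path(prefix)
    panel = np.loadtxt(prefix.with_suffix(".geno.tsv"), dtype=np.uint8, delimiter="\t")
    if panel.ndim == 1:
        panel = panel[:, None]
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    return panel, snps


def write_counts(counts, labels, gene_ids, prefix) -> None:
    """MTX sparse counts (genes x cells) + genes.tsv + cells.tsv sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(counts))
    pd.DataFrame({"gene": gene_ids}).to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell": [f"cell{i}" for i in range(len(labels))], "cluster": labels}
    ).to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False)


def read_counts(prefix) -> tuple[sparse.csr_matrix, np.ndarray, list[str]]:
    prefix = str(prefix)
    counts = sparse.csr_matrix(sio.mmread(prefix + ".mtx"))
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene"].tolist()
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")
    return counts, cells["cluster"].to_numpy(), genes


def write_specificity(spec: pd.DataFrame, path) -> None:
    spec.to_csv(path, sep="\t", index=True, index_label="gene")


def read_specificity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
    return df


def write_filter_report(report, path) -> None:
    payload = {"n_input": report.n_input, "n_output": report.n_output, **report.removed}
    Path(path).write_text(json.dumps(payload, indent=1))


def write_gene_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=False)


def read_gene_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_correlation(corr, path) -> None:
    corr.to_triplets().to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path, name: str | None = None) -> None:
    """Convert 1-based inclusive intervals to BED (0-based half-open)."""
    bed = intervals.copy()
    bed["start"] = bed["start"].astype(int) - 1
    bed["end"] = bed["end"].astype(int)
    if name is not None:
        bed["name"] = name
    bed.to_csv(path, sep="\t", index=False, header=False)
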