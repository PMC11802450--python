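"""Expression-specificity scoring from a cluster-labelled count matrix.

The score for gene g in cell type c is the fraction of g's total
ln(1+count) cluster-mean expression found in c, so each gene's scores sum
to 1 over cell types. A gene expressed identically everywhere scores 1/C
in every cell type. Gene filtering (protein-coding, expressed, unique
names, outside the MHC) happens before specificity is computed, so row
sums are over the retained cell-type universe only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: MHC exclusion interval, 1-based inclusive (GRCh38-era convention).
DEFAULT_MHC = ("6", 25_000_000, 34_000_000)

FILTER_RULES = ("unmapped_id", "non_protein_coding", "nonunique_name", "unexpressed", "mhc")


@dataclass
class ClusterExpression:
    """Mean ln(1+count) expression per gene (rows) and cluster (columns)."""

    mean: pd.DataFrame
    cells_per_cluster: pd.Series

    def __post_init__(self) -> None:
        if (self.mean.to_numpy() < 0).any():
            raise ValueError("mean-transformed expression must be nonnegative")
        if (self.cells_per_cluster < 1).any():
            raise ValueError("retained clusters must contain at least one cell")


@dataclass
class GeneFilterReport:
    """Removal counts per filtering rule; removals account for input-output."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.removed.values())
        if total != self.n_input - self.n_output:
            raise ValueError("filter report does not balance")


def transform_counts(x):
    """ln(1 + x), applied elementwise; rejects negative counts."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return np.log1p(arr)


def cluster_means(
    counts,
    labels,
    gene_ids=None,
) -> ClusterExpression:
    """Mean of ln(1+count) per gene within each cluster.

    ``counts`` is genes x cells (sparse or dense); ``labels`` assigns each
    cell to exactly one cluster. Empty clusters are excluded with a warning.
    """
    labels = np.asarray(labels)
    if counts.shape[1] != labels.shape[0]:
        raise ValueError("one label per cell is required")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(counts.shape[0])]
    if sparse.issparse(counts):
        logx = counts.tocsc(copy=True).astype(float)
        logx.data = np.log1p(logx.data)
    else:
        logx = sparse.csc_matrix(transform_counts(counts))

    observed = pd.unique(labels)
    cols = {}
    sizes = {}
    for c in sorted(observed):
        cells = np.flatnonzero(labels == c)
        if cells.size == 0:  # can only arise for caller-supplied categories
            warnings.warn(f"cluster {c} has no cells; excluded")
            continue
        cols[c] = np.asarray(logx[:, cells].mean(axis=1)).ravel()
        sizes[c] = int(cells.size)
    if not cols:
        raise ValueError("no nonempty clusters")
    mean = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    return ClusterExpression(mean, pd.Series(sizes))


def filter_genes(
    expr: ClusterExpression,
    annotation: pd.DataFrame,
    id_map: dict | None = None,
    mhc: tuple = DEFAULT_MHC,
) -> tuple[ClusterExpression, GeneFilterReport]:
    """Apply the gene filters, in order, counting removals per rule.

    Rules (each applied to the genes surviving the previous one):

    1. ``unmapped_id`` — no annotation row, or (when ``id_map`` is given)
       no unique cross-reference mapping;
    2. ``non_protein_coding`` — annotation biotype != ``protein_coding``;
    3. ``nonunique_name`` — symbol shared with another input gene
       (all genes carrying a duplicated symbol are removed);
    4. ``unexpressed`` — zero total mean-transformed expression;
    5. ``mhc`` — gene interval overlaps the MHC interval at all
       (1-based inclusive endpoints on the configured chromosome).
    """
    ann = annotation.set_index("gene") if "gene" in annotation.columns else annotation
    removed = dict.fromkeys(FILTER_RULES, 0)
    keep = list(expr.mean.index)

    mapped = []
    if id_map is not None:
        targets = [id_map.get(g) for g in keep]
        dupes = pd.Series([t for t in targets if t is not None])
        dup_set = set(dupes[dupes.duplicated(keep=False)])
    for g in keep:
        if g not in ann.index:
            removed["unmapped_id"] += 1
        elif id_map is not None and (id_map.get(g) is None or id_map[g] in dup_set):
            removed["unmapped_id"] += 1
        else:
            mapped.append(g)

    coding = [g for g in mapped if ann.loc[g, "biotype"] == "protein_coding"]
    removed["non_protein_coding"] = len(mapped) - len(coding)

    symbols = ann.loc[coding, "symbol"]
    dup_symbols = set(symbols[symbols.duplicated(keep=False)])
    named = [g for g in coding if ann.loc[g, "symbol"] not in dup_symbols]
    removed["nonunique_name"] = len(coding) - len(named)

    totals = expr.mean.loc[named].sum(axis=1)
    expressed = [g for g in named if totals[g] > 0]
    removed["unexpressed"] = len(named) - len(expressed)

    mhc_chrom, mhc_start, mhc_end = str(mhc[0]), int(mhc[1]), int(mhc[2])
    out = []
    for g in expressed:
        row = ann.loc[g]
        overlaps = (
            str(row["chrom"]) == mhc_chrom
            and int(row["start"]) <= mhc_end
            and int(row["end"]) >= mhc_start
        )
        if overlaps:
            removed["mhc"] += 1
        else:
            out.append(g)

    report = GeneFilterReport(len(keep), len(out), removed)
    filtered = ClusterExpression(expr.mean.loc[out], expr.cells_per_cluster)
    return filtered, report


def compute_specificity(expr: ClusterExpression) -> pd.DataFrame:
    """Row-normalize cluster means to specificity scores (rows sum to 1)."""
    m = expr.mean
    totals = m.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:5])
        raise ValueError(f"all-zero gene rows must be filtered first: {bad}")
    return m.div(totals, axis=0)


def downsample_clusters(
    counts,
    labels,
    max_cells: int,
    seed: int | np.random.Generator = 0,
):
    """Retain at most ``max_cells`` per cluster, sampled uniformly.

    Mirrors the robustness analysis that thins every cell type to a common
    ceiling (e.g. 3,400 / 340 / 34 cells) before recomputing specificity.
    """
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in sorted(pd.unique(labels)):
        cells = np.flatnonzero(labels == c)
        if cells.size > max_cells:
            cells = np.sort(rng.choice(cells, size=max_cells, replace=False))
        keep.append(cells)
    idx = np.concatenate(keep)
    sub = counts[:, idx] if not sparse.issparse(counts) else counts.tocsc()[:, idx].tocsr()
    return sub, labels[idx]
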