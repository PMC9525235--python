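"""Single-cell expression processing and peptide target-cell mapping.

Raw UMI counts are normalized per cell to a fixed library size (molecules
per 1,000 or 10,000 UMIs depending on dataset depth), genes with fewer than
10 total UMIs are dropped, and expression is summarized per annotated cell
cluster as the mean normalized value — the quantity behind dot plots. A
gene family is represented by its highest-expressed homologue. Finally,
each peptide's candidate target profile across cell clusters is the sum of
the normalized cluster means of its assigned receptors.

Cell clustering itself is an input (cluster labels per cell), not computed
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UMIMatrix",
    "ClusterExpression",
    "filter_genes",
    "normalize_cells",
    "cluster_means",
    "scale_by_gene",
    "top_homologue_per_family",
    "peptide_cell_targets",
    "read_umi_matrix",
    "write_umi_matrix",
]


@dataclass
class UMIMatrix:
    """Genes x cells UMI counts plus a cell -> cluster assignment."""

    counts: pd.DataFrame          # genes x cells, non-negative integers
    cluster_of: pd.Series         # index = cells

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.cluster_of.index)
        if missing:
            raise ValueError(f"cells without cluster label: {sorted(missing)[:5]}...")
        self.cluster_of = self.cluster_of.loc[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ClusterExpression:
    """Mean normalized expression per gene and cell cluster."""

    normalized_mean: pd.DataFrame     # genes x clusters
    scaled: pd.DataFrame | None = None


def filter_genes(m: UMIMatrix, min_total: int = 10) -> UMIMatrix:
    """Drop genes with total UMI count below ``min_total``."""
    totals = m.counts.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        warnings.warn("all genes removed by the total-count filter")
    return UMIMatrix(counts=m.counts.loc[keep], cluster_of=m.cluster_of)


def normalize_cells(m: UMIMatrix, scale_factor: float = 10000.0) -> pd.DataFrame:
    """Per-cell library-size normalization: count / cell total * scale factor.

    Totals are taken over the matrix as given — call this on the raw matrix
    (before gene filtering) so filtered genes still contribute to totals,
    matching the upstream normalize-then-filter order. Zero-total cells are
    dropped with a warning.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} cells with zero total counts")
    keep = totals.index.difference(zero, sort=False)
    return m.counts[keep].div(totals[keep], axis=1) * scale_factor


def cluster_means(
    normalized: pd.DataFrame, cluster_of: pd.Series, summary: str = "mean"
) -> ClusterExpression:
    """Per-gene per-cluster summary (mean by default, median by flag)."""
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    labels = cluster_of.loc[normalized.columns]
    sizes = labels.value_counts()
    empty = [c for c in cluster_of.unique() if c not in sizes.index]
    if empty:
        warnings.warn(f"clusters with no cells excluded: {empty}")
    grouped = normalized.T.groupby(labels)
    means = (grouped.mean() if summary == "mean" else grouped.median()).T
    means = means.reindex(sorted(means.columns), axis=1)
    return ClusterExpression(normalized_mean=means)


def scale_by_gene(ce: ClusterExpression) -> ClusterExpression:
    """Scale each gene row to max 1 across clusters; all-zero rows stay zero."""
    maxima = ce.normalized_mean.max(axis=1)
    scaled = ce.normalized_mean.div(maxima.where(maxima > 0, other=1.0), axis=0)
    return ClusterExpression(normalized_mean=ce.normalized_mean, scaled=scaled)


def top_homologue_per_family(
    ce: ClusterExpression, families: dict[str, list[str]]
) -> tuple[dict[str, str], list[str]]:
    """Highest-expressed gene per family (sum of cluster means; ties by id).

    Families whose genes all fell out of the matrix are reported in the
    second return value rather than silently dropped.
    """
    sums = ce.normalized_mean.sum(axis=1)
    chosen: dict[str, str] = {}
    missing: list[str] = []
    for fam in sorted(families):
        present = [g for g in families[fam] if g in sums.index]
        if not present:
            missing.append(fam)
            continue
        best = sums[present].max()
        chosen[fam] = sorted(g for g in present if sums[g] == best)[0]
    return chosen, missing


def peptide_cell_targets(
    assignments: pd.DataFrame, ce: ClusterExpression
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Peptide x cluster target scores: sum of assigned receptors' cluster means.

    ``assignments`` needs columns peptide_id and receptor_id (the output of
    the receptor assignment step). Receptors absent from the expression
    matrix are reported per peptide; a peptide with no mapped receptor gets
    a zero row.
    """
    clusters = list(ce.normalized_mean.columns)
    rows = {}
    unmapped: dict[str, list[str]] = {}
    for pid, grp in assignments.groupby("peptide_id", sort=True):
        receptors = sorted(grp["receptor_id"])
        present = [r for r in receptors if r in ce.normalized_mean.index]
        absent = [r for r in receptors if r not in ce.normalized_mean.index]
        if absent:
            unmapped[pid] = absent
        if present:
            rows[pid] = ce.normalized_mean.loc[present].sum(axis=0)
        else:
            rows[pid] = pd.Series(0.0, index=clusters)
    table = pd.DataFrame(rows).T
    table.index.name = "peptide_id"
    return table, unmapped


def plot_dotplot(ce: ClusterExpression, path, max_dot=200.0) -> None:
    """Optional rendering helper: dot plot of scaled expression per cluster.

    Dot size encodes the per-gene scaled mean (largest = the gene's hottest
    cluster); requires the scaled matrix (call scale_by_gene first).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ce.scaled is None:
        raise ValueError("scaled matrix missing; call scale_by_gene first")
    genes = list(ce.scaled.index)
    clusters = list(ce.scaled.columns)
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.3 * len(clusters) + 2), max(2.5, 0.25 * len(genes) + 1))
    )
    for gi, g in enumerate(genes):
        ax.scatter(
            range(len(clusters)),
            [gi] * len(clusters),
            s=ce.scaled.loc[g].values * max_dot,
            c=ce.scaled.loc[g].values,
            cmap="viridis",
            vmin=0,
            vmax=1,
        )
    ax.set_xticks(range(len(clusters)), clusters, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# IO: MTX triplets + gene/cell lists, dense TSV, cluster maps
# ---------------------------------------------------------------------------

def write_umi_matrix(m: UMIMatrix, prefix) -> None:
    """Write counts as MatrixMarket triplets with gene/cell/cluster TSVs."""
    from scipy import io as spio
    from scipy import sparse

    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(m.counts.values))
    pd.Series(m.genes, name="gene").to_csv(prefix + ".genes.tsv", sep="\t", index=False)
    pd.Series(m.cells, name="cell").to_csv(prefix + ".cells.tsv", sep="\t", index=False)
    m.cluster_of.rename("cluster").rename_axis("cell").to_csv(
        prefix + ".clusters.tsv", sep="\t"
    )


def read_umi_matrix(prefix) -> UMIMatrix:
    from scipy import io as spio

    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray().astype(int)
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene"].astype(str).tolist()
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")["cell"].astype(str).tolist()
    clusters = pd.read_csv(prefix + ".clusters.tsv", sep="\t", index_col="cell")["cluster"]
    clusters.index = clusters.index.astype(str)
    counts = pd.DataFrame(mat, index=genes, columns=cells)
    return UMIMatrix(counts=counts, cluster_of=clusters)
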