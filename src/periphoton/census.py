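"""Receptor-expression census over a clustered single-cell count matrix.

Given a gene x cell count matrix and per-cell cluster labels (clustering is
an upstream input, never performed here), computes per-cluster positive-cell
counts, percent expressing, and DotPlot-style scaled average expression, plus
overall co-expression percentages for gene pairs. A cell is "positive" for a
gene when its raw count exceeds zero; average expression uses the
counts-per-10k log1p normalization, then is scaled across clusters to zero
mean and unit (sample) SD per gene. Both dialect choices are arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["ExpressionCensus", "count_positive", "dotplot_stats", "coexpression"]

log = logging.getLogger(__name__)


class GeneNotFound(KeyError):
    pass


def _as_csr(matrix) -> sparse.csr_matrix:
    m = sparse.csr_matrix(matrix)
    if (m.data < 0).any():
        raise ValueError("count matrix contains negative entries")
    return m


def _gene_row(gene_names: list[str], gene: str) -> int:
    try:
        return gene_names.index(gene)
    except ValueError:
        raise GeneNotFound(f"gene {gene!r} not in matrix") from None


@dataclass
class ExpressionCensus:
    """Tidy per-(gene, cluster) census table plus degenerate-case flags.

    ``table`` columns: gene, cluster, n_cells, n_pos, pct_pos,
    avg_expr (log-normalized mean) and avg_expr_scaled (SD units across
    clusters). ``single_cluster`` flags genes whose scaled value is reported
    as 0 because only one cluster was present.
    """

    table: pd.DataFrame
    total_cells: int
    single_cluster: bool = False

    def lookup(self, gene: str, cluster: str) -> pd.Series:
        sub = self.table[(self.table.gene == gene) & (self.table.cluster == cluster)]
        if sub.empty:
            raise KeyError(f"no census row for ({gene!r}, {cluster!r})")
        return sub.iloc[0]


def count_positive(matrix, gene_names: list[str], gene: str) -> int:
    """Number of cells with a raw count > 0 for ``gene``."""
    m = _as_csr(matrix)
    row = m.getrow(_gene_row(gene_names, gene))
    return int((row.data > 0).sum())


def dotplot_stats(
    matrix,
    gene_names: list[str],
    cluster_labels,
    genes: list[str],
    target_sum: float = 1e4,
) -> ExpressionCensus:
    """Per-cluster percent expressing and scaled average expression.

    For each requested gene and cluster: ``pct_pos = 100 * n_pos / n_cells``
    and ``avg_expr`` = mean over the cluster's cells of
    ``log(1 + target_sum * count / cell_total)``; ``avg_expr_scaled``
    standardizes ``avg_expr`` across clusters (sample SD) per gene.
    Empty clusters are excluded with a warning; with a single cluster the
    scaled value is reported as 0 and flagged.
    """
    m = _as_csr(matrix)
    labels = np.asarray(cluster_labels)
    if len(labels) != m.shape[1]:
        raise ValueError(
            f"cluster labels cover {len(labels)} cells but matrix has "
            f"{m.shape[1]} columns"
        )
    clusters = [c for c in pd.unique(labels)]
    cell_totals = np.asarray(m.sum(axis=0)).ravel().astype(float)
    zero_cells = cell_totals == 0
    safe_totals = np.where(zero_cells, 1.0, cell_totals)

    rows = []
    for gene in genes:
        gi = _gene_row(gene_names, gene)
        counts = np.asarray(m.getrow(gi).todense()).ravel().astype(float)
        logn = np.log1p(target_sum * counts / safe_totals)
        logn[zero_cells] = 0.0
        per_cluster = []
        for cl in clusters:
            mask = labels == cl
            n_cells = int(mask.sum())
            if n_cells == 0:
                log.warning("cluster %r has 0 cells; excluded", cl)
                continue
            n_pos = int((counts[mask] > 0).sum())
            per_cluster.append({
                "gene": gene, "cluster": cl, "n_cells": n_cells,
                "n_pos": n_pos, "pct_pos": 100.0 * n_pos / n_cells,
                "avg_expr": float(logn[mask].mean()),
            })
        avg = np.array([r["avg_expr"] for r in per_cluster])
        if len(avg) >= 2:
            # sample-SD scaling, the DotPlot convention: two clusters with
            # one-sided expression scale to +/- 1/sqrt(2)
            sd = float(avg.std(ddof=1))
            scaled = (avg - avg.mean()) / sd if sd > 0 else np.zeros_like(avg)
        else:
            scaled = np.zeros(len(avg))
        for r, s in zip(per_cluster, scaled):
            r["avg_expr_scaled"] = float(s)
        rows.extend(per_cluster)
    table = pd.DataFrame(
        rows, columns=["gene", "cluster", "n_cells", "n_pos", "pct_pos",
                       "avg_expr", "avg_expr_scaled"],
    )
    return ExpressionCensus(
        table=table,
        total_cells=m.shape[1],
        single_cluster=len(clusters) < 2,
    )


def coexpression(matrix, gene_names: list[str], gene_a: str, gene_b: str) -> dict:
    """Percent of all cells positive for a, for b, and for both."""
    m = _as_csr(matrix)
    n = m.shape[1]
    pos_a = np.asarray(m.getrow(_gene_row(gene_names, gene_a)).todense()).ravel() > 0
    pos_b = np.asarray(m.getrow(_gene_row(gene_names, gene_b)).todense()).ravel() > 0
    return {
        "pct_a": 100.0 * pos_a.sum() / n,
        "pct_b": 100.0 * pos_b.sum() / n,
        "pct_both": 100.0 * (pos_a & pos_b).sum() / n,
        "n_cells": n,
    }
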