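"""Absolute cross-correlation matrix and thresholded co-expression network.

Edge strength between two genes is the absolute Pearson correlation of
their expression profiles across samples, so both co-activation and
mutual inhibition count as functional linkage. The network keeps only
the pairs whose correlation reaches the critical point of the ranked
correlation curve, detected with the same breakpoint machinery used for
gene screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from netmarker.expression_io import ExpressionMatrix
from netmarker.screening import RankedCurve, detect_critical_point

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric genes x genes matrix of absolute Pearson correlations."""

    C: pd.DataFrame  # values in [0, 1], unit diagonal
    excluded: list[str] = field(default_factory=list)  # constant rows removed

    @property
    def gene_ids(self) -> list[str]:
        return list(self.C.index)


def cross_correlation(expr: ExpressionMatrix, group: str | None = None) -> CorrelationMatrix:
    """Absolute Pearson correlation between all gene pairs.

    ``group`` restricts the computation to the samples of one
    disease-stage group; the default pools all samples into a single
    matrix. Constant gene rows have undefined correlation and are
    excluded (logged) rather than assigned zero.
    """
    values = expr.values
    if group is not None:
        groups = expr.groups
        if groups is None:
            raise ValueError("group labels required for per-group correlation")
        cols = groups.index[groups == group]
        if len(cols) == 0:
            raise ValueError(f"no samples in group {group!r}")
        values = values[cols]
    if values.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    x = values.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    excluded = list(values.index[constant])
    if excluded:
        logger.warning("excluding %d constant gene rows from correlation", len(excluded))
        x = x[~constant]
    genes = values.index[~constant]
    if len(genes) < 2:
        raise ValueError("fewer than 2 non-constant genes")
    corr = np.abs(np.corrcoef(x))
    corr = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        C=pd.DataFrame(corr, index=genes, columns=genes), excluded=excluded
    )


def correlation_curve(corr: CorrelationMatrix) -> RankedCurve:
    """All off-diagonal correlations sorted descending, labelled by gene pair."""
    genes = np.asarray(corr.gene_ids)
    iu = np.triu_indices(len(genes), k=1)
    vals = corr.C.to_numpy()[iu]
    pairs = np.array([f"{genes[i]}|{genes[j]}" for i, j in zip(*iu)], dtype=object)
    order = np.lexsort((pairs, -vals))
    return RankedCurve(values=vals[order], gene_ids=pairs[order])


def threshold_network(
    corr: CorrelationMatrix,
    mode: str = "auto",
    manual_threshold: float | None = None,
    breakpoint_method: str = "piecewise",
) -> nx.Graph:
    """Build the weighted co-expression network from a correlation matrix.

    In ``auto`` mode the off-diagonal correlations are ranked descending
    and the critical point of that curve sets the threshold; pairs with
    correlation >= threshold become edges weighted by the correlation.
    Genes with no surviving edge are left out of the graph and recorded
    in ``graph.graph["excluded_genes"]``.
    """
    if mode not in ("auto", "manual"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "manual":
        if manual_threshold is None:
            raise ValueError("manual mode requires manual_threshold")
        threshold = float(manual_threshold)
        cp = None
    else:
        curve = correlation_curve(corr)
        try:
            cp = detect_critical_point(curve, method=breakpoint_method)
        except ValueError as exc:
            raise ValueError(
                f"automatic threshold failed ({exc}); supply a manual threshold"
            ) from exc
        threshold = cp.threshold
    genes = np.asarray(corr.gene_ids)
    mat = corr.C.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    keep = mat[iu] >= threshold
    if not keep.any():
        raise ValueError(
            f"no edge reaches threshold {threshold:.4g}; supply a manual threshold"
        )
    g = nx.Graph(threshold=threshold)
    for i, j, w in zip(iu[0][keep], iu[1][keep], mat[iu][keep]):
        g.add_edge(genes[i], genes[j], weight=float(w))
    g.graph["excluded_genes"] = sorted(set(genes) - set(g.nodes))
    if cp is not None:
        g.graph["critical_point"] = cp
    logger.info(
        "network: %d nodes, %d edges at threshold %.4g (%d genes isolated)",
        g.number_of_nodes(),
        g.number_of_edges(),
        threshold,
        len(g.graph["excluded_genes"]),
    )
    return g


def write_edge_list(g: nx.Graph, path: str) -> None:
    """Edge-list TSV (gene_a, gene_b, weight), deterministically sorted."""
    rows = sorted((min(a, b), max(a, b), d["weight"]) for a, b, d in g.edges(data=True))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edge_list(path: str) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        g.add_edge(a, b, weight=float(w))
    return g
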