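"""Sensitive-gene screening by a critical point on the ranked measure curve.

Genes are scored by an unsupervised sensitivity measure (variance across
all samples, or a label-informativeness score), the scores are sorted in
descending order, and the rank at which the curve changes regime — the
critical point — becomes the selection threshold. The default detector
fits every two-segment piecewise-linear decomposition of the curve by
least squares and returns the split with minimal total squared error; a
maximum-distance-to-chord knee detector is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netmarker.expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RankedCurve:
    """Measure values sorted descending, with the permutation to gene ids."""

    values: np.ndarray  # non-increasing
    gene_ids: np.ndarray  # gene id at each rank

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) > 0):
            raise ValueError("ranked curve must be non-increasing")
        if len(self.values) != len(self.gene_ids):
            raise ValueError("values and gene_ids length mismatch")


@dataclass
class CriticalPoint:
    """1-based rank of the regime change and the measure value there.

    ``confident`` is False when the two-segment fit barely improves on a
    single line (globally near-linear curve): the returned rank is then
    the tie-broken smallest split and should be reviewed manually.
    """

    rank: int
    threshold: float
    confident: bool = True


def gene_variance(expr: ExpressionMatrix, transform: str = "log2_shifted") -> pd.Series:
    """Per-gene sample variance across all samples (pooled groups).

    ``transform="log2_shifted"`` applies log2(x+1) first, the usual scale
    for raw microarray intensities; ``"none"`` uses values as-is. The
    sample (n-1) denominator is used throughout.
    """
    if transform not in ("none", "log2_shifted"):
        raise ValueError(f"unknown transform {transform!r}")
    if expr.values.shape[1] < 2:
        raise ValueError("variance needs at least 2 samples")
    x = expr.values.to_numpy(dtype=float)
    if transform == "log2_shifted":
        if np.any(x < 0):
            raise ValueError("negative values: use transform='none'")
        x = np.log2(x + 1.0)
    var = x.var(axis=1, ddof=1)
    if np.all(var == 0):
        logger.warning("all genes constant: variance measure is identically zero")
    return pd.Series(var, index=expr.values.index, name="variance")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def iic_measure(expr: ExpressionMatrix) -> pd.Series:
    """Label-informativeness score per gene (bits).

    A pluggable stand-in for an information-index classification measure:
    the information gain of the group label given a median split of the
    gene (values strictly above the median vs the rest). A gene identical
    across samples scores 0; a gene perfectly separating two equal-sized
    groups scores 1 bit. The interface is stable so an alternative
    formula can be dropped in.
    """
    groups = expr.groups
    if groups is None:
        raise ValueError("group labels required for the informativeness measure")
    labels, counts = np.unique(groups.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise ValueError("informativeness undefined with a single group")
    y = np.searchsorted(labels, groups.to_numpy())
    n = len(y)
    h_label = _entropy(counts.astype(float))
    x = expr.values.to_numpy(dtype=float)
    scores = np.zeros(x.shape[0])
    for i, row in enumerate(x):
        above = row > np.median(row)
        n_above = int(above.sum())
        if n_above in (0, n):  # degenerate split, no information
            continue
        c_above = np.bincount(y[above], minlength=len(labels)).astype(float)
        c_below = np.bincount(y[~above], minlength=len(labels)).astype(float)
        h_cond = (n_above / n) * _entropy(c_above) + ((n - n_above) / n) * _entropy(c_below)
        scores[i] = max(0.0, h_label - h_cond)
    return pd.Series(scores, index=expr.values.index, name="iic")


def rank_measure(measure: pd.Series) -> RankedCurve:
    """Sort a measure vector descending; ties broken by gene id."""
    if not np.all(np.isfinite(measure.to_numpy(dtype=float))):
        raise ValueError("measure contains non-finite values")
    order = measure.sort_index().sort_values(ascending=False, kind="stable")
    return RankedCurve(
        values=order.to_numpy(dtype=float), gene_ids=order.index.to_numpy()
    )


def _prefix_sse(y: np.ndarray) -> np.ndarray:
    """SSE of the least-squares line through points (1..i, y[:i]), per prefix."""
    n = len(y)
    x = np.arange(1, n + 1, dtype=float)
    cn = x  # count of points in prefix i is i
    sx = np.cumsum(x)
    sy = np.cumsum(y)
    sxx = np.cumsum(x * x)
    syy = np.cumsum(y * y)
    sxy = np.cumsum(x * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx * sx / cn
        syy_c = syy - sy * sy / cn
        sxy_c = sxy - sx * sy / cn
        sse = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c / np.where(sxx_c > 0, sxx_c, 1), 0.0)
    return np.maximum(sse, 0.0)


def detect_critical_point(curve: RankedCurve, method: str = "piecewise") -> CriticalPoint:
    """Locate the regime change of a descending curve.

    ``method="piecewise"``: exhaustive two-segment piecewise-linear
    least-squares breakpoint — the split index s (segment 1 = ranks 1..s,
    segment 2 = ranks s+1..n, each with its own fitted line) minimizing
    the total SSE; ties broken toward the smallest rank. The returned
    threshold is the curve value at rank s.

    ``method="knee"``: the rank with maximal perpendicular distance to
    the chord joining the curve endpoints.
    """
    y = np.asarray(curve.values, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("curve must have at least 4 points")
    if np.all(y == y[0]):
        raise ValueError("no regime change: all values equal")
    if method == "piecewise":
        pre = _prefix_sse(y)
        suf = _prefix_sse(y[::-1])[::-1]
        # split s uses prefix of s points and suffix of n-s points, s in [2, n-2]
        splits = np.arange(2, n - 1)
        total = pre[splits - 1] + suf[splits]
        # ties (within float tolerance) break toward the smallest rank
        tol = 1e-9 * max(1.0, float(total.min()))
        best = int(splits[np.flatnonzero(total <= total.min() + tol)[0]])
        sse_single = float(_prefix_sse(y)[-1])
        confident = sse_single > 0 and float(total.min()) < 0.95 * sse_single
        return CriticalPoint(rank=best, threshold=float(y[best - 1]), confident=confident)
    if method == "knee":
        x = np.arange(1, n + 1, dtype=float)
        # perpendicular distance to the chord from (1, y0) to (n, y_{n-1})
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
        best = int(np.argmax(dist)) + 1
        return CriticalPoint(rank=best, threshold=float(y[best - 1]))
    raise ValueError(f"unknown method {method!r}")


def select_sensitive_genes(
    expr: ExpressionMatrix, measure: pd.Series, cp: CriticalPoint
) -> ExpressionMatrix:
    """Keep genes whose measure reaches the critical-point threshold.

    Genes with measure >= cp.threshold are retained (the gene sitting
    exactly at the critical point is included), preserving the input row
    order.
    """
    keep = measure.reindex(expr.values.index) >= cp.threshold
    if not keep.any():
        raise ValueError("threshold above the maximal measure: empty selection")
    out = ExpressionMatrix(values=expr.values.loc[keep], annotation=expr.annotation)
    logger.info(
        "selected %d of %d genes at threshold %.4g",
        out.values.shape[0],
        expr.values.shape[0],
        cp.threshold,
    )
    return out
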