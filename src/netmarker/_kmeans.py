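"""Seeded Lloyd k-means used by both module detection and sample subtyping.

Kept in-house so the per-iteration inertia monotonicity contract can be
enforced and so identical tie-breaking (lowest center index) applies on
both the gene side and the sample side.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_MAX_ITER = 300
_REL_TOL = 1e-6
_EMPTY_RETRY_CAP = 10


def _sq_dist(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (n_points, n_centers)."""
    d2 = (
        (x * x).sum(1)[:, None]
        - 2.0 * x @ centers.T
        + (centers * centers).sum(1)[None, :]
    )
    return np.maximum(d2, 0.0)


def lloyd_single(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One Lloyd run from k distinct random data points.

    Ties in assignment go to the lowest center index (argmin). Empty
    clusters are re-seeded to the point farthest from its center, up to a
    retry cap. The assignment-step inertia is checked to be non-increasing
    across iterations.
    """
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    centers = x[rng.choice(n, size=k, replace=False)].copy()
    scale = float((x * x).sum()) or 1.0
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=int)
    inertia = 0.0
    retries = 0
    for _ in range(_MAX_ITER):
        d2 = _sq_dist(x, centers)
        labels = d2.argmin(1)
        inertia = float(d2[np.arange(n), labels].sum())
        if not inertia <= prev_inertia * (1 + 1e-9) + 1e-12:
            raise AssertionError("Lloyd inertia increased between iterations")
        new_centers = centers.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centers[c] = x[mask].mean(0)
            elif retries < _EMPTY_RETRY_CAP:
                far = int(d2[np.arange(n), labels].argmax())
                new_centers[c] = x[far]
                retries += 1
                logger.debug("re-seeded empty cluster %d", c)
        movement = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if movement * movement < _REL_TOL * scale / n:
            break
        prev_inertia = inertia
    d2 = _sq_dist(x, centers)
    labels = d2.argmin(1)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, inertia


def lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 10
) -> tuple[np.ndarray, float]:
    """Best of ``n_init`` seeded Lloyd runs (lowest inertia kept)."""
    best_labels, best_inertia = None, np.inf
    for _ in range(n_init):
        labels, inertia = lloyd_single(x, k, rng)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    assert best_labels is not None
    return best_labels, best_inertia
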