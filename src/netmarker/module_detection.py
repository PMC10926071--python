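"""Partitioning the gene network into modules.

Two independent routes: (i) k-means on correlation profiles — each gene
embedded as its row of the correlation matrix — with the gap statistic
selecting the module count; (ii) Louvain greedy maximization of weighted
modularity on the thresholded network. Modularity is computed in-house
from its defining sum so the partition quality reported is exactly the
quantity Louvain climbs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from netmarker._kmeans import lloyd
from netmarker.coexpr_network import CorrelationMatrix

logger = logging.getLogger(__name__)

#: default reference-set count for the gap statistic
DEFAULT_GAP_B = 50


@dataclass
class ModulePartition:
    """Gene -> module id (contiguous integers 1..K)."""

    assignments: pd.Series  # index gene, value module id

    def __post_init__(self) -> None:
        ids = np.unique(self.assignments.to_numpy())
        if len(ids) == 0 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("module ids must be contiguous integers starting at 1")

    @property
    def k(self) -> int:
        return int(self.assignments.max())

    def genes_in(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])

    def modules(self) -> list[int]:
        return list(range(1, self.k + 1))


def _relabel(groups: list[list[str]]) -> ModulePartition:
    """Contiguous ids, ordered by (size descending, smallest gene id)."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    pairs = [(gene, i + 1) for i, grp in enumerate(ordered) for gene in sorted(grp)]
    genes, ids = zip(*pairs)
    return ModulePartition(pd.Series(ids, index=list(genes), dtype=int))


def gene_distance(corr: CorrelationMatrix) -> pd.DataFrame:
    """d = 1 - |r|. Symmetric, zero diagonal; the triangle inequality is
    NOT guaranteed (this is a dissimilarity, not a metric)."""
    d = 1.0 - corr.C
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


def correlation_features(corr: CorrelationMatrix) -> pd.DataFrame:
    """Each gene embedded as its correlation profile (row of the matrix)."""
    return corr.C.copy()


def profile_embedding(
    features: pd.DataFrame,
    var_explained: float = 0.9,
    max_components: int | None = 20,
) -> pd.DataFrame:
    """Project gene profiles onto their leading principal components.

    Raw correlation profiles live in as many dimensions as there are
    genes; in that space the bounding-box reference of the gap statistic
    loses almost nothing per extra cluster (log W falls by about
    2/d * log((k+1)/k)), so the stop rule can never fire. Truncating to
    the components explaining ``var_explained`` of the variance keeps the
    cluster geometry (distances are rotation-invariant; discarded axes
    are estimation noise) while giving the reference a meaningful
    dimensionality. Both module k-means and the gap statistic run in
    this one embedding.
    """
    x = features.to_numpy(dtype=float)
    x = x - x.mean(0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    ratio = np.cumsum(s**2) / (s**2).sum()
    q = int(np.searchsorted(ratio, var_explained) + 1)
    if max_components is not None:
        q = min(q, max_components)
    q = max(q, 2)
    return pd.DataFrame(x @ vt[:q].T, index=features.index)


def kmeans_modules(
    features: pd.DataFrame, k: int, seed: int, n_init: int = 10
) -> ModulePartition:
    """K-means on gene feature rows; best of ``n_init`` restarts."""
    rng = np.random.default_rng(seed)
    labels, inertia = lloyd(features.to_numpy(dtype=float), k, rng, n_init=n_init)
    logger.info("k-means: k=%d inertia=%.4g", k, inertia)
    groups = [list(features.index[labels == c]) for c in range(k) if (labels == c).any()]
    return _relabel(groups)


def _pooled_dispersion(
    x: np.ndarray, k: int, rng: np.random.Generator, n_init: int
) -> float:
    """W_k = sum_r (sum of within-cluster pairwise distances) / n_r.

    Clusters come from (SSE-objective) k-means; the dispersion itself is
    measured with unsquared Euclidean distances, which keeps log W_k from
    being dominated by between-cluster spread at small k.
    """
    if k == 1:
        labels = np.zeros(len(x), dtype=int)
    else:
        labels, _ = lloyd(x, k, rng, n_init=n_init)
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        if len(pts) > 1:
            w += pdist(pts).sum() / len(pts)
    return w


def gap_statistic(
    features: pd.DataFrame,
    k_range: range | list[int] = range(1, 11),
    b: int = DEFAULT_GAP_B,
    seed: int = 0,
    n_init: int = 10,
    ref_n_init: int | None = None,
    reference: str = "pca",
) -> tuple[int, pd.DataFrame]:
    """Select the number of modules by the gap statistic.

    Gap(k) = E*[log W_k] - log W_k, where W_k pools the normalized
    within-cluster pairwise distances (see :func:`_pooled_dispersion`)
    and the expectation runs over ``b`` uniform reference draws.
    ``reference="pca"`` draws uniformly in the bounding box aligned to
    the principal axes of the centered features (tighter null, robust to
    oblique cluster layouts); ``"box"`` uses the raw per-dimension
    bounding box. Returns the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}; if the criterion is never met the
    argmax of the gap is returned with a warning.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if b < 10:
        raise ValueError("need at least 10 reference draws")
    if reference not in ("pca", "box"):
        raise ValueError(f"unknown reference {reference!r}")
    if ref_n_init is None:
        ref_n_init = n_init  # references need the same convergence quality
    x = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if reference == "pca":
        center = x.mean(0)
        _, _, vt = np.linalg.svd(x - center, full_matrices=False)
        x_ref_space = (x - center) @ vt.T
    else:
        x_ref_space = x
    lo, hi = x_ref_space.min(0), x_ref_space.max(0)
    log_w = np.array([np.log(_pooled_dispersion(x, k, rng, n_init)) for k in ks])
    ref_log_w = np.empty((b, len(ks)))
    for rep in range(b):
        ref = rng.uniform(lo, hi, size=x.shape)
        # W_k is rotation-invariant, so references can stay in PCA space
        ref_log_w[rep] = [np.log(_pooled_dispersion(ref, k, rng, ref_n_init)) for k in ks]
    gap = ref_log_w.mean(0) - log_w
    sk = ref_log_w.std(0, ddof=0) * np.sqrt(1.0 + 1.0 / b)
    table = pd.DataFrame({"k": ks, "log_w": log_w, "gap": gap, "sk": sk}).set_index("k")
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            return ks[i], table
    warnings.warn("gap criterion never satisfied; returning argmax gap")
    return ks[int(np.argmax(gap))], table


def modularity(net: nx.Graph, partition: ModulePartition | pd.Series) -> float:
    """Weighted modularity of a partition.

    S = (1/2W) * sum_{i,j} [C_ij - k_i k_j / (2W)] mu(i,j) over ordered
    node pairs, where C is the weighted adjacency (no self-loops), k_i
    the weighted degree and W the total edge weight. The all-in-one
    partition scores exactly 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    assign = partition.assignments if isinstance(partition, ModulePartition) else partition
    nodes = list(net.nodes)
    missing = [n for n in nodes if n not in assign.index]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    two_w = a.sum()
    if two_w == 0:
        raise ValueError("network has no edges")
    k = a.sum(1)
    labels = assign.reindex(nodes).to_numpy()
    s = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        s += a[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / two_w
    return float(s / two_w)


def _local_move_refinement(
    net: nx.Graph, labels: dict, rng: np.random.Generator | None = None
) -> dict:
    """Exact single-node local moves until no move raises modularity.

    Closes the gap left by the aggregated phases: a partition is only
    returned once no single node prefers another (or a fresh) community.
    """
    nodes = list(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    two_w = a.sum()
    k = a.sum(1)
    idx = {n: i for i, n in enumerate(nodes)}
    lab = np.array([labels[n] for n in nodes])
    tot = np.zeros(lab.max() + 1 + len(nodes))  # spare slots for singleton moves
    np.add.at(tot, lab, k)
    improved = True
    while improved:
        improved = False
        order = np.arange(len(nodes)) if rng is None else rng.permutation(len(nodes))
        for i in order:
            current = lab[i]
            links = np.zeros(len(tot))
            np.add.at(links, lab, a[i])
            l_cur = links[current]  # i has no self-loop
            candidates = set(lab[a[i] > 0]) | {int(np.argmin(tot))}
            best_gain, best_c = 0.0, current
            for c in candidates:
                if c == current:
                    continue
                gain = (
                    2 * (links[c] - l_cur)
                    - k[i] * (2 * tot[c] - 2 * (tot[current] - k[i])) / two_w
                ) / two_w
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            if best_c != current:
                tot[current] -= k[i]
                tot[best_c] += k[i]
                lab[i] = best_c
                improved = True
    return {n: int(lab[idx[n]]) for n in nodes}


def louvain(net: nx.Graph, seed: int = 0, restarts: int = 16) -> tuple[ModulePartition, float]:
    """Louvain greedy modularity maximization.

    Node order is shuffled per seed; ``restarts`` independent runs are
    performed, each finished with an exact single-node local-move pass,
    and the partition with the highest modularity (as computed by
    :func:`modularity`) is kept. Deterministic given the seed.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(net.nodes)
    rng = np.random.default_rng(seed)
    if len(nodes) <= 12:
        # tiny graphs harbor joint-move local optima and restarts are
        # nearly free, so search much harder
        restarts = max(restarts, 64)
    best: tuple[float, ModulePartition] | None = None
    for r in range(restarts):
        if r % 2 == 0:
            comms = nx.community.louvain_communities(
                net, weight="weight", seed=seed + r
            )
            labels = {n: ci for ci, c in enumerate(comms) for n in c}
        else:
            # random multi-start: escapes joint-move local optima that
            # trap every greedy trajectory on small graphs
            k = int(rng.integers(1, len(nodes) + 1))
            labels = {n: int(rng.integers(0, k)) for n in nodes}
        labels = _local_move_refinement(net, labels, rng)
        groups: dict[int, list] = {}
        for n, c in labels.items():
            groups.setdefault(c, []).append(n)
        part = _relabel([sorted(g) for g in groups.values()])
        score = modularity(net, part)
        if best is None or score > best[0]:
            best = (score, part)
    assert best is not None
    logger.info("louvain: %d modules, S=%.4f", best[1].k, best[0])
    return best[1], best[0]


def write_partition(p: ModulePartition, path: str) -> None:
    df = p.assignments.rename("module").rename_axis("gene").reset_index()
    df.sort_values(["module", "gene"]).to_csv(path, sep="\t", index=False)
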