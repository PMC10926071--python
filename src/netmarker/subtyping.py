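"""Sample subtyping from representative-gene expression vectors.

Patient samples (healthy excluded) are described by the expression of the
module representatives and clustered with four algorithms: k-means, a
self-organizing map (SOM), a competitive (winner-take-all) network, and
agglomerative hierarchical clustering. Clusters are mapped to clinical
stage labels by plurality vote — clusters sharing a plurality class are
merged — and scored one-vs-rest with precision, recall, F1 and micro
accuracy, typically aggregated over 50 repeated runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from netmarker._kmeans import lloyd
from netmarker.expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubtypeFeatures:
    """Patients-only feature matrix (samples x representative genes)."""

    X: pd.DataFrame
    labels: pd.Series  # sample -> clinical stage

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)


@dataclass
class ClusterAssignment:
    assignments: pd.Series  # sample -> cluster id
    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class EvaluationReport:
    """Per-class one-vs-rest confusion counts and derived metrics.

    ``per_class`` has columns TP, FP, FN, TN, precision, recall, f1 and
    an ``undefined_precision`` flag (precision reported as 0 when no
    sample was assigned to the class). ``accuracy`` is micro accuracy:
    the fraction of correctly labelled samples.
    """

    per_class: pd.DataFrame
    accuracy: float

    def __post_init__(self) -> None:
        pc = self.per_class
        totals = pc[["TP", "FP", "FN", "TN"]].sum(axis=1)
        if totals.nunique() > 1:
            raise ValueError("confusion counts must sum to the sample total per class")
        defined = (pc["precision"] + pc["recall"]) > 0
        expected = np.where(
            defined,
            2 * pc["precision"] * pc["recall"]
            / (pc["precision"] + pc["recall"]).replace(0, np.nan),
            0.0,
        )
        if not np.allclose(pc["f1"].to_numpy(), np.nan_to_num(expected), atol=1e-12):
            raise ValueError("F1 must be the harmonic mean of precision and recall")


def build_features(
    expr: ExpressionMatrix,
    representative_genes: list[str],
    exclude_groups: tuple[str, ...] = ("healthy",),
    standardize: str = "zscore",
) -> SubtypeFeatures:
    """Patients-only matrix of representative-gene expression.

    Columns are z-scored by default (representative genes can sit on very
    different intensity scales); ``standardize="none"`` keeps raw values.
    """
    missing = [g for g in representative_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"representative genes missing from matrix: {missing}")
    if not representative_genes:
        raise ValueError("empty representative set")
    groups = expr.groups
    if groups is None:
        raise ValueError("group labels required to exclude healthy samples")
    keep = ~groups.isin(exclude_groups)
    x = expr.values.loc[representative_genes, keep[keep].index].T.astype(float)
    if standardize == "zscore":
        std = x.std(axis=0, ddof=0)
        if (std == 0).any():
            bad = list(std.index[std == 0])
            raise ValueError(f"zero-variance features {bad}; cannot standardize")
        x = (x - x.mean(axis=0)) / std
    elif standardize != "none":
        raise ValueError(f"unknown standardize mode {standardize!r}")
    return SubtypeFeatures(X=x, labels=groups[keep].copy())


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


def som_fit(
    f: SubtypeFeatures,
    rows: int = 2,
    cols: int = 3,
    epochs: int = 200,
    seed: int = 0,
    lr0: float = 0.5,
) -> ClusterAssignment:
    """Kohonen self-organizing map on a rows x cols grid.

    Online training: prototypes initialized from random samples; for each
    presented sample the best-matching unit (BMU) wins and every
    prototype moves toward the sample with a Gaussian neighborhood factor
    on the grid. Learning rate decays linearly from ``lr0`` to 0 and the
    neighborhood radius from max(rows, cols) to 1 over the epochs. Each
    sample is finally assigned to its BMU.
    """
    if rows * cols < 2:
        raise ValueError("grid must have at least 2 units")
    x = f.X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n, _ = x.shape
    n_units = rows * cols
    grid = _grid_coords(rows, cols)
    prototypes = x[rng.choice(n, size=n_units, replace=n_units > n)].copy()
    radius0, radius1 = float(max(rows, cols)), 1.0
    for epoch in range(epochs):
        t = epoch / max(1, epochs - 1)
        lr = lr0 * (1.0 - t)
        sigma = radius0 + (radius1 - radius0) * t
        for i in rng.permutation(n):
            d2 = ((prototypes - x[i]) ** 2).sum(1)
            bmu = int(d2.argmin())
            g2 = ((grid - grid[bmu]) ** 2).sum(1)
            h = np.exp(-g2 / (2.0 * sigma * sigma))
            prototypes += lr * h[:, None] * (x[i] - prototypes)
    d2 = ((x[:, None, :] - prototypes[None, :, :]) ** 2).sum(2)
    units = d2.argmin(1)
    return ClusterAssignment(
        assignments=pd.Series(units, index=f.X.index, name="unit"),
        algorithm="som",
        params={"rows": rows, "cols": cols, "epochs": epochs, "lr0": lr0},
        seed=seed,
    )


def kmeans_samples(f: SubtypeFeatures, k: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """Seeded Lloyd k-means on the sample vectors."""
    if k > len(f.X):
        raise ValueError(f"k={k} exceeds sample count {len(f.X)}")
    labels, _ = lloyd(f.X.to_numpy(dtype=float), k, np.random.default_rng(seed), n_init)
    return ClusterAssignment(
        assignments=pd.Series(labels, index=f.X.index, name="cluster"),
        algorithm="kmeans",
        params={"k": k},
        seed=seed,
    )


def competitive_fit(
    f: SubtypeFeatures, k: int, epochs: int = 200, seed: int = 0, lr0: float = 0.5
) -> ClusterAssignment:
    """Competitive (winner-take-all) network: like a SOM without neighborhood.

    Prototypes are seeded farthest-point style (first one random, each
    further one the sample farthest from the existing prototypes) so
    winner-take-all training does not strand dead units inside one cloud.
    """
    if k > len(f.X):
        raise ValueError(f"k={k} exceeds sample count {len(f.X)}")
    x = f.X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(x)))]
    while len(chosen) < k:
        d2 = np.min(
            ((x[:, None, :] - x[chosen][None, :, :]) ** 2).sum(2), axis=1
        )
        chosen.append(int(d2.argmax()))
    prototypes = x[chosen].copy()
    for epoch in range(epochs):
        lr = lr0 * (1.0 - epoch / max(1, epochs - 1))
        for i in rng.permutation(len(x)):
            d2 = ((prototypes - x[i]) ** 2).sum(1)
            winner = int(d2.argmin())
            prototypes[winner] += lr * (x[i] - prototypes[winner])
    d2 = ((x[:, None, :] - prototypes[None, :, :]) ** 2).sum(2)
    return ClusterAssignment(
        assignments=pd.Series(d2.argmin(1), index=f.X.index, name="cluster"),
        algorithm="competitive",
        params={"k": k, "epochs": epochs},
        seed=seed,
    )


def hierarchical_fit(f: SubtypeFeatures, k: int, method: str = "average") -> ClusterAssignment:
    """Agglomerative clustering (average linkage by default) cut at k clusters."""
    if k > len(f.X):
        raise ValueError(f"k={k} exceeds sample count {len(f.X)}")
    z = linkage(f.X.to_numpy(dtype=float), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        assignments=pd.Series(labels, index=f.X.index, name="cluster"),
        algorithm="hierarchical",
        params={"k": k, "linkage": method},
    )


def map_clusters_to_labels(a: ClusterAssignment, truth: pd.Series) -> pd.Series:
    """Relabel each cluster to its plurality true class.

    Clusters sharing a plurality class merge into it, so the number of
    predicted classes never exceeds the number of true classes. An exact
    plurality tie is broken toward the class that is rarer overall
    (logged), then lexicographically.
    """
    truth = truth.reindex(a.assignments.index)
    class_sizes = truth.value_counts()
    mapping: dict[int, str] = {}
    for cluster in sorted(a.assignments.unique()):
        members = truth[a.assignments == cluster]
        counts = members.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            top.sort(key=lambda c: (class_sizes[c], c))
            logger.info(
                "plurality tie in cluster %s (%s); assigned rarer class %s",
                cluster, sorted(top), top[0],
            )
        mapping[cluster] = top[0]
    return a.assignments.map(mapping).rename("predicted")


def evaluate(pred: pd.Series, truth: pd.Series) -> EvaluationReport:
    """One-vs-rest confusion counts per class plus micro accuracy.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean of
    the two (0 when both are 0). An empty predicted class yields
    precision 0 with the ``undefined_precision`` flag set.
    """
    truth = truth.reindex(pred.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some predicted samples")
    classes = sorted(truth.unique())
    n = len(pred)
    rows = {}
    for cls in classes:
        tp = int(((pred == cls) & (truth == cls)).sum())
        fp = int(((pred == cls) & (truth != cls)).sum())
        fn = int(((pred != cls) & (truth == cls)).sum())
        tn = n - tp - fp - fn
        undefined = (tp + fp) == 0
        pre = 0.0 if undefined else tp / (tp + fp)
        rec = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
        f1 = 0.0 if (pre + rec) == 0 else 2 * pre * rec / (pre + rec)
        rows[cls] = {
            "TP": tp, "FP": fp, "FN": fn, "TN": tn,
            "precision": pre, "recall": rec, "f1": f1,
            "undefined_precision": undefined,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class.index.name = "class"
    return EvaluationReport(per_class=per_class, accuracy=float((pred == truth).mean()))


_ALGORITHMS = {
    "som": som_fit,
    "kmeans": kmeans_samples,
    "competitive": competitive_fit,
    "hierarchical": hierarchical_fit,
}


def run_algorithm(
    f: SubtypeFeatures, algorithm: str, params: dict, seed: int = 0
) -> ClusterAssignment:
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    fit = _ALGORITHMS[algorithm]
    if algorithm == "hierarchical":  # deterministic, takes no seed
        return fit(f, **params)
    return fit(f, seed=seed, **params)


def repeat_experiment(
    f: SubtypeFeatures,
    algorithm: str,
    params: dict,
    n_runs: int = 50,
    base_seed: int = 0,
) -> dict:
    """Run cluster -> map -> evaluate ``n_runs`` times with consecutive seeds.

    Returns a dict with the per-run accuracy table, the mean/sd accuracy,
    the per-class metrics averaged over runs, and the last run's report.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    accs, per_class_frames = [], []
    report = None
    for r in range(n_runs):
        assign = run_algorithm(f, algorithm, params, seed=base_seed + r)
        pred = map_clusters_to_labels(assign, f.labels)
        report = evaluate(pred, f.labels)
        accs.append(report.accuracy)
        per_class_frames.append(report.per_class[["precision", "recall", "f1"]])
    acc = np.asarray(accs)
    stacked = pd.concat(per_class_frames, keys=range(n_runs), names=["run", "class"])
    return {
        "algorithm": algorithm,
        "params": params,
        "n_runs": n_runs,
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=0)),
        "per_run_accuracy": pd.Series(acc, name="accuracy"),
        "per_class_mean": stacked.groupby(level="class").mean(),
        "last_report": report,
    }
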