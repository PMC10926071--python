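"""Per-module hub extraction.

After cutting inter-module edges, each gene in a module subgraph is
scored by its weighted degree (sum of incident edge weights) and its
average shortest path length (ASPL) to the other genes of its connected
component. The module representative is the gene best ranked jointly on
both criteria — largest degree and smallest ASPL — resolved by rank sum
when the two disagree. Disconnected modules are represented by their
largest component.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from netmarker.module_detection import ModulePartition

logger = logging.getLogger(__name__)


def module_subgraph(net: nx.Graph, partition: ModulePartition, module: int) -> nx.Graph:
    """Induced subgraph on the genes of one module (inter-module edges cut)."""
    if module not in partition.modules():
        raise ValueError(f"unknown module id {module}")
    genes = [g for g in partition.genes_in(module) if g in net]
    return net.subgraph(genes).copy()


def _largest_component(sub: nx.Graph) -> set:
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    return comps[0]


def node_stats(sub: nx.Graph, paths: str = "hops") -> pd.DataFrame:
    """Weighted degree, ASPL and component size for every gene of a subgraph.

    ``paths="hops"`` measures shortest paths in hop counts (the edges are
    already strong by construction); ``"weighted"`` uses 1 - weight as
    edge length. ASPL is defined within the gene's connected component
    and is NaN for isolated genes.
    """
    if sub.number_of_nodes() == 0:
        raise ValueError("empty subgraph")
    if paths not in ("hops", "weighted"):
        raise ValueError(f"unknown paths mode {paths!r}")
    if paths == "weighted":
        for _, _, d in sub.edges(data=True):
            d["_len"] = 1.0 - d["weight"]
    rows = []
    for comp in nx.connected_components(sub):
        comp_size = len(comp)
        cg = sub.subgraph(comp)
        for gene in comp:
            degree = float(cg.degree(gene, weight="weight"))
            if comp_size == 1:
                aspl = np.nan
            else:
                if paths == "hops":
                    lengths = nx.single_source_shortest_path_length(cg, gene)
                else:
                    lengths = nx.single_source_dijkstra_path_length(cg, gene, weight="_len")
                aspl = float(
                    sum(v for k, v in lengths.items() if k != gene) / (comp_size - 1)
                )
            rows.append((gene, degree, aspl, comp_size))
    return (
        pd.DataFrame(rows, columns=["gene", "weighted_degree", "aspl", "component_size"])
        .set_index("gene")
        .sort_index()
    )


def select_representative(sub: nx.Graph, paths: str = "hops") -> tuple[str, dict]:
    """Pick the module hub: largest weighted degree, smallest ASPL.

    Only genes of the largest connected component are eligible. Degree is
    ranked descending and ASPL ascending (min ranks); the gene with the
    minimal rank sum wins; remaining ties go to smaller ASPL, then to the
    lexicographically smallest gene id. Returns the gene and a diagnostics
    dict (its stats, its two ranks, and whether the criteria conflicted).
    """
    stats = node_stats(sub, paths=paths)
    eligible = stats.loc[sorted(_largest_component(sub))]
    if len(eligible) == 1:
        gene = eligible.index[0]
        row = eligible.loc[gene]
        return gene, {
            "weighted_degree": float(row.weighted_degree),
            "aspl": float(row.aspl) if np.isfinite(row.aspl) else np.nan,
            "component_size": int(row.component_size),
            "degree_rank": 1,
            "aspl_rank": 1,
            "conflict": False,
        }
    deg = eligible["weighted_degree"].to_numpy()
    aspl = eligible["aspl"].to_numpy()
    deg_rank = rankdata(-deg, method="min")
    aspl_rank = rankdata(aspl, method="min")
    rank_sum = deg_rank + aspl_rank
    order = sorted(
        range(len(eligible)),
        key=lambda i: (rank_sum[i], aspl[i], eligible.index[i]),
    )
    best = order[0]
    conflict = not (deg_rank[best] == 1 and aspl_rank[best] == 1)
    if conflict:
        logger.info(
            "degree/ASPL criteria disagree in this module; rank-sum winner %s",
            eligible.index[best],
        )
    return eligible.index[best], {
        "weighted_degree": float(deg[best]),
        "aspl": float(aspl[best]),
        "component_size": int(eligible["component_size"].iloc[best]),
        "degree_rank": int(deg_rank[best]),
        "aspl_rank": int(aspl_rank[best]),
        "conflict": conflict,
    }


def extract_all(
    net: nx.Graph, partition: ModulePartition, paths: str = "hops"
) -> pd.DataFrame:
    """One representative per module, with selection diagnostics.

    Returns a DataFrame indexed by module id with columns representative,
    weighted_degree, aspl, component_size, degree_rank, aspl_rank,
    conflict.
    """
    rows = {}
    for module in partition.modules():
        sub = module_subgraph(net, partition, module)
        if sub.number_of_nodes() == 0:
            raise ValueError(f"module {module} has no genes present in the network")
        gene, diag = select_representative(sub, paths=paths)
        rows[module] = {"representative": gene, **diag}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def write_representatives(reps: pd.DataFrame, path: str) -> None:
    reps.reset_index().to_csv(path, sep="\t", index=False)
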