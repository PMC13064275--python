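"""Signed co-occurrence networks over core ASVs and their topology.

Edges are Pearson correlations of log-transformed normalized abundances
thresholded at |r| >= 0.3 (sign retained); nodes are ASVs with >= 50%
subject-level prevalence in the stratum. Path-based metrics use the
correlation-to-dissimilarity map w = sqrt(2 (1 - r)); modularity and
eigenvector centrality weight edges by |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io_preprocess import prevalence_by_subject


def core_asv_filter(
    table: pd.DataFrame, meta: pd.DataFrame, group: str, site: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Stratum samples x core ASVs (subject prevalence >= threshold, inclusive)."""
    prev = prevalence_by_subject(table, meta, group, site)
    keep = prev.index[prev >= threshold]
    meta = meta.loc[table.index.intersection(meta.index)]
    stratum = meta[(meta["group"] == group) & (meta["site"] == site)]
    return table.loc[stratum.index, keep]


def build_network(values: pd.DataFrame, r_threshold: float = 0.3) -> nx.Graph:
    """Correlation network over ``log(x + 1)``-transformed abundances.

    Constant ASVs have undefined correlations and become isolated nodes.
    Edge attributes: ``r``, ``sign`` (+1/-1), ``abs_r`` and the
    dissimilarity weight ``dissim = sqrt(2 (1 - r))``.
    """
    if values.shape[1] < 3:
        raise ValueError("need at least 3 nodes")
    if values.shape[0] < 4:
        raise ValueError("need at least 4 samples for meaningful correlations")
    logged = np.log(np.asarray(values, float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logged, rowvar=False)
    g = nx.Graph()
    nodes = list(values.columns)
    g.add_nodes_from(nodes)
    for i, j in combinations(range(len(nodes)), 2):
        r = corr[i, j]
        if np.isfinite(r) and abs(r) >= r_threshold:
            g.add_edge(nodes[i], nodes[j], r=float(r),
                       sign=1 if r > 0 else -1,
                       abs_r=float(abs(r)),
                       dissim=float(np.sqrt(max(2.0 * (1.0 - r), 0.0))))
    return g


@dataclass
class TopologyRecord:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    modularity: float
    pep: float
    edge_density: float
    robustness: float
    avg_path_length: float
    degree_centrality_mean: float
    betweenness_centrality_mean: float
    closeness_centrality_mean: float
    eigenvector_centrality_mean: float
    n_modules: int

    def to_dict(self) -> dict:
        return asdict(self)


def modules(g: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Modularity communities on the |r|-weighted skeleton.

    Greedy agglomeration plus a few seeded Louvain restarts; the partition
    with the highest modularity wins. Deterministic under the seed.
    """
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}
    candidates = [nx.community.greedy_modularity_communities(g, weight="abs_r")]
    for k in range(3):
        candidates.append(nx.community.louvain_communities(g, weight="abs_r",
                                                           seed=seed + k))
    best = max(candidates,
               key=lambda c: nx.community.modularity(g, c, weight="abs_r"))
    return {n: i for i, c in enumerate(best) for n in c}


def robustness(
    g: nx.Graph, removal_fraction: float = 0.5, n_rep: int = 100, seed: int = 0
) -> float:
    """Largest-component retention after random node removal.

    Mean over seeded trials of |largest connected component| / (N - removed)
    with ``removed = ceil(removal_fraction * N)`` (capped at N - 1).
    """
    if not 0.0 <= removal_fraction < 1.0:
        raise ValueError("removal_fraction must lie in [0, 1)")
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    removed = min(int(np.ceil(removal_fraction * n)), n - 1)
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_rep):
        drop = set(rng.choice(len(nodes), size=removed, replace=False))
        sub = g.subgraph([nd for k, nd in enumerate(nodes) if k not in drop])
        lcc = max((len(c) for c in nx.connected_components(sub)), default=0)
        vals.append(lcc / (n - removed))
    return float(np.mean(vals))


def detect_hubs(g: nx.Graph, quantile: float = 0.95) -> set[str]:
    """Nodes at or above the ``quantile``-th eigenvector-centrality quantile.

    Centrality is computed on the largest connected component with |r|
    weights; ties at the cut are all included.
    """
    if g.number_of_nodes() == 0:
        return set()
    comps = list(nx.connected_components(g))
    lcc = g.subgraph(max(comps, key=len))
    if lcc.number_of_edges() == 0:
        return set()
    eig = nx.eigenvector_centrality_numpy(lcc, weight="abs_r")
    scores = np.array(list(eig.values()))
    cut = np.quantile(scores, quantile)
    tol = 1e-9 * max(1.0, abs(cut))  # numerically tied nodes are all included
    return {n for n, v in eig.items() if v >= cut - tol}


def topology(g: nx.Graph, seed: int = 0, robustness_reps: int = 100) -> TopologyRecord:
    """Topology panel of a co-occurrence network.

    Clustering and density use the unweighted skeleton; the average path
    length is the mean dissimilarity-weighted shortest path over connected
    pairs of the largest component; centralities are averaged over nodes
    (betweenness/closeness on dissimilarity weights, eigenvector on |r|
    weights within the largest component). An edgeless network reports
    density 0, PEP 0 and NaN path length/modularity.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    mod_assign = modules(g, seed=seed)
    n_modules = len(set(mod_assign.values()))
    if e == 0:
        return TopologyRecord(
            n_nodes=n, n_edges=0, clustering_coefficient=0.0, modularity=float("nan"),
            pep=0.0, edge_density=0.0,
            robustness=robustness(g, seed=seed, n_rep=robustness_reps) if n >= 2 else float("nan"),
            avg_path_length=float("nan"), degree_centrality_mean=0.0,
            betweenness_centrality_mean=0.0, closeness_centrality_mean=0.0,
            eigenvector_centrality_mean=float("nan"), n_modules=n_modules,
        )
    comms: dict[int, set] = {}
    for node, m in mod_assign.items():
        comms.setdefault(m, set()).add(node)
    modularity = nx.community.modularity(g, comms.values(), weight="abs_r")
    pep = 100.0 * sum(1 for *_, d in g.edges(data=True) if d["sign"] > 0) / e
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    lcc_nodes = max(nx.connected_components(g), key=len)
    lcc = g.subgraph(lcc_nodes)
    apl = (nx.average_shortest_path_length(lcc, weight="dissim")
           if lcc.number_of_nodes() > 1 else float("nan"))
    deg = np.mean(list(nx.degree_centrality(g).values()))
    btw = np.mean(list(nx.betweenness_centrality(g, weight="dissim").values()))
    clo = np.mean(list(nx.closeness_centrality(g, distance="dissim").values()))
    eig = np.mean(list(nx.eigenvector_centrality_numpy(lcc, weight="abs_r").values()))
    return TopologyRecord(
        n_nodes=n, n_edges=e,
        clustering_coefficient=float(nx.average_clustering(g)),
        modularity=float(modularity), pep=float(pep), edge_density=float(density),
        robustness=robustness(g, seed=seed, n_rep=robustness_reps),
        avg_path_length=float(apl),
        degree_centrality_mean=float(deg), betweenness_centrality_mean=float(btw),
        closeness_centrality_mean=float(clo), eigenvector_centrality_mean=float(eig),
        n_modules=n_modules,
    )


def compare_networks(
    records: dict[str, TopologyRecord], hub_sets: dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side topology table per group plus pairwise hub Jaccard overlap."""
    if len(records) < 2:
        raise ValueError("need at least 2 networks to compare")
    metrics = pd.DataFrame({g: r.to_dict() for g, r in records.items()})
    groups = list(records)
    jac = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        sa, sb = set(hub_sets.get(a, ())), set(hub_sets.get(b, ()))
        union = sa | sb
        j = len(sa & sb) / len(union) if union else 1.0
        jac.loc[a, b] = jac.loc[b, a] = j
    return metrics, jac


def edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [{"node_a": a, "node_b": b, "r": d["r"], "sign": d["sign"]}
            for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "sign"])
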