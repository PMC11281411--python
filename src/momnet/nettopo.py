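"""Topological, module, role and comparative analyses of co-occurrence
networks.

Centralities follow the common convention for thresholded association
networks: betweenness, closeness and the clustering coefficient are
computed on the unweighted graph (the correlation threshold already
binarizes association strength), closeness per connected component with
Wasserman-Faust normalization, and eigenvector centrality on |r| weights.
Modules come from seeded Louvain on |r| weights; node roles from the
Guimera-Amaral Zi (within-module degree z-score) / Pi (participation
coefficient) plane with the conventional 2.5 / 0.62 cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import ConfigError, SYMPTOM_LAYER, SampleTable

METRICS = ("degree", "betweenness", "closeness", "eigenvector", "clustering")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    """Node -> module map with the modularity Q of the partition.

    Modules are labeled 1..k by descending size.
    """

    membership: dict
    modularity: float
    seed: int
    resolution: float
    sizes: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        counts = pd.Series(self.membership).value_counts().sort_index()
        self.sizes = counts

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def members(self, module) -> list:
        return [n for n, m in self.membership.items() if m == module]


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, eigenvector centrality
    (on |r| weights) and local clustering coefficient."""
    if net.number_of_nodes() == 0:
        raise ConfigError("empty network")
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net, wf_improved=True)
    clustering = nx.clustering(net)
    try:
        eigen = nx.eigenvector_centrality(net, max_iter=1000, tol=1e-8,
                                          weight="absr")
    except nx.PowerIterationFailedConvergence as exc:
        raise ConfigError(
            "eigenvector centrality failed to converge; relax the tolerance "
            "or raise max_iter"
        ) from exc
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
            "eigenvector": pd.Series(eigen),
            "clustering": pd.Series(clustering, dtype=float),
        }
    )
    frame.index.name = "node_id"
    return frame


def detect_modules(net: nx.Graph, seed: int = 0,
                   resolution: float = 1.0) -> ModulePartition:
    """Seeded Louvain community detection on |r| edge weights."""
    if net.number_of_edges() == 0:
        raise ConfigError("cannot detect modules in an edgeless network")
    communities = nx.community.louvain_communities(
        net, weight="absr", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    membership = {n: i + 1 for i, comm in enumerate(communities) for n in comm}
    q = nx.community.modularity(net, communities, weight="absr",
                                resolution=resolution)
    return ModulePartition(membership=membership, modularity=float(q),
                           seed=seed, resolution=resolution)


def zi_pi(net: nx.Graph, partition: ModulePartition,
          z_thr: float = ZI_THRESHOLD, p_thr: float = PI_THRESHOLD) -> pd.DataFrame:
    """Within-module degree z-score (Zi), participation coefficient (Pi)
    and the derived topological role per node.

    Roles: module hub (Zi >= z_thr, Pi < p_thr), connector (Zi < z_thr,
    Pi >= p_thr), network hub (both above), peripheral (both below).
    Degree-0 nodes have undefined Pi and are flagged peripheral.
    """
    membership = partition.membership
    missing = [n for n in net.nodes if n not in membership]
    if missing:
        raise ConfigError(f"partition does not cover nodes: {missing[:5]}")
    kappa_own = {}
    kappa_per_module: dict = {}
    for node in net.nodes:
        per = {}
        for nbr in net.neighbors(node):
            m = membership[nbr]
            per[m] = per.get(m, 0) + 1
        kappa_per_module[node] = per
        kappa_own[node] = per.get(membership[node], 0)

    module_stats = {}
    for module in partition.sizes.index:
        members = [n for n in net.nodes if membership[n] == module]
        vals = np.array([kappa_own[n] for n in members], dtype=float)
        if len(vals) >= 2:
            module_stats[module] = (vals.mean(), vals.std(ddof=0))
        else:
            module_stats[module] = (vals.mean() if len(vals) else 0.0, 0.0)

    rows = []
    for node in net.nodes:
        k = net.degree(node)
        mean, sd = module_stats[membership[node]]
        zi = (kappa_own[node] - mean) / sd if sd > 0 else 0.0
        if k == 0:
            pi = np.nan
            role = "peripheral"
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in kappa_per_module[node].values())
            hi_z, hi_p = zi >= z_thr, pi >= p_thr
            if hi_z and hi_p:
                role = "network hub"
            elif hi_z:
                role = "module hub"
            elif hi_p:
                role = "connector"
            else:
                role = "peripheral"
        rows.append((node, membership[node], float(zi), pi, role))
    out = pd.DataFrame(rows, columns=["node_id", "module", "Zi", "Pi", "role"])
    return out.set_index("node_id")


def degree_powerlaw(net: nx.Graph):
    """Least-squares slope and R^2 of log(frequency) vs log(degree)."""
    degrees = np.array([d for _, d in net.degree() if d >= 1])
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 5:
        raise ConfigError("need at least 5 distinct positive degrees")
    x = np.log(values.astype(float))
    y = np.log(counts.astype(float))
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def positive_edge_fraction(net: nx.Graph) -> float:
    """Fraction of edges with positive correlation."""
    m = net.number_of_edges()
    if m == 0:
        raise ConfigError("network has no edges")
    pos = sum(1 for _, _, d in net.edges(data=True) if d["r"] > 0)
    return pos / m


def module_overlap(part_a: ModulePartition, part_b: ModulePartition,
                   top_k: int = 5) -> pd.DataFrame:
    """Shared-node counts and percentage of the union for the top_k
    largest modules of each partition (UpSet-style long table)."""
    top_a = list(part_a.sizes.sort_values(ascending=False).index[:top_k])
    top_b = list(part_b.sizes.sort_values(ascending=False).index[:top_k])
    rows = []
    for ma in top_a:
        set_a = set(part_a.members(ma))
        for mb in top_b:
            set_b = set(part_b.members(mb))
            shared = len(set_a & set_b)
            union = len(set_a | set_b)
            pct = 100.0 * shared / union if union else 0.0
            rows.append((ma, mb, len(set_a), len(set_b), shared, pct))
    return pd.DataFrame(
        rows,
        columns=["module_a", "module_b", "size_a", "size_b", "shared",
                 "pct_of_union"],
    )


def compare_node_metrics(topo_a: pd.DataFrame, topo_b: pd.DataFrame,
                         subset=None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per centrality metric between the node-level
    values of two networks, optionally restricted to a node subset."""
    if topo_a.empty or topo_b.empty:
        raise ConfigError("topology tables must be non-empty")
    a, b = topo_a, topo_b
    if subset is not None:
        subset = set(subset)
        a = a.loc[a.index.intersection(subset)]
        b = b.loc[b.index.intersection(subset)]
        if a.empty or b.empty:
            raise ConfigError("subset does not intersect both networks")
    rows = []
    for metric in METRICS:
        x, y = a[metric].to_numpy(), b[metric].to_numpy()
        if np.all(np.concatenate([x, y]) == x[0] if len(x) else True):
            rows.append((metric, len(x) * len(y) / 2.0, 1.0))
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append((metric, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["metric", "U", "p"]).set_index("metric")


def module_summary(net: nx.Graph, partition: ModulePartition,
                   annotation_key: str | None = None) -> dict:
    """Per-module size, node share and annotation composition, plus the
    node share captured by the top ceil(25%) largest modules."""
    n_nodes = net.number_of_nodes()
    if n_nodes == 0:
        raise ConfigError("empty network")
    sizes = partition.sizes.sort_values(ascending=False)
    per_module = pd.DataFrame({
        "size": sizes,
        "node_share_pct": 100.0 * sizes / n_nodes,
    })
    composition = {}
    if annotation_key is not None:
        for module in sizes.index:
            members = partition.members(module)
            labels = pd.Series(
                [net.nodes[n].get(annotation_key, "unannotated") for n in members]
            )
            composition[module] = (100.0 * labels.value_counts() / len(members))
    k_top = int(np.ceil(0.25 * len(sizes)))
    top_share = 100.0 * sizes.iloc[:k_top].sum() / n_nodes
    return {
        "per_module": per_module,
        "composition": composition,
        "top25pct_modules": k_top,
        "top25pct_node_share_pct": float(top_share),
    }


def symptom_clustering(net: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Distribution of symptom-layer nodes over modules.

    Returns per-module symptom counts, the percentage of all symptom
    nodes, and the cumulative share over modules ranked by symptom count.
    """
    symptom_nodes = [n for n, d in net.nodes(data=True)
                     if d.get("layer") == SYMPTOM_LAYER]
    if not symptom_nodes:
        raise ConfigError("network contains no symptom nodes")
    counts: dict = {}
    for node in symptom_nodes:
        m = partition.membership.get(node)
        if m is None:
            raise ConfigError(f"partition does not cover symptom node {node!r}")
        counts[m] = counts.get(m, 0) + 1
    total = len(symptom_nodes)
    out = (
        pd.Series(counts, name="symptom_count")
        .sort_values(ascending=False)
        .to_frame()
    )
    out.index.name = "module"
    out["symptom_pct"] = 100.0 * out["symptom_count"] / total
    out["cumulative_pct"] = out["symptom_pct"].cumsum()
    return out


def symptom_edge_counts(net: nx.Graph) -> pd.Series:
    """Count symptom-incident edges by the omics layer of the other
    endpoint, plus the total (symptom-symptom edges count once, under
    the key ``symptom``)."""
    counts: dict = {}
    total = 0
    for u, v in net.edges:
        lu = net.nodes[u].get("layer")
        lv = net.nodes[v].get("layer")
        if SYMPTOM_LAYER not in (lu, lv):
            continue
        other = lv if lu == SYMPTOM_LAYER else lu
        counts[other] = counts.get(other, 0) + 1
        total += 1
    if total == 0:
        raise ConfigError("network has no symptom-incident edges")
    out = pd.Series(counts, name="edges").sort_index()
    out.loc["total"] = total
    return out


def score_scales(samples: SampleTable) -> pd.DataFrame:
    """Per-sample scale totals and sub-scores.

    GSS total is the plain item sum; SDS/SAS follow the Zung convention,
    index = round(raw sum x 1.25). Declared sub-scales (e.g. the SDS
    physiological/psychological item subsets) are raw sums.
    """
    if samples.symptom_items is None:
        raise ConfigError("sample table has no symptom items")
    items = samples.symptom_items
    out = pd.DataFrame(index=items.index)
    for scale, item_list in samples.scale_defs.items():
        missing_cols = [it for it in item_list if it not in items.columns]
        if missing_cols:
            raise ConfigError(f"{scale}: missing items {missing_cols[:5]}")
        block = items[item_list]
        if block.isna().any().any():
            bad = block.index[block.isna().any(axis=1)][0]
            raise ConfigError(f"{scale}: missing item score for sample {bad!r}")
        raw = block.sum(axis=1)
        if scale == "GSS":
            out["GSS_total"] = raw
        else:
            out[f"{scale}_raw"] = raw
            out[f"{scale}_index"] = (raw * 1.25).round().astype(int)
        for sub, sub_items in samples.subscale_defs.get(scale, {}).items():
            out[f"{scale}_{sub}"] = items[sub_items].sum(axis=1)
    return out
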