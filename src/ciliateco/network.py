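"""Co-occurrence networks calibrated against Erdos-Renyi nulls.

Edges are pairwise Spearman correlations across samples passing strict
thresholds (|rho| > 0.2 and p < 0.05 by default).  Modules come from
Louvain modularity maximization on the unweighted, sign-ignored graph.
Topology (clustering, path length, modularity) is compared with an
ensemble of G(n, m) random graphs with the observed node and edge counts;
the small-world coefficient sigma = (C/C_null) / (L/L_null) flags values
above 1.  Levins' niche breadth B = 1 / sum(p_j^2) measures how evenly a
taxon spreads over samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceTable, AnnotationGapError, relative_abundance


def filter_taxa(
    table: AbundanceTable,
    min_occurrence: int = 2,
    min_rel_abund: float = 0.005,
) -> list:
    """Taxa retained for network construction: present in at least
    ``min_occurrence`` samples and reaching a per-sample relative abundance
    strictly above ``min_rel_abund`` somewhere."""
    rel = relative_abundance(table, "per_sample")
    occurrence = (table.data > 0).sum(axis=0)
    max_rel = rel.max(axis=0)
    keep = (occurrence >= min_occurrence) & (max_rel > min_rel_abund)
    return list(table.taxa[keep])


@dataclass
class EcoNetwork:
    """Signed correlation graph over typed nodes."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    excluded: list = field(default_factory=list)  # constant features dropped

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"],
             "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])


def build_network(
    blocks: dict[str, tuple[pd.DataFrame, str]],
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
    annotations: dict[str, dict] | None = None,
    p_adjust: str | None = None,
) -> EcoNetwork:
    """All-pairs Spearman network over one or more feature blocks.

    ``blocks`` maps a block name to ``(features, node_type)`` where
    ``features`` is a sample x feature DataFrame; blocks must share the
    same sample index.  An edge is kept iff |rho| strictly exceeds
    ``r_threshold`` and p is strictly below ``p_threshold`` (optionally
    BH-adjusted).  Nodes without any edge are dropped.  Constant features
    (undefined correlation) are excluded and recorded.
    """
    frames, node_types = [], {}
    index = None
    for name, (df, node_type) in blocks.items():
        df = pd.DataFrame(df)
        if index is None:
            index = df.index
        elif not df.index.equals(index):
            raise ValueError(f"block {name!r} is not sample-aligned")
        for col in df.columns:
            if col in node_types:
                raise ValueError(f"duplicate feature name across blocks: {col}")
            node_types[col] = node_type
        frames.append(df)
    data = pd.concat(frames, axis=1)

    constant = [c for c in data.columns if data[c].nunique() <= 1]
    if constant:
        data = data.drop(columns=constant)
    features = list(data.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 non-constant features")

    rho, p = stats.spearmanr(data.to_numpy(), axis=0)
    if np.ndim(rho) == 0:   # scipy collapses the 2-feature case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu, ju = np.triu_indices(len(features), k=1)
    pvals = p[iu, ju]
    if p_adjust == "bh":
        pvals = stats.false_discovery_control(pvals, method="bh")

    g = nx.Graph()
    mask = (np.abs(rho[iu, ju]) > r_threshold) & (pvals < p_threshold)
    for k in np.flatnonzero(mask):
        a, b = features[iu[k]], features[ju[k]]
        r = float(rho[iu[k], ju[k]])
        g.add_edge(a, b, rho=r, p=float(pvals[k]), sign=int(np.sign(r)))
    for node in g.nodes:
        g.nodes[node]["node_type"] = node_types[node]
        if annotations and node in annotations:
            g.nodes[node].update(annotations[node])
    return EcoNetwork(g, r_threshold, p_threshold, excluded=constant)


def detect_modules(
    net: EcoNetwork, resolution: float = 1.0, seed: int | None = 0
) -> tuple[dict, float]:
    """Louvain partition of the unweighted graph; returns (node -> module
    id, modularity Q).  Module ids are 1-based, ordered by decreasing size.
    An edgeless graph gets one singleton module per node and Q = 0."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return {}, 0.0
    if g.number_of_edges() == 0:
        return {node: i + 1 for i, node in enumerate(g.nodes)}, 0.0
    communities = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    partition = {node: i + 1 for i, c in enumerate(communities) for node in c}
    q = nx.community.modularity(g, communities, weight=None)
    return partition, float(q)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    clustering: float
    modularity: float
    avg_path_length: float
    n_components: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def topology(net: EcoNetwork | nx.Graph, partition: dict | None = None,
             seed: int | None = 0) -> TopologySummary:
    """Whole-network topology.

    Clustering is the mean local transitivity with degree < 2 nodes
    contributing 0; average path length is computed within the largest
    connected component.  If no partition is supplied one is detected.
    """
    g = net.graph if isinstance(net, EcoNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0)
    if partition is None:
        wrapped = net if isinstance(net, EcoNetwork) else EcoNetwork(g, 0, 0)
        partition, q = detect_modules(wrapped, seed=seed)
    else:
        groups: dict = {}
        for node, mod in partition.items():
            groups.setdefault(mod, set()).add(node)
        q = nx.community.modularity(g, groups.values(), weight=None) if e else 0.0
    clustering = nx.average_clustering(g) if n else 0.0
    components = list(nx.connected_components(g))
    largest = max(components, key=len) if components else set()
    apl = (nx.average_shortest_path_length(g.subgraph(largest))
           if len(largest) > 1 else 0.0)
    return TopologySummary(n, e, 2 * e / n if n else 0.0, float(clustering),
                           float(q), float(apl), len(components))


def er_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed: int | None = 0,
    metrics: tuple = ("clustering", "avg_path_length", "modularity"),
) -> pd.DataFrame:
    """Topology of ``reps`` uniform G(n, m) random graphs with exactly the
    observed node and edge counts."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges impossible with {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(reps):
        s = int(rng.integers(0, 2**31 - 1))
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=s)
        row = {"n_edges": g.number_of_edges()}
        if "clustering" in metrics:
            row["clustering"] = nx.average_clustering(g)
        if "avg_path_length" in metrics:
            comps = list(nx.connected_components(g))
            big = max(comps, key=len)
            row["avg_path_length"] = (
                nx.average_shortest_path_length(g.subgraph(big))
                if len(big) > 1 else 0.0)
        if "modularity" in metrics:
            communities = nx.community.louvain_communities(g, weight=None, seed=s)
            row["modularity"] = nx.community.modularity(g, communities, weight=None)
        rows.append(row)
    return pd.DataFrame(rows)


def small_world_sigma(real: TopologySummary, null_means: dict) -> float:
    """sigma = (C_real / C_null) / (L_real / L_null); > 1 is small-world."""
    c_null = null_means.get("clustering", 0.0)
    l_null = null_means.get("avg_path_length", 0.0)
    if c_null <= 0 or l_null <= 0 or real.avg_path_length <= 0:
        raise ValueError("small-world coefficient undefined: null means must be positive")
    return (real.clustering / c_null) / (real.avg_path_length / l_null)


def levins_breadth(row) -> float:
    """Levins' niche breadth B = 1 / sum(p_j^2), the effective number of
    samples a taxon occupies; B in [1, n_samples]."""
    x = np.asarray(row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("niche breadth undefined for an all-zero taxon")
    p = x / total
    return float(1.0 / (p * p).sum())


def module_report(
    table: AbundanceTable,
    net: EcoNetwork,
    partition: dict,
) -> pd.DataFrame:
    """Per-module summary: size, mean degree, mean abundance, mean Levins
    niche breadth (over member taxa present in the table)."""
    degree = dict(net.graph.degree())
    rows = []
    for mod in sorted(set(partition.values())):
        members = [nd for nd, m in partition.items() if m == mod]
        taxa = [t for t in members if t in table.taxa]
        breadth = [levins_breadth(table.data[t]) for t in taxa
                   if table.data[t].sum() > 0]
        rows.append({
            "module": mod,
            "n_nodes": len(members),
            "mean_degree": float(np.mean([degree[nd] for nd in members])),
            "mean_abundance": float(table.data[taxa].mean().mean()) if taxa else np.nan,
            "mean_niche_breadth": float(np.mean(breadth)) if breadth else np.nan,
        })
    return pd.DataFrame(rows).set_index("module")


def module_preference(
    table: AbundanceTable,
    partition: dict,
    frame,
    by: tuple = ("season", "zone"),
) -> pd.DataFrame:
    """Mean module relative abundance per season / zone class.

    Module abundance per sample is the summed relative abundance of member
    taxa; the profile is its mean within each class, and the preference is
    the argmax class (empty when the profile is flat)."""
    rel = relative_abundance(table, "per_sample")
    rows = []
    for mod in sorted(set(partition.values())):
        taxa = [t for t, m in partition.items() if m == mod and t in table.taxa]
        if not taxa:
            continue
        share = rel[taxa].sum(axis=1)
        rec = {"module": mod}
        profile = {}
        for field_name in by:
            means = share.groupby(frame.data[field_name]).mean()
            for cls, val in means.items():
                profile[f"{field_name}[{cls}]"] = float(val)
            spread = means.max() - means.min()
            rec[f"preference_{field_name}"] = (
                str(means.idxmax()) if spread > 1e-12 else "")
        rec.update(profile)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("module")


EDGE_CLASSES = ("ciliate-ciliate", "ciliate-phytoplankton",
                "ciliate-environment", "other")


@dataclass
class EdgeClassification:
    counts: pd.DataFrame          # per class: n, n_positive, n_negative, proportions
    feeding_by_phylum: pd.DataFrame
    trophy_by_env_group: pd.DataFrame


def classify_edges(
    net: EcoNetwork,
    traits: pd.DataFrame | None = None,
    phylum_map: pd.Series | None = None,
    env_groups: dict | None = None,
) -> EdgeClassification:
    """Classify edges by endpoint node types and cross-tabulate the
    ciliate-phytoplankton edges (feeding habit x phylum) and the
    ciliate-environment edges (trophic type x environment group)."""
    def edge_class(tu: str, tv: str) -> str:
        pair = frozenset((tu, tv))
        if pair == {"ciliate"}:
            return "ciliate-ciliate"
        if pair == {"ciliate", "phytoplankton"}:
            return "ciliate-phytoplankton"
        if pair == {"ciliate", "environment"}:
            return "ciliate-environment"
        return "other"

    counts = {c: {"n": 0, "positive": 0, "negative": 0} for c in EDGE_CLASSES}
    cp_rows, ce_rows = [], []
    for u, v, d in net.graph.edges(data=True):
        tu = net.graph.nodes[u].get("node_type")
        tv = net.graph.nodes[v].get("node_type")
        if tu is None or tv is None:
            raise AnnotationGapError(f"edge ({u}, {v}) has untyped endpoints")
        cls = edge_class(tu, tv)
        counts[cls]["n"] += 1
        counts[cls]["positive" if d["sign"] > 0 else "negative"] += 1
        if cls == "ciliate-phytoplankton":
            cil, phy = (u, v) if tu == "ciliate" else (v, u)
            feeding = (traits.loc[cil, "feeding_habit"]
                       if traits is not None and cil in traits.index else None)
            phylum = (phylum_map.get(phy) if phylum_map is not None else None)
            if feeding is None or phylum is None:
                raise AnnotationGapError(f"unannotated nodes on edge ({u}, {v})")
            cp_rows.append({"feeding_habit": feeding, "phylum": phylum})
        elif cls == "ciliate-environment":
            cil, envv = (u, v) if tu == "ciliate" else (v, u)
            trophy = (traits.loc[cil, "trophy"]
                      if traits is not None and cil in traits.index else None)
            group = (env_groups.get(envv) if env_groups is not None else None)
            if trophy is None or group is None:
                raise AnnotationGapError(f"unannotated nodes on edge ({u}, {v})")
            ce_rows.append({"trophy": trophy, "env_group": group})

    count_df = pd.DataFrame(counts).T
    total = count_df["n"].replace(0, np.nan)
    count_df["positive_pct"] = 100.0 * count_df["positive"] / total
    count_df["negative_pct"] = 100.0 * count_df["negative"] / total
    fxp = (pd.crosstab(pd.DataFrame(cp_rows)["feeding_habit"],
                       pd.DataFrame(cp_rows)["phylum"])
           if cp_rows else pd.DataFrame())
    txg = (pd.crosstab(pd.DataFrame(ce_rows)["trophy"],
                       pd.DataFrame(ce_rows)["env_group"])
           if ce_rows else pd.DataFrame())
    return EdgeClassification(count_df, fxp, txg)
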