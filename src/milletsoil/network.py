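"""Species-level co-occurrence networks, topology, modules and Zi-Pi
keystone classification.

Construction follows the common web-tool convention for soil microbiome
studies: taxa are pre-filtered by mean relative abundance (> 0.5 % for
bacteria and fungi, > 0.01 % for archaea), every taxon pair is correlated
with Spearman's rho across samples, and an edge is kept when |rho| is at
least ``r_min`` (default 0.6) and the Benjamini-Hochberg adjusted p-value
is below ``alpha`` (default 0.05).  The edge sign records whether the
association is positive or negative; module detection and topology run on
absolute weights.

Node roles use the within-module degree z-score Zi and the participation
coefficient

    Pi = 1 - sum_s (k_is / k_i)^2

with the Guimera-Amaral thresholds: module hub Zi > 2.5, connector
Pi > 0.62, network hub both, else peripheral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, phylum_of

#: Minimum mean relative abundance per kingdom for network inclusion.
ABUNDANCE_FILTERS = {"bacteria": 0.005, "fungi": 0.005, "archaea": 0.0001}

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


class EmptyNetworkError(ValueError):
    """No taxa survive the abundance filter."""


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    average_path_length: float  # over connected pairs; NaN if no edges
    path_length_is_partial: bool
    modularity: float | None
    positive_edge_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NodeRole:
    taxon: str
    module: int
    zi: float
    pi: float
    role: str


def filter_taxa(table: AbundanceTable,
                threshold: float | None = None) -> AbundanceTable:
    """Keep taxa whose mean relative abundance exceeds the kingdom
    threshold."""
    rel = table if table.is_relative() else table.as_relative()
    thr = ABUNDANCE_FILTERS[table.kingdom] if threshold is None else threshold
    keep = rel.matrix.mean(axis=1) > thr
    if not keep.any():
        raise EmptyNetworkError(
            f"no {table.kingdom} taxa exceed mean abundance {thr}")
    return AbundanceTable(table.kingdom, rel.matrix.loc[keep])


def build_network(filtered: AbundanceTable, r_min: float = 0.6,
                  alpha: float = 0.05) -> nx.Graph:
    """Spearman co-occurrence graph over the filtered taxa.

    Nodes carry ``phylum``; edges carry ``rho``, ``p_adj``, ``sign`` and
    ``weight`` = |rho|.  Taxa constant across samples have undefined
    correlations and are excluded with a warning.
    """
    mat = filtered.matrix
    if mat.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 taxa")
    const = mat.nunique(axis=1) == 1
    if const.any():
        warnings.warn(f"excluding {int(const.sum())} constant taxa from "
                      "the network", stacklevel=2)
        mat = mat.loc[~const]
    taxa = list(mat.index)
    rho, pval = stats.spearmanr(mat.to_numpy().T)
    if np.ndim(rho) == 0:  # exactly two taxa: scipy returns scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    iu = np.triu_indices(len(taxa), 1)
    raw_p = pval[iu]
    _, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    g = nx.Graph(kingdom=filtered.kingdom, r_min=r_min, alpha=alpha)
    for t in taxa:
        g.add_node(t, phylum=phylum_of(t))
    for (i, j), r, pa in zip(zip(*iu), rho[iu], p_adj):
        if abs(r) >= r_min and pa < alpha:
            g.add_edge(taxa[i], taxa[j], rho=float(r), p_adj=float(pa),
                       sign=1 if r > 0 else -1, weight=abs(float(r)))
    return g


def topology(g: nx.Graph, modules: dict | None = None) -> TopologyMetrics:
    """Global topology metrics; average path length is computed over
    connected pairs only and flagged when the graph is disconnected."""
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    e = g.number_of_edges()
    density = 0.0 if n < 2 else 2 * e / (n * (n - 1))
    avg_degree = 2 * e / n
    total = pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs == 0:
        apl, partial = float("nan"), True
    else:
        apl = total / pairs
        partial = pairs < n * (n - 1)
    pos = sum(1 for _, _, d in g.edges(data=True)
              if d.get("sign", 1) > 0)
    q = None
    if modules is not None and e > 0:
        comms: dict[int, set] = {}
        for node, m in modules.items():
            comms.setdefault(m, set()).add(node)
        q = nx.community.modularity(g, comms.values(), weight="weight")
    return TopologyMetrics(n_nodes=n, n_edges=e, density=density,
                           average_degree=avg_degree,
                           average_path_length=apl,
                           path_length_is_partial=partial,
                           modularity=q,
                           positive_edge_fraction=pos / e if e else 0.0)


def detect_modules(g: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain modules on absolute edge weights.

    Returns (node -> module id, modularity Q); deterministic under seed.
    Isolated nodes each get their own module.
    """
    if g.number_of_edges() < 1:
        raise ValueError("need >= 1 edge for module detection")
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    q = nx.community.modularity(g, comms, weight="weight")
    assignment = {}
    for mid, nodes in enumerate(sorted(comms, key=lambda s: sorted(s)[0])):
        for node in nodes:
            assignment[node] = mid
    return assignment, q


def zipi(g: nx.Graph, modules: dict) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient
    (Pi) per node, with Guimera-Amaral role classes.

    Degrees are unweighted edge counts.  A module whose within-module
    degrees have zero spread gives Zi = 0 for its members; isolated nodes
    are peripheral with Zi = Pi = 0.
    """
    within = {}
    for node in g.nodes:
        m = modules[node]
        within[node] = sum(1 for nb in g.neighbors(node)
                           if modules[nb] == m)
    by_module: dict[int, list] = {}
    for node, m in modules.items():
        by_module.setdefault(m, []).append(node)
    roles = []
    for node in g.nodes:
        m = modules[node]
        members = by_module[m]
        ks = np.array([within[x] for x in members], dtype=float)
        sd = ks.std(ddof=0)
        zi = 0.0 if sd == 0 else (within[node] - ks.mean()) / sd
        k_total = g.degree(node)
        if k_total == 0:
            pi = 0.0
        else:
            per_mod: dict[int, int] = {}
            for nb in g.neighbors(node):
                per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
            pi = 1.0 - sum((k / k_total) ** 2 for k in per_mod.values())
        hub = zi > ZI_THRESHOLD
        conn = pi > PI_THRESHOLD
        role = ("network hub" if hub and conn else
                "module hub" if hub else
                "connector" if conn else "peripheral")
        roles.append(NodeRole(taxon=node, module=m, zi=float(zi),
                              pi=float(pi), role=role))
    return roles


def edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [{"taxon_a": a, "taxon_b": b, "rho": d["rho"],
             "p_adj": d["p_adj"], "sign": d["sign"]}
            for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows,
                        columns=["taxon_a", "taxon_b", "rho", "p_adj",
                                 "sign"])
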