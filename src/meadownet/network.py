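"""Thresholded Spearman co-occurrence networks and their topology.

Pipeline: all-pairs Spearman rank correlation on the (rarefied,
dominance-filtered) abundance table, then an edge for every OTU pair with
|rho| > r_threshold and p < p_threshold. Cross-domain networks are the same
graphs with every within-domain edge removed, leaving only
bacteria-fungi, bacteria-archaea and fungi-archaea associations.

Topology follows the Gephi conventions these networks are usually reported
with: node/edge counts over connected OTUs, Newman modularity of a seeded
Louvain partition, unweighted local clustering (degree < 2 contributes 0),
and path length / diameter over connected pairs only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, domain_of_otu, relative_abundance

logger = logging.getLogger(__name__)

DOMAIN_PAIRS = (("bacteria", "fungi"), ("bacteria", "archaea"), ("fungi", "archaea"))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    modularity: float
    diameter: float
    avg_path_length: float
    avg_clustering_coefficient: float
    positive_proportion: float
    negative_proportion: float

    def to_dict(self) -> dict:
        return asdict(self)


def spearman_all_pairs(table: CountTable) -> pd.DataFrame:
    """Spearman rho and two-sided p (t approximation) for every OTU pair.

    Correlations are computed on relative abundances with average ranks for
    ties. OTUs constant across samples have undefined rank correlation and
    are excluded with a logged report. Requires >= 4 samples so the
    p-value approximation is meaningful.
    """
    n, m = table.shape
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation p-values, got {n}")
    if m < 2:
        raise ValueError("need >= 2 OTUs")
    rel = relative_abundance(table)
    variable = rel.nunique(axis=0) > 1
    dropped = list(rel.columns[~variable])
    if dropped:
        logger.warning("excluding %d zero-variance OTU(s): %s",
                       len(dropped), dropped[:10])
    rel = rel.loc[:, variable]
    otus = list(rel.columns)
    if len(otus) < 2:
        return pd.DataFrame(columns=["otu_i", "otu_j", "rho", "p"])
    res = stats.spearmanr(rel.to_numpy())
    rho = np.atleast_2d(res.statistic)
    pval = np.atleast_2d(res.pvalue)
    if rho.shape == (1, 1):  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        pval = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    iu = np.triu_indices(len(otus), 1)
    return pd.DataFrame({
        "otu_i": np.asarray(otus)[iu[0]],
        "otu_j": np.asarray(otus)[iu[1]],
        "rho": rho[iu],
        "p": pval[iu],
    })


@dataclass
class CorrelationHistogram:
    """Frequency distribution of all pairwise correlations on [-1, 1]."""

    bin_edges: np.ndarray
    frequencies: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "frequency": self.frequencies,
        })


def correlation_histogram(results: pd.DataFrame, n_bins: int = 40) -> CorrelationHistogram:
    """Bin all pairwise rho values (significant or not) on [-1, 1]."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if results.empty:
        raise ValueError("no correlation results to bin")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    freq, _ = np.histogram(results["rho"].to_numpy(), bins=edges)
    return CorrelationHistogram(bin_edges=edges, frequencies=freq)


def build_network(
    results: pd.DataFrame,
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
    correction: str = "none",
    domains=None,
    keep_isolated: bool = False,
    all_otus=None,
) -> nx.Graph:
    """Graph with an edge wherever |rho| > r_threshold and p < p_threshold.

    ``correction="BH"`` applies Benjamini-Hochberg to the p-values first
    (the conventional raw-p construction is the default). ``domains`` tags
    nodes: a single domain label, a dict OTU -> domain, or None to infer
    from merged-table id prefixes. Isolated OTUs are dropped unless
    ``keep_isolated`` is set (then ``all_otus`` supplies the full node set).
    """
    if not (0 < r_threshold < 1 and 0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")

    def tag(otu):
        if isinstance(domains, str):
            return domains
        if isinstance(domains, dict):
            return domains.get(otu)
        try:
            return domain_of_otu(otu)
        except ValueError:
            return None

    g = nx.Graph()
    if not results.empty:
        p = results["p"].to_numpy().copy()
        if correction == "BH":
            p = _benjamini_hochberg(p)
        keep = (np.abs(results["rho"].to_numpy()) > r_threshold) & (p < p_threshold)
        for row in results.loc[keep].itertuples(index=False):
            sign = "+" if row.rho > 0 else "-"
            g.add_edge(row.otu_i, row.otu_j, rho=float(row.rho), sign=sign)
    if keep_isolated:
        seen = set(results["otu_i"]) | set(results["otu_j"]) if not results.empty else set()
        for otu in (all_otus if all_otus is not None else seen):
            g.add_node(otu)
    for node in g.nodes:
        g.nodes[node]["domain"] = tag(node)
    return g


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def cross_domain_filter(net: nx.Graph, keep_isolated: bool = False) -> nx.Graph:
    """Retain only edges whose endpoints belong to different domains."""
    for node, data in net.nodes(data=True):
        if data.get("domain") is None:
            raise ValueError(f"node {node!r} carries no domain tag")
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, data in net.edges(data=True):
        if net.nodes[u]["domain"] != net.nodes[v]["domain"]:
            out.add_edge(u, v, **data)
    if not keep_isolated:
        out.remove_nodes_from([n for n in out.nodes if out.degree(n) == 0])
    return out


def topology_summary(net: nx.Graph, community_seed: int = 0) -> TopologySummary:
    """Network-, node- and edge-level descriptors of a co-occurrence graph."""
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n < 1:
        raise ValueError("empty network")
    if n < 2:
        logger.warning("density undefined for a single-node network")
        density = float("nan")
    else:
        density = 2.0 * e / (n * (n - 1))
    avg_degree = 2.0 * e / n

    if e > 0:
        communities = nx.community.louvain_communities(net, weight=None,
                                                       seed=community_seed)
        modularity = nx.community.modularity(net, communities, weight=None)
        signs = [d["sign"] for _, _, d in net.edges(data=True)]
        pos = signs.count("+") / e
        neg = signs.count("-") / e
    else:
        modularity = float("nan")
        pos = neg = float("nan")

    clustering = sum(nx.clustering(net).values()) / n

    total_len = 0
    total_pairs = 0
    diameter = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, dist in lengths.items():
            if target != source:
                total_len += dist
                total_pairs += 1
                diameter = max(diameter, dist)
    if total_pairs:
        avg_path = total_len / total_pairs
    else:
        avg_path = float("nan")
        diameter = float("nan")

    return TopologySummary(
        n_nodes=n, n_edges=e, average_degree=avg_degree, density=density,
        modularity=modularity, diameter=float(diameter), avg_path_length=avg_path,
        avg_clustering_coefficient=clustering,
        positive_proportion=pos, negative_proportion=neg,
    )


def domain_pair_summary(net: nx.Graph) -> pd.DataFrame:
    """Edge count and sign proportions per domain pair of a cross-domain net."""
    counts = {pair: {"edges": 0, "positive": 0} for pair in DOMAIN_PAIRS}
    for u, v, data in net.edges(data=True):
        du, dv = net.nodes[u]["domain"], net.nodes[v]["domain"]
        if du == dv:
            raise ValueError(
                f"intra-domain edge {u!r}-{v!r}; run cross_domain_filter first"
            )
        pair = tuple(sorted((du, dv)))
        pair = next(p for p in DOMAIN_PAIRS if set(p) == set(pair))
        counts[pair]["edges"] += 1
        counts[pair]["positive"] += data["sign"] == "+"
    rows = []
    for pair, c in counts.items():
        e = c["edges"]
        rows.append({
            "domain_a": pair[0], "domain_b": pair[1], "n_edges": e,
            "positive_proportion": c["positive"] / e if e else float("nan"),
            "negative_proportion": (e - c["positive"]) / e if e else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    if format == "graphml":
        out = nx.Graph()
        for node, data in net.nodes(data=True):
            out.add_node(node, domain=data.get("domain") or "")
        for u, v, data in net.edges(data=True):
            out.add_edge(u, v, rho=float(data["rho"]), sign=data["sign"])
        nx.write_graphml(out, path)
    elif format == "edge-list-tsv":
        rows = [
            {"otu_i": u, "otu_j": v,
             "domain_i": net.nodes[u].get("domain") or "",
             "domain_j": net.nodes[v].get("domain") or "",
             "rho": data["rho"], "sign": data["sign"]}
            for u, v, data in sorted(net.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["otu_i", "otu_j", "domain_i", "domain_j",
                                    "rho", "sign"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for node, data in g.nodes(data=True):
            out.add_node(node, domain=data.get("domain") or None)
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, rho=float(data["rho"]), sign=data["sign"])
        return out
    if format == "edge-list-tsv":
        df = pd.read_csv(path, sep="\t")
        out = nx.Graph()
        for row in df.itertuples(index=False):
            out.add_node(row.otu_i, domain=row.domain_i or None)
            out.add_node(row.otu_j, domain=row.domain_j or None)
            out.add_edge(row.otu_i, row.otu_j, rho=float(row.rho), sign=row.sign)
        return out
    raise ValueError(f"unknown format {format!r}")
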