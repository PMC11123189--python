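"""Co-occurrence networks: thresholded signed Spearman graphs, topology
metrics, and natural-connectivity robustness under node removal.

Edges connect taxa whose per-sample abundances correlate strongly
(|rho| > 0.6 by default) and significantly (BH-adjusted p < 0.01 by
default, following the conservative reading of the thresholds; raw-p mode
is available). Robustness is measured by natural connectivity,
nc = ln( (1/n) sum_i exp(lambda_i) ) over adjacency eigenvalues, as nodes
are removed at random or in descending-degree order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io_tables import ValidationError


def spearman_matrix(abund: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (mid-rank ties) and t-approximation p-values.

    ``abund`` is samples x taxa.
    """
    if abund.shape[0] < 5:
        raise ValidationError("need >= 5 samples for rank correlations")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho, p = stats.spearmanr(abund.to_numpy(), axis=0)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    if rho.shape == (1, 1):  # two-taxon case: spearmanr returns scalars
        r = float(rho[0, 0])
        pv = float(p[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    cols = abund.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def build_network(
    abund: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    adjust: str = "bh",
    prevalence_min: float = 1 / 3,
    drop_isolated: bool = True,
    group: str | None = None,
) -> nx.Graph:
    """Build a signed co-occurrence graph from a samples x taxa table.

    Taxa present in fewer than ``prevalence_min`` of the samples are
    dropped before correlation (all-zero vectors produce spurious tied
    correlations). Edge attributes: rho, p, q, sign; node attribute:
    mean abundance.
    """
    if adjust not in {"bh", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    prevalence = (abund > 0).mean(axis=0)
    kept = abund.loc[:, prevalence >= prevalence_min]
    if kept.shape[1] < 2:
        raise ValidationError("fewer than 2 taxa pass the prevalence filter")
    rho, p = spearman_matrix(kept)
    taxa = list(kept.columns)
    iu = np.triu_indices(len(taxa), k=1)
    pvals = p.to_numpy()[iu]
    rhos = rho.to_numpy()[iu]
    finite = np.isfinite(pvals) & np.isfinite(rhos)
    qvals = np.full(pvals.shape, np.nan)
    if adjust == "bh" and finite.any():
        qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    else:
        qvals = pvals
    G = nx.Graph(group=group, r_threshold=r_threshold, p_threshold=p_threshold)
    mean_ab = kept.mean(axis=0)
    for t in taxa:
        G.add_node(t, abundance=float(mean_ab[t]))
    for (i, j, r, pv, q) in zip(iu[0], iu[1], rhos, pvals, qvals):
        if np.isfinite(r) and np.isfinite(q) and abs(r) > r_threshold and q < p_threshold:
            G.add_edge(
                taxa[i], taxa[j], rho=float(r), p=float(pv), q=float(q),
                sign="positive" if r > 0 else "negative",
            )
    if drop_isolated:
        G.remove_nodes_from(list(nx.isolates(G)))
    return G


def node_topology(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, eigenvector centrality and
    clustering coefficient.

    Closeness is the harmonic form (well defined on disconnected graphs),
    normalized by n-1. Eigenvector centrality is computed on the largest
    connected component; nodes outside it get 0.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("need >= 2 nodes")
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=True)
    harmonic = {k: v / (n - 1) for k, v in nx.harmonic_centrality(net).items()}
    eigen = dict.fromkeys(net.nodes, 0.0)
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    giant = net.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        eigen.update(nx.eigenvector_centrality_numpy(giant))
    clustering = nx.clustering(net)
    return pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(harmonic),
            "eigenvector": pd.Series(eigen),
            "clustering": pd.Series(clustering),
        }
    ).sort_index()


def modularity(net: nx.Graph) -> tuple[float, list[set]]:
    """Greedy modularity maximization (deterministic agglomeration)."""
    if net.number_of_edges() == 0:
        return 0.0, [set(c) for c in nx.connected_components(net)]
    communities = [set(c) for c in nx.community.greedy_modularity_communities(net)]
    return float(nx.community.modularity(net, communities)), communities


def _centralization(values: np.ndarray, max_sum: float) -> float:
    if max_sum <= 0:
        return 0.0
    return float((values.max() - values).sum() / max_sum)


def network_topology(net: nx.Graph) -> dict:
    """Network-level topology metrics.

    Diameter and average path length are computed on the largest connected
    component; the complexity index is edges per node (linkage density);
    centralizations follow Freeman's formulas on normalized scores.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("need >= 2 nodes")
    e = net.number_of_edges()
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    giant = net.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diameter, apl = 0, 0.0
    q, communities = modularity(net)
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    betw = np.array(list(nx.betweenness_centrality(net, normalized=True).values()))
    deg_centralization = (
        _centralization(degrees, (n - 1.0) * (n - 2.0)) if n > 2 else 0.0
    )
    betw_centralization = _centralization(betw, n - 1.0)
    return {
        "nodes": n,
        "edges": e,
        "average_degree": 2.0 * e / n,
        "edge_density": 2.0 * e / (n * (n - 1)),
        "diameter": diameter,
        "average_path_length": apl,
        "average_clustering": nx.average_clustering(net),
        "modularity": q,
        "n_communities": len(communities),
        "complexity_index": e / n,
        "degree_centralization": deg_centralization,
        "betweenness_centralization": betw_centralization,
    }


def natural_connectivity(net: nx.Graph) -> float:
    """nc = ln( (1/n) sum_i exp(lambda_i) ), adjacency eigenvalues.

    Computed via a log-sum-exp so large spectra do not overflow. The
    edgeless graph gives exactly 0.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("need >= 2 nodes")
    A = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(A)
    return float(logsumexp(lam) - np.log(n))


@dataclass
class RobustnessCurve:
    strategy: str
    table: pd.DataFrame  # fraction, n_removed, natural_connectivity
    truncated: bool


def robustness_curve(
    net: nx.Graph,
    strategy: str = "random",
    fractions=None,
    n_repeats: int = 20,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity as a function of the fraction of nodes removed.

    ``random`` removes uniform node subsets without replacement, averaged
    over ``n_repeats``; ``degree`` removes nodes in descending-degree order
    (ties broken by node id, deterministic). The curve stops (flagged
    truncated) once fewer than 2 nodes would remain.
    """
    if strategy not in {"random", "degree"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    if fractions is None:
        fractions = np.arange(0.0, 0.91, 0.1)
    fractions = np.asarray(sorted(fractions), dtype=float)
    if fractions.min() < 0 or fractions.max() > 0.9:
        raise ValidationError("fractions must lie in [0, 0.9]")
    nodes = sorted(net.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    by_degree = sorted(nodes, key=lambda v: (-net.degree(v), v))
    rows = []
    truncated = False
    for frac in fractions:
        k = int(round(frac * n))
        if n - k < 2:
            truncated = True
            break
        if strategy == "degree":
            remaining = net.subgraph([v for v in nodes if v not in set(by_degree[:k])])
            nc = natural_connectivity(remaining)
        else:
            vals = []
            for _ in range(n_repeats):
                drop = set(rng.choice(n, size=k, replace=False))
                remaining = net.subgraph([v for i, v in enumerate(nodes) if i not in drop])
                vals.append(natural_connectivity(remaining))
            nc = float(np.mean(vals))
        rows.append({"fraction": frac, "n_removed": k, "natural_connectivity": nc})
    return RobustnessCurve(strategy, pd.DataFrame(rows), truncated)


def write_edge_list(net: nx.Graph, path) -> None:
    """Edge list TSV: source, target, rho, p, q, sign."""
    rows = [
        {"source": u, "target": v, **data} for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )
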