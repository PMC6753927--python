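"""Spearman co-occurrence networks and their topology metrics.

Edges connect OTU pairs whose Spearman correlation across samples is both
strong (|rho| strictly above the threshold, 0.7 by default) and significant
(p strictly below 0.01 by default).  Topology metrics follow the usual
"network analyzer" conventions: mean local clustering with degree-deficient
nodes counting 0, characteristic path length as the median over nodes of the
mean within-component shortest-path length, density 2E/(N(N-1)), and
heterogeneity as the coefficient of variation of the degree sequence.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig


def spearman_matrix(t) -> pd.DataFrame:
    """All pairwise Spearman correlations between OTU rows.

    Computed as Pearson correlation of midranks (average ranks for ties)
    taken within each OTU across samples.  OTUs constant across samples have
    undefined correlations; their entries are NaN and a warning names them.
    """
    arr = t.values
    n_otus, n_samples = arr.shape
    if n_samples < 4:
        raise ValueError(f"need >= 4 samples for correlation, got {n_samples}")
    if n_otus < 2:
        raise ValueError("need >= 2 OTUs")
    ranks = stats.rankdata(arr, axis=1)
    const = ranks.std(axis=1) == 0
    if const.any():
        warnings.warn(
            "constant OTU(s) have undefined correlations: "
            f"{[o for o, c in zip(t.otu_ids, const) if c]}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=t.otu_ids, columns=t.otu_ids)


def correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman rho via the t approximation.

    t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom; |rho| = 1
    returns 0 exactly (the statistic diverges).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if np.isnan(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def permutation_pvalue(x, y, n_perm: int = 9999, seed: int = 0) -> float:
    """Two-sided permutation p-value for Spearman rho between two vectors.

    Enumerates all n! permutations when n <= 8 (exact, no pseudocount);
    otherwise samples ``n_perm`` permutations with the +1 correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    obs = abs(_pearson(rx_c, ry - ry.mean()))
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(_pearson(rx_c, ry[list(perm)] - ry.mean()))
            count += r >= obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    yp = ry[perms] - ry.mean()
    r = np.abs(yp @ rx_c / (np.linalg.norm(yp, axis=1) * np.linalg.norm(rx_c)))
    return float((1 + np.sum(r >= obs - 1e-12)) / (1 + n_perm))


def _pearson(xc, yc) -> float:
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def pvalue_matrix(t, rho: pd.DataFrame | None = None,
                  method: str = "t_approx", n_perm: int = 9999,
                  seed: int = 0) -> pd.DataFrame:
    """P-values for every OTU pair, matching :func:`spearman_matrix` layout."""
    if rho is None:
        rho = spearman_matrix(t)
    n = t.shape[1]
    if method == "t_approx":
        r = rho.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
            p = 2.0 * stats.t.sf(np.abs(tt), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        p = np.where(np.isnan(r), np.nan, p)
        np.fill_diagonal(p, 0.0)
        return pd.DataFrame(p, index=rho.index, columns=rho.columns)
    if method == "exact_perm":
        ids = t.otu_ids
        arr = t.values
        p = np.zeros((len(ids), len(ids)))
        rng = np.random.default_rng(seed)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pij = permutation_pvalue(arr[i], arr[j], n_perm=n_perm,
                                         seed=int(rng.integers(2**31 - 1)))
                p[i, j] = p[j, i] = pij
        return pd.DataFrame(p, index=ids, columns=ids)
    raise ValueError(f"unknown p-value method {method!r}")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values for a flat vector (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def build_network(rho: pd.DataFrame, pvals: pd.DataFrame,
                  cfg: AnalysisConfig | None = None, kind_label: str = "",
                  taxonomy: dict | None = None) -> nx.Graph:
    """Assemble the thresholded co-occurrence network.

    An edge exists iff |rho| > rho_threshold and p < p_threshold (both
    strict).  Nodes without any retained edge are excluded.  Edge attributes:
    ``rho``, ``p`` and ``sign`` ("positive"/"negative").
    """
    cfg = cfg or AnalysisConfig()
    r = rho.to_numpy()
    p = pvals.to_numpy()
    if cfg.apply_bh_correction:
        iu = np.triu_indices_from(p, 1)
        flat = benjamini_hochberg(p[iu])
        p = p.copy()
        p[iu] = flat
        p[(iu[1], iu[0])] = flat
    ids = list(rho.index)
    with np.errstate(invalid="ignore"):
        mask = (np.abs(r) > cfg.rho_threshold) & (p < cfg.p_threshold)
    mask &= np.isfinite(r) & np.isfinite(p)
    g = nx.Graph(kind_label=kind_label)
    iu = np.triu_indices(len(ids), 1)
    sel = mask[iu]
    for i, j in zip(iu[0][sel], iu[1][sel]):
        rij = float(r[i, j])
        g.add_edge(ids[i], ids[j], rho=rij, p=float(p[i, j]),
                   sign="positive" if rij > 0 else "negative")
    if g.number_of_edges() == 0:
        warnings.warn("no edge passed the correlation thresholds; "
                      "network is empty", stacklevel=2)
    if taxonomy:
        for node in g.nodes:
            if node in taxonomy:
                g.nodes[node]["lineage"] = taxonomy[node]
    return g


# --- topology metrics --------------------------------------------------------

def clustering_coefficient(net: nx.Graph, count_zeros: bool = True) -> float:
    """Mean local clustering coefficient 2*e_n / (k_n*(k_n-1)).

    Nodes with degree < 2 contribute 0 when ``count_zeros`` (the common
    network-analyzer convention) or are excluded otherwise.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(net, count_zeros=count_zeros))


def characteristic_path_length(net: nx.Graph) -> float:
    """Median over nodes of the mean shortest-path length to reachable nodes.

    Path lengths are unweighted; each node's mean is taken within its
    connected component only (disconnected pairs are excluded), and isolated
    nodes are left out of the median.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    means = []
    n_components = 0
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        n_components += 1
        sub = net.subgraph(comp)
        for node in sub:
            lengths = nx.single_source_shortest_path_length(sub, node)
            means.append((sum(lengths.values())) / (len(comp) - 1))
    if not means:
        raise ValueError("characteristic path length undefined: all nodes isolated")
    if n_components > 1 or len(means) < net.number_of_nodes():
        import logging
        logging.getLogger(__name__).info(
            "CPL computed within components (%d non-trivial); disconnected "
            "pairs excluded", n_components)
    return float(np.median(means))


def network_density(net: nx.Graph) -> float:
    """2E / (N(N-1)); a single-node graph has density 0 by convention."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        return 0.0
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def network_heterogeneity(net: nx.Graph) -> float:
    """Coefficient of variation of the degree sequence (population variance)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = np.array([d for _, d in net.degree()], dtype=float)
    mean = deg.mean()
    if mean == 0:
        raise ValueError("heterogeneity undefined: mean degree is 0")
    return float(np.sqrt(deg.var()) / mean)


@dataclass
class TopologySummary:
    """The standard whole-network descriptors of a co-occurrence network."""

    n_nodes: int
    n_edges_total: int
    n_edges_positive: int
    n_edges_negative: int
    clustering_coefficient: Optional[float]
    characteristic_path_length: Optional[float]
    density: Optional[float]
    heterogeneity: Optional[float]
    modularity: Optional[float]

    ROW_LABELS = (
        ("n_nodes", "Number of nodes"),
        ("n_edges_total", "Number of edges (in total)"),
        ("n_edges_positive", "Number of edges (positive)"),
        ("n_edges_negative", "Number of edges (negative)"),
        ("clustering_coefficient", "Clustering coefficient"),
        ("characteristic_path_length", "Characteristic path length"),
        ("density", "Network density"),
        ("heterogeneity", "Network heterogeneity"),
        ("modularity", "Modularity"),
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, getattr(self, attr)) for attr, label in self.ROW_LABELS]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def topology_summary(net: nx.Graph, partition=None) -> TopologySummary:
    """Fill all topology fields; metric errors on degenerate graphs surface
    as absent (None) fields rather than exceptions."""
    signs = [d.get("sign") for _, _, d in net.edges(data=True)]
    n_pos = sum(s == "positive" for s in signs)
    n_neg = sum(s == "negative" for s in signs)

    def _try(fn):
        try:
            return fn(net)
        except ValueError:
            return None

    return TopologySummary(
        n_nodes=net.number_of_nodes(),
        n_edges_total=net.number_of_edges(),
        n_edges_positive=n_pos,
        n_edges_negative=n_neg,
        clustering_coefficient=_try(clustering_coefficient),
        characteristic_path_length=_try(characteristic_path_length),
        density=_try(network_density),
        heterogeneity=_try(network_heterogeneity),
        modularity=None if partition is None else partition.q,
    )
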