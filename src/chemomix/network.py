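"""Significance-gated Spearman correlation networks.

Among the analytes that differ significantly between treatments,
pairwise Spearman rank correlations (mid-ranks for ties, samples from
both treatments pooled) are tested two-sided and family-wise corrected
by Holm's step-down procedure over all analyte pairs.  Pairs surviving
the gate become signed undirected edges.  Clusters are the connected
components (size >= 2), and the "central network" annotation is the
k-core (k=3 by default): the maximal subgraph in which every compound
is correlated to at least three others.

Because Holm over thousands of pairs puts the per-pair level at
1e-5 .. 1e-6, where the usual t approximation
t = rho * sqrt((n-2)/(1-rho^2)) understates the true tail probability
several-fold for a dozen samples, tie-free pairs at n <= 13 are tested
against the *exact* permutation null of the rank statistic
S = sum d_i^2 (computed once per n by dynamic programming); pairs with
ties, or larger n, fall back to the t approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalyteTable, ValidationError


@dataclass(frozen=True)
class CorrelationEdge:
    analyte_a: str  # lexicographically smaller id
    analyte_b: str
    rho: float
    p: float
    p_holm: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho >= 0 else "negative"


@dataclass
class CorrelationNetwork:
    edges: list[CorrelationEdge]
    nodes: set[str] = field(default_factory=set)  # isolated analytes excluded
    alpha: float = 0.05

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        for e in self.edges:
            G.add_edge(e.analyte_a, e.analyte_b, rho=e.rho, p_holm=e.p_holm,
                       sign=e.sign)
        return G

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self.edges if e.sign == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e.sign == "negative")


@dataclass
class NetworkClusters:
    components: list[set[str]]  # connected components, size >= 2, largest first
    core_nodes: set[str]  # union of per-component k-cores
    degree: dict[str, int]
    k: int = 3


_EXACT_N_MAX = 13


@lru_cache(maxsize=8)
def _spearman_s_null_cdf(n: int) -> np.ndarray:
    """CDF of S = sum (i - pi(i))^2 over all permutations of range(n).

    Computed by a subset dynamic programme: positions are filled in
    order, the bitmask tracks which ranks are used, and the value array
    counts permutations by partial S.
    """
    smax = n * (n * n - 1) // 3
    f = [None] * (1 << n)
    f[0] = np.zeros(smax + 1)
    f[0][0] = 1.0
    for mask in range(1, 1 << n):
        k = mask.bit_count() - 1  # position being assigned (0-based)
        acc = np.zeros(smax + 1)
        m = mask
        while m:
            j = (m & -m).bit_length() - 1
            d2 = (k - j) ** 2
            prev = f[mask ^ (1 << j)]
            if d2 == 0:
                acc += prev
            else:
                acc[d2:] += prev[:-d2]
            m &= m - 1
        f[mask] = acc
    pmf = f[(1 << n) - 1] / math.factorial(n)
    return np.cumsum(pmf)


def exact_spearman_p(rho: float, n: int) -> float:
    """Exact two-sided p for a tie-free Spearman rho at sample size n."""
    if not 4 <= n <= _EXACT_N_MAX:
        raise ValidationError(f"exact null available for 4 <= n <= {_EXACT_N_MAX}")
    smax = n * (n * n - 1) // 3
    s = (1.0 - rho) * smax / 2.0
    s_obs = int(round(s / 2.0)) * 2  # S is always even
    s_obs = min(max(s_obs, 0), smax)
    cdf = _spearman_s_null_cdf(n)
    lo = min(s_obs, smax - s_obs)
    # two-sided: both tails at |rho| >= observed (null symmetric about S = smax/2)
    return float(min(1.0, 2.0 * cdf[lo]))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))


def spearman_matrix(
    table: AnalyteTable | pd.DataFrame,
    p_method: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p over all samples.

    ``p_method``: "exact" (permutation null; tie-free, n <= 13 only),
    "t" (t approximation), or "auto" (exact where valid, t otherwise).
    Constant analytes (undefined rank correlation) are dropped with a
    warning.  Requires >= 4 samples and >= 2 analytes.
    """
    if p_method not in ("auto", "exact", "t"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    X = table.filled(0.0) if isinstance(table, AnalyteTable) else table
    n = X.shape[1]
    if n < 4:
        raise ValidationError("Spearman matrix needs >= 4 samples")
    constant = X.index[X.nunique(axis=1) <= 1].tolist()
    if constant:
        warnings.warn(
            f"constant analytes skipped in correlation: {constant}", stacklevel=2
        )
        X = X.drop(index=constant)
    if X.shape[0] < 2:
        raise ValidationError("Spearman matrix needs >= 2 non-constant analytes")

    values = X.to_numpy(dtype=float)
    ranks = stats.rankdata(values, axis=1)
    rho = np.corrcoef(ranks)
    p = _t_approx_p(rho, n)

    exact_ok = n <= _EXACT_N_MAX and p_method in ("auto", "exact")
    if exact_ok:
        tie_free = np.array([len(np.unique(row)) == n for row in values])
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                if tie_free[i] and tie_free[j]:
                    p[i, j] = p[j, i] = exact_spearman_p(rho[i, j], n)
                elif p_method == "exact":
                    raise ValidationError(
                        "exact Spearman p requires tie-free data"
                    )
    elif p_method == "exact":
        raise ValidationError(
            f"exact Spearman p requires 4 <= n <= {_EXACT_N_MAX}"
        )
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=X.index, columns=X.index),
        pd.DataFrame(p, index=X.index, columns=X.index),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    a = p[order] * (m - np.arange(m))
    a = np.maximum.accumulate(a)
    out = np.empty(m)
    out[order] = np.minimum(a, 1.0)
    return out


def holm_adjust_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """Holm adjustment over the upper triangle of a symmetric p matrix
    (family = all analyte pairs)."""
    iu = np.triu_indices(p.shape[0], k=1)
    flat = p.to_numpy()[iu]
    adj = holm_adjust(flat)
    out = np.zeros_like(p.to_numpy())
    out[iu] = adj
    out = out + out.T
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def build_network(
    rho: pd.DataFrame, p_holm: pd.DataFrame, alpha: float = 0.05
) -> CorrelationNetwork:
    """Edges for every analyte pair with Holm-adjusted p < alpha."""
    if not rho.index.equals(p_holm.index) or not rho.columns.equals(p_holm.columns):
        raise ValidationError("rho and p matrices are not conformal")
    edges = []
    ids = list(rho.index)
    R = rho.to_numpy()
    P = p_holm.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(R[i, j]):
                continue
            if P[i, j] < alpha:
                a, b = sorted((ids[i], ids[j]))
                edges.append(
                    CorrelationEdge(
                        analyte_a=a,
                        analyte_b=b,
                        rho=float(R[i, j]),
                        p=np.nan,
                        p_holm=float(P[i, j]),
                    )
                )
    nodes = {e.analyte_a for e in edges} | {e.analyte_b for e in edges}
    return CorrelationNetwork(edges=sorted(edges, key=lambda e: (e.analyte_a, e.analyte_b)),
                              nodes=nodes, alpha=alpha)


def extract_clusters(network: CorrelationNetwork, k: int = 3) -> NetworkClusters:
    """Connected components (size >= 2) and the degree->=k core.

    Components reproduce small 2- and 3-compound clusters; the k-core
    (iteratively deleting nodes of within-subgraph degree < k) marks the
    densely inter-correlated "central network" nodes.
    """
    G = network.graph()
    components = sorted(
        (set(c) for c in nx.connected_components(G) if len(c) >= 2),
        key=lambda c: (-len(c), sorted(c)),
    )
    core = set(nx.k_core(G, k).nodes) if G.number_of_nodes() else set()
    return NetworkClusters(
        components=components,
        core_nodes=core,
        degree=dict(G.degree()),
        k=k,
    )


def significance_gated_network(
    table: AnalyteTable,
    significant: list[str],
    alpha: float = 0.05,
    k: int = 3,
) -> tuple[CorrelationNetwork, NetworkClusters, pd.DataFrame, pd.DataFrame]:
    """Full chain: restrict to significant analytes, correlate, Holm-gate,
    build the network and extract clusters.

    Returns (network, clusters, rho matrix, Holm-adjusted p matrix).
    """
    sub = table.subset_analytes([a for a in table.analyte_ids if a in set(significant)])
    rho, p = spearman_matrix(sub)
    p_holm = holm_adjust_matrix(p)
    net = build_network(rho, p_holm, alpha)
    # carry raw p onto edges
    edges = [
        CorrelationEdge(
            analyte_a=e.analyte_a,
            analyte_b=e.analyte_b,
            rho=e.rho,
            p=float(p.loc[e.analyte_a, e.analyte_b]),
            p_holm=e.p_holm,
        )
        for e in net.edges
    ]
    net = CorrelationNetwork(edges=edges, nodes=net.nodes, alpha=alpha)
    return net, extract_clusters(net, k), rho, p_holm


def export_graph(
    network: CorrelationNetwork,
    clusters: NetworkClusters,
    fmt: str,
    path: str | Path,
) -> Path:
    """Export as SIF ("a pos b" / "a neg b") or attribute-rich GraphML."""
    path = Path(path)
    if fmt == "SIF":
        lines = [
            f"{e.analyte_a}\t{'pos' if e.sign == 'positive' else 'neg'}\t{e.analyte_b}"
            for e in network.edges
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path
    if fmt == "GraphML":
        G = nx.Graph()
        comp_of = {
            n: idx for idx, comp in enumerate(clusters.components) for n in comp
        }
        for n in network.nodes:
            G.add_node(
                n,
                degree=clusters.degree.get(n, 0),
                component=comp_of.get(n, -1),
                in_core=n in clusters.core_nodes,
            )
        for e in network.edges:
            G.add_edge(
                e.analyte_a,
                e.analyte_b,
                rho=e.rho,
                p_holm=e.p_holm,
                sign=e.sign,
            )
        nx.write_graphml(G, path)
        return path
    raise ValidationError(f"unknown export format {fmt!r}")


def write_edges(network: CorrelationNetwork, path: str | Path) -> Path:
    rows = [
        {
            "analyte_a": e.analyte_a,
            "analyte_b": e.analyte_b,
            "rho": e.rho,
            "p": e.p,
            "p_holm": e.p_holm,
            "sign": e.sign,
        }
        for e in network.edges
    ]
    path = Path(path)
    pd.DataFrame(
        rows, columns=["analyte_a", "analyte_b", "rho", "p", "p_holm", "sign"]
    ).to_csv(path, index=False)
    return path


def write_clusters(clusters: NetworkClusters, path: str | Path) -> Path:
    rows = []
    for idx, comp in enumerate(clusters.components):
        for node in sorted(comp):
            rows.append(
                {
                    "analyte": node,
                    "component": idx,
                    "component_size": len(comp),
                    "degree": clusters.degree.get(node, 0),
                    "in_core": node in clusters.core_nodes,
                }
            )
    path = Path(path)
    pd.DataFrame(
        rows, columns=["analyte", "component", "component_size", "degree", "in_core"]
    ).to_csv(path, index=False)
    return path
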