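"""Gene-by-gene cofitness networks.

Cofitness is the correlation of two genes' knockout fitness effects
across environments, weighted by measurement error — correlated fitness
profiles can indicate shared regulation or function.  Because only a
handful of environments are measured, apparent correlations arise easily
by chance; each pair is therefore tested against a resampled null
(permutation plus parametric bootstrap of the fitness estimates), edges
are called by BH-FDR, and the resulting unweighted graph is partitioned
into communities with the fluid-communities algorithm, keeping the
partition of highest Newman-Girvan modularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import asyn_fluidc, modularity

from .inference import FitnessMatrix, fdr_correct

__all__ = [
    "weighted_pearson",
    "cofitness_pair",
    "cofitness_matrix",
    "edge_null_pvalues",
    "build_network",
    "detect_communities",
    "cluster_overlap",
    "CofitnessNetwork",
]


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with common per-observation weights.

    mu(x)   = sum w x / sum w
    wcov    = sum w (x - mu(x)) (y - mu(y)) / sum w
    rho     = wcov(x,y) / sqrt(wcov(x,x) wcov(y,y))

    Undefined (NaN) when either weighted variance vanishes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cxy = np.sum(w * (x - mx) * (y - my)) / wsum
    cxx = np.sum(w * (x - mx) ** 2) / wsum
    cyy = np.sum(w * (y - my) ** 2) / wsum
    if cxx == 0 or cyy == 0:
        return np.nan
    return float(cxy / np.sqrt(cxx * cyy))


def cofitness_pair(sx, sy, varx, vary) -> float:
    """Cofitness of two genes: weighted Pearson with w_k = 1/(var_x + var_y)."""
    return weighted_pearson(sx, sy, 1.0 / (np.asarray(varx) + np.asarray(vary)))


def _included_genes(fm: FitnessMatrix, min_experiments: int = 4) -> list[str]:
    """Genes significantly non-neutral somewhere and measured in >=4
    experiments."""
    ok = fm.ever_significant() & (fm.n_measured() >= min_experiments)
    return list(fm.genes[ok])


def cofitness_matrix(
    fm: FitnessMatrix, min_experiments: int = 4, min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise cofitness over shared environments, after inclusion filters.

    Pairs sharing fewer than ``min_shared`` measured environments are NaN.
    """
    genes = _included_genes(fm, min_experiments)
    S = fm.s.loc[genes].to_numpy(float)
    V = fm.var.loc[genes].to_numpy(float)
    n = len(genes)
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.isfinite(S[i]) & np.isfinite(S[j])
            if shared.sum() < min_shared:
                continue
            rho[i, j] = rho[j, i] = cofitness_pair(
                S[i, shared], S[j, shared], V[i, shared], V[j, shared]
            )
    return pd.DataFrame(rho, index=genes, columns=genes)


def edge_null_pvalues(
    sx, sy, sex, sey,
    n_resample: int = 300,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> tuple[float, float]:
    """One-sided resampling p-value for a gene pair's cofitness.

    The null re-draws each fitness as N(s_hat, se) (parametric
    bootstrap), independently permutes both genes' environment
    assignments, and recomputes cofitness; p is the plus-one-corrected
    fraction of null values at least as large as observed (or as extreme,
    if ``two_sided``).  Returns (rho_observed, p).
    """
    sx = np.asarray(sx, float)
    sy = np.asarray(sy, float)
    sex = np.asarray(sex, float)
    sey = np.asarray(sey, float)
    if rng is None:
        rng = np.random.default_rng()
    w = 1.0 / (sex**2 + sey**2)
    obs = weighted_pearson(sx, sy, w)
    n = len(sx)
    exceed = 0
    for _ in range(n_resample):
        px = rng.permutation(n)
        py = rng.permutation(n)
        bx = rng.normal(sx[px], sex[px])
        by = rng.normal(sy[py], sey[py])
        null = weighted_pearson(bx, by, 1.0 / (sex[px] ** 2 + sey[py] ** 2))
        if np.isnan(null):
            continue
        if (abs(null) >= abs(obs)) if two_sided else (null >= obs):
            exceed += 1
    p = (exceed + 1) / (n_resample + 1)
    return obs, p


@dataclass
class CofitnessNetwork:
    graph: nx.Graph
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    communities: dict | None = None  # gene -> community label
    modularity: float = np.nan

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "rho": self.rho.at[a, b],
                "p": self.p.at[a, b],
                "q": self.q.at[a, b],
            }
            for a, b in self.graph.edges
        ]
        return pd.DataFrame(rows)

    def community_table(self) -> pd.DataFrame:
        if self.communities is None:
            raise ValueError("communities not yet detected")
        return pd.DataFrame(
            {
                "gene": list(self.communities),
                "community": list(self.communities.values()),
                "modularity": self.modularity,
            }
        )


def build_network(
    fm: FitnessMatrix,
    n_resample: int = 300,
    alpha: float = 0.05,
    min_experiments: int = 4,
    min_shared: int = 3,
    seed: int = 0,
) -> CofitnessNetwork:
    """Cofitness matrix + null tests + BH edge calls in one pass."""
    genes = _included_genes(fm, min_experiments)
    S = fm.s.loc[genes]
    SE = fm.se.loc[genes]
    rng = np.random.default_rng(seed)
    n = len(genes)
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    pmat = np.full((n, n), np.nan)
    pairs = []
    pvals = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = S.iloc[i].notna() & S.iloc[j].notna()
            if shared.sum() < min_shared:
                continue
            r, p = edge_null_pvalues(
                S.iloc[i][shared], S.iloc[j][shared],
                SE.iloc[i][shared], SE.iloc[j][shared],
                n_resample=n_resample, rng=rng,
            )
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
            pairs.append((i, j))
            pvals.append(p)
    qmat = np.full((n, n), np.nan)
    G = nx.Graph()
    G.add_nodes_from(genes)
    if pairs:
        q, reject = fdr_correct(pvals, alpha=alpha)
        for (i, j), qv, rej in zip(pairs, q, reject):
            qmat[i, j] = qmat[j, i] = qv
            if rej:
                G.add_edge(genes[i], genes[j], rho=rho[i, j])
    mk = lambda m: pd.DataFrame(m, index=genes, columns=genes)
    return CofitnessNetwork(G, mk(rho), mk(pmat), mk(qmat))


def detect_communities(
    graph: nx.Graph,
    k_range: tuple[int, int] = (4, 20),
    reps_per_k: int = 200,
    seed: int = 0,
) -> tuple[dict, float]:
    """Best-modularity fluid-communities partition of the edge graph.

    Edges are treated as unweighted.  The stochastic fluid algorithm is
    restarted ``reps_per_k`` times for every community count k in
    ``k_range`` (clipped per connected component); the partition with
    the highest Newman-Girvan modularity wins.  Isolated nodes become
    singleton communities.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    rng = np.random.default_rng(seed)
    labels: dict = {}
    next_label = 0
    chosen_comms: list[set] = []
    components = list(nx.connected_components(graph))
    n_nontrivial = sum(1 for c in components if len(c) > 1)
    for comp_nodes in components:
        comp = graph.subgraph(comp_nodes).copy()
        if comp.number_of_nodes() == 1:
            labels[next(iter(comp_nodes))] = next_label
            next_label += 1
            continue
        # the requested k range applies to a connected graph; a
        # disconnected one is partitioned per component, where a single
        # community must be allowed (the global community count is then
        # at least the component count)
        k_lo = (
            max(1, min(k_range[0], comp.number_of_nodes()))
            if n_nontrivial == 1
            else 1
        )
        k_hi = min(k_range[1], comp.number_of_nodes())
        best_q, best = -np.inf, None
        for k in range(k_lo, k_hi + 1):
            for _ in range(reps_per_k):
                parts = list(
                    asyn_fluidc(comp, k, seed=int(rng.integers(2**31)))
                )
                qv = modularity(comp, parts)
                if qv > best_q:
                    best_q, best = qv, parts
        for part in best:
            for node in part:
                labels[node] = next_label
            next_label += 1
        chosen_comms.extend(best)
    # modularity of the full partition on the full graph
    by_label: dict = {}
    for node, lab in labels.items():
        by_label.setdefault(lab, set()).add(node)
    q_total = modularity(graph, list(by_label.values()))
    return labels, float(q_total)


def cluster_overlap(partition_a: dict, partition_b: dict) -> float:
    """P(two genes share a community in B | they share one in A).

    Evaluated over all gene pairs present in both partitions; undefined
    (raises) when no pair is together in A.
    """
    common = sorted(set(partition_a) & set(partition_b))
    if not common:
        raise ValueError("partitions share no genes")
    together_a = 0
    together_both = 0
    for i in range(len(common)):
        for j in range(i + 1, len(common)):
            a, b = common[i], common[j]
            if partition_a[a] == partition_a[b]:
                together_a += 1
                if partition_b[a] == partition_b[b]:
                    together_both += 1
    if together_a == 0:
        raise ValueError("no gene pair shares a community in partition A")
    return together_both / together_a
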