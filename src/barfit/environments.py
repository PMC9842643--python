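"""Similarity of fitness effects across environments.

Environments are compared by the error-weighted correlation of knockout
fitness effects across genes, clustered hierarchically (Ward linkage on
1 - rho, negative correlations clipped to zero distance-wise), with
clade support from a gene bootstrap, and summarized by PCA of
quantile-normalized fitness profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.preprocessing import quantile_transform

from .cofitness import weighted_pearson
from .inference import FitnessMatrix

__all__ = [
    "environment_correlation",
    "cluster_environments",
    "bootstrap_support",
    "pca_environments",
    "EnvironmentTree",
]


def environment_correlation(
    fm: FitnessMatrix,
    se_cutoff: float = 0.01,
    min_shared: int = 3,
    pairwise_filter: bool = True,
) -> pd.DataFrame:
    """Environment x environment weighted Pearson correlation of fitness.

    Genes with noisy estimates (SE > ``se_cutoff``, i.e. >1% by default)
    are removed — per pair when ``pairwise_filter`` (a gene noisy in
    either member drops from that pair only), globally otherwise.
    Weights are 1/(var_i + var_j) per gene.  Pairs sharing fewer than
    ``min_shared`` clean genes are NaN.
    """
    envs = fm.environments
    S = fm.s
    V = fm.var
    clean = fm.se.le(se_cutoff)
    if not pairwise_filter:
        keep = clean.all(axis=1)
        S, V, clean = S[keep], V[keep], clean[keep]
    n = len(envs)
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (
                S[envs[i]].notna() & S[envs[j]].notna()
                & clean[envs[i]] & clean[envs[j]]
            )
            if ok.sum() < min_shared:
                continue
            w = 1.0 / (V.loc[ok, envs[i]] + V.loc[ok, envs[j]])
            rho[i, j] = rho[j, i] = weighted_pearson(
                S.loc[ok, envs[i]], S.loc[ok, envs[j]], w
            )
    return pd.DataFrame(rho, index=envs, columns=envs)


@dataclass
class EnvironmentTree:
    """Ward dendrogram over environments with per-clade bootstrap support."""

    linkage_matrix: np.ndarray
    labels: list[str]
    support: dict | None = None  # frozenset(leaves) -> support in [0,1]
    method: str = "ward"

    def clades(self) -> list[frozenset]:
        """Leaf sets of all internal nodes (including the root)."""
        tree = to_tree(self.linkage_matrix)
        out = []

        def walk(node):
            if node.is_leaf():
                return frozenset([self.labels[node.id]])
            leaves = walk(node.left) | walk(node.right)
            out.append(frozenset(leaves))
            return leaves

        walk(tree)
        return out

    def newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            sup = ""
            if self.support is not None:
                leaves = frozenset(
                    self.labels[i] for i in node.pre_order(lambda x: x.id)
                )
                if leaves in self.support:
                    sup = f"{self.support[leaves]:.3f}"
            return (
                f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
                f"{sup}:{length:.6g}"
            )

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def _ward_tree(rho: pd.DataFrame) -> EnvironmentTree:
    d = 1.0 - np.clip(rho.to_numpy(float), 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = np.nan_to_num(d, nan=1.0)  # unmeasurable pairs: maximally distant
    Z = linkage(squareform(d, checks=False), method="ward")
    return EnvironmentTree(Z, list(rho.index))


def cluster_environments(rho: pd.DataFrame) -> EnvironmentTree:
    """Ward hierarchical clustering with distance 1 - max(rho, 0).

    Negative correlations (rare and small in this setting) are clipped
    to distance 1.  Ties resolve deterministically by scipy's linkage
    ordering, i.e. by label order of the input matrix.
    """
    return _ward_tree(rho)


def bootstrap_support(
    fm: FitnessMatrix,
    n_boot: int = 1000,
    se_cutoff: float = 0.01,
    rng: np.random.Generator | None = None,
) -> EnvironmentTree:
    """Gene-bootstrap support for every clade of the environment tree.

    Uses only the intersection of genes that pass the noise filter in
    all environments, so every bootstrap replicate correlates the same
    gene universe.  Support of a clade is the fraction of bootstrap
    trees containing a clade with the identical leaf set.
    """
    keep = (fm.se.le(se_cutoff) & fm.s.notna()).all(axis=1)
    sub_s = fm.s[keep]
    sub_v = fm.var[keep]
    envs = fm.environments
    if len(sub_s) < 3:
        raise ValueError("fewer than 3 genes pass the filter in all environments")

    def tree_from(idx) -> EnvironmentTree:
        S = sub_s.to_numpy(float)[idx]
        V = sub_v.to_numpy(float)[idx]
        n = len(envs)
        rho = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                w = 1.0 / (V[:, i] + V[:, j])
                rho[i, j] = rho[j, i] = weighted_pearson(S[:, i], S[:, j], w)
        return _ward_tree(pd.DataFrame(rho, index=envs, columns=envs))

    base = tree_from(np.arange(len(sub_s)))
    clades = base.clades()
    hits = {c: 0 for c in clades}
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(n_boot):
        idx = rng.integers(0, len(sub_s), size=len(sub_s))
        boot_clades = set(tree_from(idx).clades())
        for c in clades:
            if c in boot_clades:
                hits[c] += 1
    base.support = {c: hits[c] / n_boot for c in clades}
    return base


def pca_environments(
    fm: FitnessMatrix, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of normalized fitness profiles.

    Only genes measured in every environment enter.  Each environment's
    fitness column is quantile-transformed to a Gaussian and then
    standardized, so that the scale of effects is comparable across
    conditions; PCA scores are returned per environment (environments
    as samples, genes as features) together with explained-variance
    fractions over all components.
    """
    complete = fm.s.dropna(axis=0)
    if complete.empty:
        raise ValueError("no gene measured across all environments")
    X = quantile_transform(
        complete.to_numpy(float),
        output_distribution="normal",
        n_quantiles=min(len(complete), 1000),
        copy=True,
    )
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X.T)  # environments as samples
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=fm.environments, columns=cols),
        pca.explained_variance_ratio_,
    )
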