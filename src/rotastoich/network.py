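"""Compositional co-occurrence networks via the SparCC procedure.

SparCC (sparse compositional correlation) estimates correlations between
the unobserved basis abundances underlying a closed (compositional)
count matrix.  From component fractions ``x_i`` it forms the log-ratio
variation matrix ``T_ij = var(log(x_i / x_j))`` and, under the
assumption that the average correlation is small (sparsity), solves the
linear system

    t_i = sum_j T_ij = (D - 2) * w_i^2 + sum_j w_j^2

for the basis variances ``w_i^2``, giving

    rho_ij = (w_i^2 + w_j^2 - T_ij) / (2 w_i w_j),

clipped to [-1, 1].  Strongly correlated pairs violate the sparsity
assumption, so the pair with the largest |rho| above an exclusion
threshold is iteratively removed from the system and the variances
re-solved (up to ``max_exclusions`` pairs).

Zeros are handled with a pseudocount of 1 by default; a Dirichlet
resampling mode (alpha = count + 1, median over inner iterations) is
available.  Edge significance comes from a permutation null (each
taxon's counts shuffled independently across samples), Benjamini–
Hochberg adjusted over the upper triangle; the published retention rule
|rho| > 0.6 and q < 0.01 is the default threshold pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeding import substream
from .synthetic import CountMatrix

__all__ = [
    "CorrelationEstimate",
    "NetworkTopology",
    "sparcc_correlations",
    "permutation_pvalues",
    "bh_fdr",
    "build_network",
    "topology",
    "aggregate_taxa",
]


@dataclass
class CorrelationEstimate:
    rho: pd.DataFrame
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    method: str = "pseudocount"
    n_inner_iterations: int = 1
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    transitivity: float
    density: float
    modularity: float
    empty: bool = False


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """T_ij = var(log(x_i / x_j)) across samples; fractions: taxa x samples."""
    logf = np.log(fractions)
    d = logf[:, None, :] - logf[None, :, :]
    return d.var(axis=2, ddof=1)


def _basis_rho(t_mat: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve the sparsity system for basis variances and return rho."""
    d = t_mat.shape[0]
    m = np.ones((d, d))
    np.fill_diagonal(m, d - 2)
    t_eff = t_mat.copy()
    for i, j in excluded:
        t_eff[i, j] = t_eff[j, i] = 0.0
        m[i, j] -= 1
        m[j, i] -= 1
        m[i, i] -= 1
        m[j, j] -= 1
    t_vec = t_eff.sum(axis=1)
    omega2 = np.linalg.solve(m, t_vec)
    omega2 = np.clip(omega2, 1e-12, None)
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t_mat) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_single(fractions: np.ndarray, exclusion_threshold: float,
                   max_exclusions: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    t_mat = _variation_matrix(fractions)
    excluded: set[tuple[int, int]] = set()
    rho = _basis_rho(t_mat, excluded)
    for _ in range(max_exclusions):
        off = np.abs(rho).copy()
        np.fill_diagonal(off, 0.0)
        for i, j in excluded:
            off[i, j] = off[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(off)), off.shape)
        if off[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        rho = _basis_rho(t_mat, excluded)
    return rho, sorted(excluded)


def sparcc_correlations(
    m: CountMatrix,
    n_inner_iterations: int = 20,
    exclusion_threshold: float = 0.8,
    max_exclusions: int | None = None,
    method: str = "pseudocount",
    seed: int = 0,
) -> CorrelationEstimate:
    """SparCC correlation estimate for a taxa × sample count matrix.

    ``method="pseudocount"`` (default, deterministic) forms fractions as
    (count + 1) / (depth + n_taxa); ``method="dirichlet"`` draws
    fractions from Dirichlet(count + 1) ``n_inner_iterations`` times and
    returns the elementwise median.  Needs ≥4 taxa (the basis system is
    underdetermined below that) and ≥5 samples.
    """
    counts = m.counts.to_numpy(dtype=float)
    d, n = counts.shape
    if d < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if n < 5:
        raise ValueError("SparCC needs at least 5 samples")
    if (counts.std(axis=0) == 0).any():
        raise ValueError("degenerate sample with all-equal counts")
    if max_exclusions is None:
        max_exclusions = d // 3

    if method == "pseudocount":
        fracs = (counts + 1.0) / (counts + 1.0).sum(axis=0, keepdims=True)
        rho, excl = _sparcc_single(fracs, exclusion_threshold, max_exclusions)
        n_iter = 1
    elif method == "dirichlet":
        rng = substream(seed, "sparcc_dirichlet")
        rhos = []
        excl = []
        for _ in range(n_inner_iterations):
            fracs = np.empty_like(counts)
            for s in range(n):
                fracs[:, s] = rng.dirichlet(counts[:, s] + 1.0)
            r, e = _sparcc_single(fracs, exclusion_threshold, max_exclusions)
            rhos.append(r)
            excl.extend(e)
        rho = np.median(np.stack(rhos), axis=0)
        np.fill_diagonal(rho, 1.0)
        excl = sorted(set(excl))
        n_iter = n_inner_iterations
    else:
        raise ValueError("method must be 'pseudocount' or 'dirichlet'")

    taxa = list(m.counts.index)
    return CorrelationEstimate(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        excluded_pairs=[(taxa[i], taxa[j]) for i, j in excl],
        method=method,
        n_inner_iterations=n_iter,
    )


def permutation_pvalues(
    m: CountMatrix,
    estimate: CorrelationEstimate,
    n_permutations: int = 99,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided permutation p-values for each correlation.

    Null: each taxon's counts permuted independently across samples
    (destroying all between-taxon dependence while preserving marginals),
    SparCC re-estimated on pseudocount fractions without exclusions
    (deterministic and cheap; exclusions only matter for strong true
    correlations, absent under the null), and
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_permutations + 1).
    The result is also stored on ``estimate.p``.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations to resolve p < 0.05")
    counts = m.counts.to_numpy(dtype=float)
    d, n = counts.shape
    obs = np.abs(estimate.rho.to_numpy())
    rng = substream(seed, "sparcc_permutation")
    exceed = np.zeros((d, d))
    for _ in range(n_permutations):
        perm = np.empty_like(counts)
        for i in range(d):
            perm[i] = counts[i, rng.permutation(n)]
        fracs = (perm + 1.0) / (perm + 1.0).sum(axis=0, keepdims=True)
        rho_perm, _ = _sparcc_single(
            fracs,
            exclusion_threshold=1.1,  # no exclusions under the null
            max_exclusions=0,
        )
        exceed += np.abs(rho_perm) >= obs
    p = (1.0 + exceed) / (n_permutations + 1.0)
    np.fill_diagonal(p, np.nan)
    pdf = pd.DataFrame(p, index=estimate.rho.index, columns=estimate.rho.columns)
    estimate.p = pdf
    estimate.q = bh_fdr(pdf)
    return pdf


def bh_fdr(p: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjustment over the upper triangle."""
    mat = p.to_numpy(dtype=float)
    iu = np.triu_indices(mat.shape[0], 1)
    pvals = mat[iu]
    if np.nanmin(pvals) < 0 or np.nanmax(pvals) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(mat, np.nan)
    adj = multipletests(pvals, method="fdr_bh")[1]
    q[iu] = adj
    q[(iu[1], iu[0])] = adj
    return pd.DataFrame(q, index=p.index, columns=p.columns)


def build_network(
    estimate: CorrelationEstimate,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    keep_isolates: bool = False,
) -> nx.Graph:
    """Threshold the estimate into a signed undirected network.

    An edge is retained iff |rho| > ``rho_min`` and q < ``q_max``.
    Isolated taxa are dropped unless ``keep_isolates``.
    """
    if not (0 <= rho_min < 1):
        raise ValueError("rho_min must be in [0, 1)")
    if not (0 < q_max <= 1):
        raise ValueError("q_max must be in (0, 1]")
    if estimate.q is None:
        raise ValueError("q-values not computed; run permutation_pvalues first")
    taxa = list(estimate.rho.index)
    g = nx.Graph(rho_min=rho_min, q_max=q_max)
    if keep_isolates:
        g.add_nodes_from(taxa)
    rho = estimate.rho.to_numpy()
    q = estimate.q.to_numpy()
    for i, j in itertools.combinations(range(len(taxa)), 2):
        if abs(rho[i, j]) > rho_min and q[i, j] < q_max:
            g.add_edge(taxa[i], taxa[j], rho=float(rho[i, j]),
                       q=float(q[i, j]),
                       sign="positive" if rho[i, j] > 0 else "negative")
    return g


def topology(net: nx.Graph) -> NetworkTopology:
    """Global topology metrics of a co-occurrence network.

    Average degree 2E/N, global clustering (transitivity), density, and
    modularity Q of the greedy agglomerative partition on the unweighted
    edge set.  An empty network yields all-zero metrics with a flag.
    """
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    avg_degree = 2.0 * e / n
    if e == 0:
        return NetworkTopology(n, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    communities = nx.community.greedy_modularity_communities(net, weight=None)
    q = nx.community.modularity(net, communities, weight=None)
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_degree,
        transitivity=nx.transitivity(net),
        density=nx.density(net),
        modularity=float(q),
    )


def aggregate_taxa(m: CountMatrix, level: int = 1, top: int | None = None,
                   sep: str = ";") -> CountMatrix:
    """Aggregate a count matrix by a lineage field (e.g. phylum).

    ``level`` indexes the ``sep``-separated lineage string; taxa without
    a lineage go to "unclassified".  ``top`` keeps the most abundant n
    aggregates.  Used for coarse (phylum-level) network inference.
    """
    if m.lineages is None:
        raise ValueError("count matrix has no lineage annotations")

    def label(t):
        parts = str(m.lineages.loc[t]).split(sep)
        return parts[level].strip() if level < len(parts) and parts[level].strip() else "unclassified"

    grouped = m.counts.groupby([label(t) for t in m.counts.index]).sum()
    grouped.index.name = "taxon_id"
    if top is not None:
        keep = grouped.sum(axis=1).sort_values(ascending=False).index[:top]
        grouped = grouped.loc[keep]
    return CountMatrix(counts=grouped, sample_treatments=m.sample_treatments,
                       lineages=None)
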