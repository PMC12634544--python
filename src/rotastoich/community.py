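"""Alpha diversity, Bray–Curtis ordination and PERMANOVA.

Chao1 is the bias-corrected form ``S_obs + F1(F1-1)/(2(F2+1))`` (defined
even without doubletons); Simpson defaults to the Gini–Simpson index
``1 - sum(p_i^2)`` with the classical dominance ``D`` available via
``kind="dominance"``.  Principal coordinates analysis Gower-centers the
squared distances and applies the Cailliez additive correction when the
most negative eigenvalue exceeds 1e-8 in magnitude (Bray–Curtis matrices
are generally non-Euclidean).  PERMANOVA uses Anderson's distance-based
sum-of-squares decomposition with free permutation of labels and an
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._seeding import substream
from .synthetic import CountMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "chao1",
    "simpson",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.data.to_numpy()
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    correction: str  # "none" or "cailliez"


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_permutations: int
    seed: int


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate of one sample."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector: richness undefined")
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def simpson(counts, kind: str = "gini") -> float:
    """Simpson diversity of one sample.

    ``kind="gini"`` (default) returns the Gini–Simpson index 1 − Σp²;
    ``kind="dominance"`` returns the classical dominance D = Σp².
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector: diversity undefined")
    d = float(((c / total) ** 2).sum())
    if kind == "gini":
        return 1.0 - d
    if kind == "dominance":
        return d
    raise ValueError("kind must be 'gini' or 'dominance'")


def alpha_diversity(matrix: CountMatrix, prefix: str = "") -> pd.DataFrame:
    """Per-sample Chao1 and Gini–Simpson table for a count matrix."""
    rows = {}
    for sample in matrix.counts.columns:
        v = matrix.counts[sample].to_numpy()
        rows[sample] = {f"{prefix}chao1": chao1(v), f"{prefix}simpson": simpson(v)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.insert(0, "treatment", matrix.sample_treatments.loc[out.index].to_numpy())
    out.index.name = "sample"
    return out


def bray_curtis(matrix: CountMatrix, relative: bool = False) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between samples.

    ``BC(x, y) = 1 - 2 Σ min(x_i, y_i) / (Σx + Σy)`` computed on raw
    counts by default, or on per-sample proportions with
    ``relative=True``.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    zero = [s for s in counts.columns if counts[s].sum() == 0]
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    x = counts.to_numpy(dtype=float).T  # samples x taxa
    if relative:
        x = x / x.sum(axis=1, keepdims=True)
    d = squareform(pdist(x, metric="braycurtis"))
    ids = pd.Index(counts.columns)
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    # largest real eigenvalue of the 2n x 2n block matrix
    # [[0, 2*delta1], [-I, -4*delta2]] with delta1/delta2 the centered
    # -0.5 d^2 and -0.5 d matrices (Cailliez 1983)
    n = d.shape[0]
    delta1 = _gower_center(d ** 2)
    delta2 = -0.5 * (np.eye(n) - np.full((n, n), 1.0 / n)) @ d @ (
        np.eye(n) - np.full((n, n), 1.0 / n)
    )
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigs = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eigs.real))


def pcoa(d: DistanceMatrix, negative_tol: float = 1e-8) -> OrdinationResult:
    """Metric embedding of a distance matrix (principal coordinates).

    Gower-centering followed by eigendecomposition; when the most
    negative eigenvalue's magnitude exceeds ``negative_tol`` the
    Cailliez additive constant is applied and the decomposition redone
    (tagged in the result).  Axis i explains λ_i / Σ positive λ.
    """
    dm = d.values()
    correction = "none"
    evals, evecs = np.linalg.eigh(_gower_center(dm ** 2))
    if evals.min() < -negative_tol:
        c = _cailliez_constant(dm)
        dm = dm + c * (1.0 - np.eye(dm.shape[0]))
        evals, evecs = np.linalg.eigh(_gower_center(dm ** 2))
        correction = "cailliez"
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(negative_tol, evals.max() * 1e-12) if evals.max() > 0 else evals > 0
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.data.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=lam / lam.sum(),
        correction=correction,
    )


def _ss_decomposition(d2: np.ndarray, onehot: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    sizes = onehot.sum(axis=0)
    # per group g: sum_{i<j in g} d2_ij / n_g
    within_pairs = np.einsum("ig,jg,ij->g", onehot, onehot, d2) / 2.0
    ss_within = float((within_pairs / sizes).sum())
    return float(ss_total), ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F from the distance-based between/within decomposition;
    p = (1 + #{F_perm >= F_obs}) / (n_permutations + 1) under free
    permutation of labels.  Every group needs at least two samples.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[d.data.index]
    labels = np.asarray(groups)
    if labels.shape[0] != d.data.shape[0]:
        raise ValueError("groups length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(u) for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"singleton group(s): {small}")
    n = labels.shape[0]
    d2 = d.values() ** 2
    onehot = np.eye(k)[codes]
    ss_total, ss_within = _ss_decomposition(d2, onehot)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total

    rng = substream(seed, "permanova")
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    oh = np.eye(k)[perms]  # (P, n, k)
    within_pairs = np.einsum("pig,pjg,ij->pg", oh, oh, d2) / 2.0
    ss_within_perm = (within_pairs / sizes).sum(axis=1)
    ss_between_perm = ss_total - ss_within_perm
    f_perm = (ss_between_perm / (k - 1)) / (ss_within_perm / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (n_permutations + 1.0)
    return PermanovaResult(F=float(f_obs), R2=float(r2), p=float(p),
                           n_permutations=n_permutations, seed=seed)
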