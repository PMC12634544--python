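"""Synthetic-data generators for the rotation-system pipeline.

Three generators produce everything the downstream stages consume:

``generate_soil_table``
    Replicate-level soil physicochemical / enzyme tables drawn from
    truncated-at-zero normals with per-treatment means and SDs.  The
    bundled default parameters are the published group means ± SD of the
    four-stage rotation experiment (four treatments B1–B4, three
    replicate plots).

``generate_count_matrix``
    Compositional taxa × sample count matrices: log-normal basis
    abundances with a known basis covariance (and optional per-treatment
    fold changes), closed to proportions and sampled multinomially at a
    fixed read depth (default 60,000 reads/sample).  This is exactly the
    generative model the SparCC estimator assumes, so the returned true
    basis correlation matrix is a fair oracle for network recovery tests.

``generate_latent_dataset``
    Latent-variable datasets with known inner path coefficients and
    reflective loadings, the recovery harness for the PLS-PM stage.

All randomness flows from ``SyntheticConfig.seed`` through named
substreams (see :mod:`rotastoich._seeding`); identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "VariableSpec",
    "CountSpec",
    "LatentSpec",
    "SyntheticConfig",
    "CountMatrix",
    "LatentDataset",
    "generate_soil_table",
    "generate_count_matrix",
    "generate_latent_dataset",
    "load_sros2_params",
    "sros2_config",
    "DEFAULT_TREATMENTS",
]

DEFAULT_TREATMENTS: tuple[str, ...] = ("B1", "B2", "B3", "B4")

_MAX_TRUNCATION_TRIES = 1000


@dataclass(frozen=True)
class VariableSpec:
    """Per-treatment mean/SD specification of one observed soil variable."""

    name: str
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        for t, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"variable {self.name!r}: negative SD for {t}")


@dataclass(frozen=True)
class CountSpec:
    """Log-normal-basis + multinomial count model parameters.

    ``log_mean`` is the per-taxon mean of log basis abundance;
    ``log_cov`` the basis covariance on the log scale (identity·scale if
    omitted).  ``fold_changes`` maps treatment → {taxon index → fold}
    applied multiplicatively to the basis abundance.
    """

    n_taxa: int
    read_depth: int = 60_000
    log_mean: Sequence[float] | float = 0.0
    log_cov: np.ndarray | None = None
    log_var: float = 1.0
    fold_changes: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    n_samples_per_treatment: int | None = None
    lineages: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("count model needs at least 4 taxa")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")

    def resolved_cov(self) -> np.ndarray:
        if self.log_cov is None:
            return np.eye(self.n_taxa) * self.log_var
        cov = np.asarray(self.log_cov, dtype=float)
        if cov.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("log_cov shape does not match n_taxa")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("log_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("log_cov must be positive semi-definite")
        return cov


@dataclass(frozen=True)
class LatentSpec:
    """Structure and true parameters of a latent-variable dataset.

    ``paths`` maps (response, predictor) latent names to the true inner
    coefficient; the latent order must topologically sort the paths
    (predictor strictly earlier than response), which enforces
    acyclicity.  Loadings are reflective, in (0, 1].
    """

    latents: Sequence[str]
    blocks: Mapping[str, Sequence[str]]
    loadings: Mapping[str, float]
    paths: Mapping[tuple[str, str], float]
    n_samples: int = 100
    noise_sd: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        order = {name: i for i, name in enumerate(self.latents)}
        seen: set[str] = set()
        for lv in self.latents:
            if lv not in self.blocks or len(self.blocks[lv]) == 0:
                raise ValueError(f"latent {lv!r} has no indicator block")
            for ind in self.blocks[lv]:
                if ind in seen:
                    raise ValueError(f"duplicate indicator name {ind!r}")
                seen.add(ind)
                lam = self.loadings.get(ind, None)
                if lam is None or not (0.0 < lam <= 1.0):
                    raise ValueError(f"loading for {ind!r} must be in (0, 1]")
        for (resp, pred) in self.paths:
            if resp not in order or pred not in order:
                raise ValueError(f"path ({resp}, {pred}) references unknown latent")
            if order[pred] >= order[resp]:
                raise ValueError(
                    "inner model must be acyclic: predictor must precede its "
                    f"response in the latent order (violated by {pred}->{resp})"
                )


@dataclass(frozen=True)
class SyntheticConfig:
    """Master configuration shared by all three generators."""

    seed: int
    treatments: Sequence[str] = DEFAULT_TREATMENTS
    n_replicates: int = 3
    variable_specs: Sequence[VariableSpec] = ()
    variable_corr: np.ndarray | None = None
    count_spec: CountSpec | None = None
    latent_spec: LatentSpec | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per treatment")
        names = [v.name for v in self.variable_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in variable_specs")


@dataclass
class CountMatrix:
    """Taxa × sample nonnegative integer count matrix.

    ``counts``: DataFrame indexed by taxon id with sample-id columns;
    ``sample_treatments``: Series mapping sample id → treatment label;
    ``true_basis_correlation``: generator's basis correlation oracle
    (None for matrices read from disk); ``lineages``: optional taxonomy
    strings aligned with the taxon index.
    """

    counts: pd.DataFrame
    sample_treatments: pd.Series
    true_basis_correlation: np.ndarray | None = None
    lineages: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")

    def to_tsv(self, counts_path, mapping_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "taxon_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        if mapping_path is not None:
            self.sample_treatments.rename("treatment").rename_axis("sample").to_csv(
                mapping_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, counts_path, mapping_path) -> "CountMatrix":
        raw = pd.read_csv(counts_path, sep="\t")
        counts = raw.set_index("taxon_id")
        mapping = pd.read_csv(mapping_path, sep="\t").set_index("sample")["treatment"]
        return cls(counts=counts, sample_treatments=mapping.loc[counts.columns])


@dataclass
class LatentDataset:
    """Indicator table plus the generating truth for PLS-PM recovery."""

    data: pd.DataFrame
    latent_scores: pd.DataFrame
    true_paths: dict[tuple[str, str], float]
    true_loadings: dict[str, float]


# ---------------------------------------------------------------------------
# soil table


def generate_soil_table(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a replicate-level soil table from the configured group moments.

    Each replicate row is drawn from a normal (optionally correlated
    across variables through a Gaussian copula on ``variable_corr``)
    truncated at zero by whole-row resampling, which keeps every
    marginal continuous and strictly positive.  Deterministic given
    ``config.seed``.
    """
    if not config.variable_specs:
        raise ValueError("variable_specs must be nonempty")
    rng = substream(config.seed, "soil_table")
    names = [v.name for v in config.variable_specs]
    p = len(names)

    corr = None
    if config.variable_corr is not None:
        corr = np.asarray(config.variable_corr, dtype=float)
        if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("variable_corr must be a symmetric p x p matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("variable_corr must be positive semi-definite")
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))

    rows = []
    for t in config.treatments:
        mu = np.array([v.means[t] for v in config.variable_specs])
        sd = np.array([v.sds[t] for v in config.variable_specs])
        if (sd == 0).all() and (mu <= 0).any():
            raise ValueError("degenerate spec: zero SD with nonpositive mean")
        for rep in range(1, config.n_replicates + 1):
            for _ in range(_MAX_TRUNCATION_TRIES):
                z = rng.standard_normal(p)
                if corr is not None:
                    z = chol @ z
                x = mu + sd * z
                if (x > 0).all():
                    break
            else:
                raise RuntimeError(
                    "could not draw a strictly positive replicate; check means/SDs"
                )
            rows.append({"treatment": t, "replicate": rep, **dict(zip(names, x))})
    table = pd.DataFrame(rows, columns=["treatment", "replicate", *names])
    table["treatment"] = pd.Categorical(
        table["treatment"], categories=list(config.treatments), ordered=True
    )
    return table


# ---------------------------------------------------------------------------
# count matrix


def generate_count_matrix(config: SyntheticConfig) -> CountMatrix:
    """Simulate compositional counts from the log-normal basis model.

    Per sample: basis abundance ``a = exp(mu_treatment + L z)`` with
    ``L L' = log_cov``; treatment fold changes enter as additive log
    offsets; proportions ``a / sum(a)`` are sampled multinomially at the
    configured read depth, so every column sums to ``read_depth``
    exactly.  The basis correlation implied by ``log_cov`` is returned
    for recovery tests.
    """
    spec = config.count_spec
    if spec is None:
        raise ValueError("config.count_spec is not set")
    cov = spec.resolved_cov()
    rng = substream(config.seed, "count_matrix")

    mu = np.asarray(spec.log_mean, dtype=float)
    if mu.ndim == 0:
        mu = np.full(spec.n_taxa, float(mu))
    if mu.shape != (spec.n_taxa,):
        raise ValueError("log_mean length does not match n_taxa")

    # eigen square root: robust to semi-definite covariances
    evals, evecs = np.linalg.eigh(cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    n_per = spec.n_samples_per_treatment or config.n_replicates
    sample_ids, treatments, cols = [], [], []
    for t in config.treatments:
        shift = np.zeros(spec.n_taxa)
        for idx, fold in spec.fold_changes.get(t, {}).items():
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            shift[idx] = np.log(fold)
        for rep in range(1, n_per + 1):
            log_basis = mu + shift + root @ rng.standard_normal(spec.n_taxa)
            basis = np.exp(log_basis - log_basis.max())  # overflow guard
            props = basis / basis.sum()
            cols.append(rng.multinomial(spec.read_depth, props))
            sample_ids.append(f"{t}_r{rep}")
            treatments.append(t)

    taxa = [f"taxon_{i + 1}" for i in range(spec.n_taxa)]
    counts = pd.DataFrame(np.array(cols).T, index=pd.Index(taxa, name="taxon_id"),
                          columns=sample_ids)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    lineages = None
    if spec.lineages is not None:
        if len(spec.lineages) != spec.n_taxa:
            raise ValueError("lineages length does not match n_taxa")
        lineages = pd.Series(list(spec.lineages), index=counts.index)
    return CountMatrix(
        counts=counts,
        sample_treatments=pd.Series(treatments, index=sample_ids, name="treatment"),
        true_basis_correlation=corr,
        lineages=lineages,
    )


# ---------------------------------------------------------------------------
# latent dataset


def generate_latent_dataset(config: SyntheticConfig) -> LatentDataset:
    """Simulate indicators from a known reflective latent path model.

    Exogenous latent scores are standard normal; each endogenous score is
    the true-coefficient linear combination of its predecessors plus
    normal structural noise (default residual SD chosen so the score has
    unit variance when predecessors are independent).  Indicators are
    ``loading × latent + N(0, sqrt(1 − loading²))``.  Scores and
    indicators are standardized; the generating truth is returned.
    """
    spec = config.latent_spec
    if spec is None:
        raise ValueError("config.latent_spec is not set")
    rng = substream(config.seed, "latent_dataset")
    n = spec.n_samples

    scores: dict[str, np.ndarray] = {}
    for lv in spec.latents:
        preds = [(p, b) for (r, p), b in spec.paths.items() if r == lv]
        if not preds:
            scores[lv] = rng.standard_normal(n)
        else:
            signal = sum(b * scores[p] for p, b in preds)
            if spec.noise_sd is not None and lv in spec.noise_sd:
                sd = spec.noise_sd[lv]
            else:
                sd = np.sqrt(max(1.0 - sum(b * b for _, b in preds), 0.05))
            scores[lv] = signal + sd * rng.standard_normal(n)
        scores[lv] = _standardize(scores[lv])

    data = {}
    for lv in spec.latents:
        for ind in spec.blocks[lv]:
            lam = spec.loadings[ind]
            x = lam * scores[lv] + np.sqrt(max(1.0 - lam * lam, 0.0)) * rng.standard_normal(n)
            data[ind] = _standardize(x)

    return LatentDataset(
        data=pd.DataFrame(data),
        latent_scores=pd.DataFrame(scores),
        true_paths=dict(spec.paths),
        true_loadings={i: spec.loadings[i] for lv in spec.latents for i in spec.blocks[lv]},
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / s


# ---------------------------------------------------------------------------
# bundled rotation-study parameters


def load_sros2_params(include_micronutrients: bool = True) -> list[VariableSpec]:
    """Load the bundled per-treatment generating parameters.

    Soil/enzyme means ± SD are the published group values of the
    four-stage rotation experiment; micronutrient parameters are
    synthetic (constructed to match the narrated percent changes, see
    ``data/sros2_micronutrients_synthetic.tsv``).
    """
    specs: list[VariableSpec] = []
    files = ["sros2_soil_params.tsv"]
    if include_micronutrients:
        files.append("sros2_micronutrients_synthetic.tsv")
    for fname in files:
        with resources.files("rotastoich.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh, sep="\t")
        for _, row in df.iterrows():
            specs.append(
                VariableSpec(
                    name=row["variable"],
                    means={t: float(row[f"{t}_mean"]) for t in DEFAULT_TREATMENTS},
                    sds={t: float(row[f"{t}_sd"]) for t in DEFAULT_TREATMENTS},
                )
            )
    return specs


def sros2_config(
    seed: int,
    n_replicates: int = 3,
    include_micronutrients: bool = True,
    count_spec: CountSpec | None = None,
    latent_spec: LatentSpec | None = None,
) -> SyntheticConfig:
    """Default configuration emulating the rotation study's design.

    Four treatments B1–B4, three replicate plots, soil/enzyme variables
    at the published group means ± SD.
    """
    return SyntheticConfig(
        seed=seed,
        n_replicates=n_replicates,
        variable_specs=load_sros2_params(include_micronutrients),
        count_spec=count_spec,
        latent_spec=latent_spec,
    )
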