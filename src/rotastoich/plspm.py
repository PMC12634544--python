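"""Partial least squares path modeling (PLS-PM), mode A, from scratch.

A path model has ordered latent variables, each measured reflectively by
a block of observed indicators, and an acyclic inner model (strictly
lower-triangular adjacency over the latent order).  Estimation follows
the classical Wold/Lohmöller alternating algorithm:

1. latent scores = standardized weighted sums of their (standardized)
   indicator blocks;
2. inner proxies per weighting scheme — centroid (sign of score
   correlation with adjacent latents), factorial (correlation weights),
   or path (regression weights for predecessors, correlations for
   successors);
3. mode-A outer weight update: correlation of each indicator with its
   block's inner proxy;

iterated until the largest absolute outer-weight change falls below
``tol``.  Path coefficients are then OLS regressions of each endogenous
score on its predecessors' scores; loadings are indicator–score
correlations.  The global sign indeterminacy of each latent is fixed by
requiring its largest-|loading| indicator to load positively.

Fit indices: R² per endogenous latent, communality = loading², AVE =
mean squared loading per block, and GoF = sqrt(mean communality × mean
R²), with GoF > 0.6 conventionally read as excellent fit for
soil–microbe systems.  Path coefficients are validated by row-resampling
bootstrap with percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._seeding import substream

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "BootstrapResult",
    "fit_plspm",
    "gof",
    "ave",
    "bootstrap_paths",
    "load_model_spec",
    "GOF_EXCELLENT",
]

GOF_EXCELLENT = 0.6

_SCHEMES = ("centroid", "factorial", "path")


@dataclass(frozen=True)
class PathModelSpec:
    """Blocks + inner structure of a PLS path model (reflective mode A)."""

    latents: tuple[str, ...]
    blocks: dict[str, tuple[str, ...]]
    inner: tuple[tuple[str, str], ...]  # (response, predictor) edges
    scheme: str = "path"

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        order = {lv: i for i, lv in enumerate(self.latents)}
        seen: set[str] = set()
        for lv in self.latents:
            block = self.blocks.get(lv, ())
            if not block:
                raise ValueError(f"latent {lv!r} has an empty indicator block")
            for ind in block:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} appears in two blocks")
                seen.add(ind)
        for resp, pred in self.inner:
            if resp not in order or pred not in order:
                raise ValueError(f"inner edge ({resp}, {pred}) uses unknown latent")
            if order[pred] >= order[resp]:
                raise ValueError(
                    "inner adjacency must be strictly lower-triangular: "
                    f"{pred!r} must precede {resp!r} in the latent order"
                )
        adjacent = set()
        for resp, pred in self.inner:
            adjacent.add(resp)
            adjacent.add(pred)
        for lv in self.latents:
            if lv not in adjacent:
                raise ValueError(f"latent {lv!r} is disconnected from the inner model")

    def predecessors(self, lv: str) -> list[str]:
        return [p for r, p in self.inner if r == lv]

    def successors(self, lv: str) -> list[str]:
        return [r for r, p in self.inner if p == lv]

    @property
    def endogenous(self) -> list[str]:
        return [lv for lv in self.latents if self.predecessors(lv)]


@dataclass
class PathModelFit:
    spec: PathModelSpec
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    communalities: dict[str, float]
    scores: pd.DataFrame
    path_coefficients: dict[tuple[str, str], float]
    r2: dict[str, float]
    ave: dict[str, float]
    gof: float
    iterations: int
    tolerance_reached: float

    @property
    def excellent_fit(self) -> bool:
        return self.gof > GOF_EXCELLENT


@dataclass
class BootstrapResult:
    paths: dict[tuple[str, str], dict[str, float]]  # mean, se, ci_low, ci_high, p
    n_boot: int
    seed: int
    n_failed: int = 0
    samples: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _standardize_matrix(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant indicator column")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(
    data: pd.DataFrame,
    spec: PathModelSpec,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PathModelFit:
    """Fit the path model by the alternating outer/inner algorithm.

    Rows with any missing indicator are dropped (listwise).  Raises on
    non-convergence (carrying the last weight change) and on constant
    indicators.
    """
    indicators = [ind for lv in spec.latents for ind in spec.blocks[lv]]
    missing = [c for c in indicators if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks indicator columns: {missing}")
    frame = data[indicators].dropna()
    n = len(frame)
    max_preds = max((len(spec.predecessors(lv)) for lv in spec.latents), default=0)
    if n <= max_preds + 1:
        raise ValueError("too few complete rows for the inner regressions")
    x = _standardize_matrix(frame.to_numpy(dtype=float))
    cols = {ind: i for i, ind in enumerate(indicators)}
    block_ix = {lv: np.array([cols[i] for i in spec.blocks[lv]]) for lv in spec.latents}

    weights = {lv: np.ones(len(spec.blocks[lv])) for lv in spec.latents}

    def scores_from(w):
        y = {}
        for lv in spec.latents:
            s = x[:, block_ix[lv]] @ w[lv]
            sd = s.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate latent score for {lv!r}")
            y[lv] = (s - s.mean()) / sd
        return y

    y = scores_from(weights)
    delta = np.inf
    for iteration in range(1, max_iter + 1):
        # inner proxies
        z = {}
        for lv in spec.latents:
            proxy = np.zeros(n)
            preds, succs = spec.predecessors(lv), spec.successors(lv)
            if spec.scheme == "path":
                if preds:
                    pmat = np.column_stack([y[p] for p in preds])
                    beta = np.linalg.lstsq(pmat, y[lv], rcond=None)[0]
                    proxy = proxy + pmat @ beta
                for s_lv in succs:
                    proxy = proxy + _corr(y[lv], y[s_lv]) * y[s_lv]
            else:
                for adj in [*preds, *succs]:
                    c = _corr(y[lv], y[adj])
                    e = np.sign(c) if spec.scheme == "centroid" else c
                    proxy = proxy + e * y[adj]
            z[lv] = proxy

        # mode-A outer weight update
        new_weights = {}
        for lv in spec.latents:
            zc = z[lv] - z[lv].mean()
            sd = zc.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance inner proxy for {lv!r}")
            zc /= sd
            w = x[:, block_ix[lv]].T @ zc / (n - 1)
            new_weights[lv] = w

        delta = max(
            np.abs(_unit(new_weights[lv]) - _unit(weights[lv])).max()
            for lv in spec.latents
        )
        weights = new_weights
        y = scores_from(weights)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"PLS-PM did not converge in {max_iter} iterations "
            f"(last weight change {delta:.3e})"
        )

    # sign alignment: largest-|loading| indicator loads positively
    loadings = {}
    for lv in spec.latents:
        lam = np.array([_corr(x[:, cols[i]], y[lv]) for i in spec.blocks[lv]])
        anchor = int(np.argmax(np.abs(lam)))
        if lam[anchor] < 0:
            y[lv] = -y[lv]
            weights[lv] = -weights[lv]
            lam = -lam
        for ind, l in zip(spec.blocks[lv], lam):
            loadings[ind] = float(l)

    # structural regressions
    paths: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    for lv in spec.endogenous:
        preds = spec.predecessors(lv)
        pmat = np.column_stack([y[p] for p in preds])
        beta = np.linalg.lstsq(pmat, y[lv], rcond=None)[0]
        fitted = pmat @ beta
        r2[lv] = float(1.0 - ((y[lv] - fitted) ** 2).sum() / (y[lv] ** 2).sum())
        for p_lv, b in zip(preds, beta):
            paths[(lv, p_lv)] = float(b)

    communalities = {ind: loadings[ind] ** 2 for ind in indicators}
    ave_vals = {
        lv: float(np.mean([communalities[i] for i in spec.blocks[lv]]))
        for lv in spec.latents
    }
    gof_val = float(
        np.sqrt(np.mean(list(communalities.values())) * np.mean(list(r2.values())))
    )
    flat_weights = {
        ind: float(w)
        for lv in spec.latents
        for ind, w in zip(spec.blocks[lv], weights[lv])
    }
    return PathModelFit(
        spec=spec,
        outer_weights=flat_weights,
        loadings=loadings,
        communalities=communalities,
        scores=pd.DataFrame({lv: y[lv] for lv in spec.latents}, index=frame.index),
        path_coefficients=paths,
        r2=r2,
        ave=ave_vals,
        gof=gof_val,
        iterations=iteration,
        tolerance_reached=float(delta),
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _unit(w: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def gof(fit: PathModelFit) -> float:
    """Goodness-of-Fit: sqrt(mean communality × mean R² over endogenous).

    Recomputed from the stored communalities and R² (identity with
    ``fit.gof`` to machine precision).
    """
    if not fit.r2:
        raise ValueError("model has no endogenous latent: GoF undefined")
    return float(
        np.sqrt(
            np.mean(list(fit.communalities.values())) * np.mean(list(fit.r2.values()))
        )
    )


def ave(fit: PathModelFit) -> dict[str, float]:
    """Average variance extracted per block (mean squared loading)."""
    return dict(fit.ave)


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 1000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> BootstrapResult:
    """Row-resampling bootstrap of the path coefficients.

    Each resample is refit; the fit's own orientation rule keeps signs
    comparable across resamples.  Reports per-path mean, SE, percentile
    95% CI and a two-sided bootstrap p-value (smoothed sign-count,
    2·min(#{β* ≤ 0}, #{β* ≥ 0})+1 over n_boot+1).  Errors if more than
    10% of resamples fail.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    full = fit_plspm(data, spec, tol=tol, max_iter=max_iter)
    rng = substream(seed, "plspm_bootstrap")
    n = len(full.scores)
    frame = data.reset_index(drop=True)
    draws: dict[tuple[str, str], list[float]] = {k: [] for k in full.path_coefficients}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            refit = fit_plspm(frame.iloc[idx], spec, tol=tol, max_iter=max_iter)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
            continue
        for k in draws:
            draws[k].append(refit.path_coefficients[k])
    if failed > 0.1 * n_boot:
        raise RuntimeError(
            f"bootstrap unstable: {failed}/{n_boot} resamples failed to fit"
        )
    paths = {}
    samples = {}
    for k, vals in draws.items():
        arr = np.asarray(vals)
        lo, hi = np.percentile(arr, [2.5, 97.5])
        n_eff = arr.size
        p = (2.0 * min((arr <= 0).sum(), (arr >= 0).sum()) + 1.0) / (n_eff + 1.0)
        paths[k] = {
            "estimate": full.path_coefficients[k],
            "mean": float(arr.mean()),
            "se": float(arr.std(ddof=1)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": float(min(p, 1.0)),
        }
        samples[k] = arr
    return BootstrapResult(paths=paths, n_boot=n_boot, seed=seed,
                           n_failed=failed, samples=samples)


def load_model_spec(path) -> PathModelSpec:
    """Read a YAML/JSON model file: latents, blocks, inner edges, scheme.

    Format::

        latents: [treatment, soil_properties, ...]
        blocks:
          treatment: [treatment_ordinal]
          soil_properties: [SOC, TN, AP, pH]
        inner:
          - [soil_properties, treatment]   # response, predictor
        scheme: path
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PathModelSpec(
        latents=tuple(raw["latents"]),
        blocks={lv: tuple(v) for lv, v in raw["blocks"].items()},
        inner=tuple((r, p) for r, p in raw["inner"]),
        scheme=raw.get("scheme", "path"),
    )
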