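"""End-to-end pipeline orchestration from a single YAML config.

Runs (as enabled): synthetic data generation (or user table loading) →
treatment statistics → enzyme stoichiometry → community analysis →
co-occurrence networks → PLS-PM, writing TSV/JSON/GraphML artifacts into
an output directory and a ``report.json`` with per-stage file checksums.
All randomness flows from the config seed through named substreams, so a
re-run with an identical config reproduces identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, community, enzyme_stoich, network, plspm, soil_stats
from .synthetic import (
    CountMatrix,
    CountSpec,
    SyntheticConfig,
    VariableSpec,
    generate_count_matrix,
    generate_soil_table,
    load_sros2_params,
)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_all", "load_config"]

_STAGES = ("simulate", "stats", "stoich", "community", "network", "plspm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int
    treatments: tuple[str, ...] = ("B1", "B2", "B3", "B4")
    n_replicates: int = 3
    alpha: float = 0.05
    stages: tuple[str, ...] = _STAGES
    soil: dict = field(default_factory=lambda: {"bundled_params": True})
    counts: dict = field(default_factory=dict)
    community: dict = field(default_factory=lambda: {"permutations": 999})
    network: dict = field(
        default_factory=lambda: {"rho_min": 0.6, "q_max": 0.01, "permutations": 99}
    )
    plspm: dict = field(default_factory=lambda: {"model": "bundled", "n_boot": 200})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    config: dict
    version: str
    outputs: dict[str, dict[str, str]]  # stage -> {filename: sha256}
    wall_time_s: float

    def to_json(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "version": self.version,
                    "wall_time_s": self.wall_time_s,
                    "config": self.config,
                    "outputs": self.outputs,
                },
                indent=2,
                sort_keys=True,
            )
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = {}
    for key in ("seed", "n_replicates", "alpha", "soil", "counts",
                "community", "network", "plspm"):
        if key in raw:
            kwargs[key] = raw[key]
    if "treatments" in raw:
        kwargs["treatments"] = tuple(raw["treatments"])
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "seed" not in kwargs:
        raise ValueError("config must set an explicit seed (no wall-clock seeding)")
    return PipelineConfig(**kwargs)


def bundled_demo_config_path() -> Path:
    return Path(str(resources.files("rotastoich.data").joinpath("demo.yaml")))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _count_matrix_from_entry(name: str, entry: dict, cfg: PipelineConfig) -> CountMatrix:
    if "path" in entry:
        return CountMatrix.from_tsv(entry["path"], entry["mapping"])
    n_taxa = int(entry["n_taxa"])
    if "log_mean_range" in entry:
        lo, hi = entry["log_mean_range"]
        log_mean = np.linspace(float(lo), float(hi), n_taxa)
    else:
        log_mean = float(entry.get("log_mean", 0.0))
    log_var = float(entry.get("log_var", 1.0))
    log_cov = None
    if "corr_block" in entry:
        block = entry["corr_block"]
        idx = [int(i) for i in block["taxa"]]
        rho = float(block["rho"])
        log_cov = np.eye(n_taxa) * log_var
        for a in idx:
            for b in idx:
                if a != b:
                    log_cov[a, b] = rho * log_var
    spec = CountSpec(
        n_taxa=n_taxa,
        read_depth=int(entry.get("read_depth", 60_000)),
        log_mean=log_mean,
        log_cov=log_cov,
        log_var=log_var,
        n_samples_per_treatment=(
            int(entry["n_samples_per_treatment"])
            if "n_samples_per_treatment" in entry
            else None
        ),
        fold_changes={
            t: {int(i): float(f) for i, f in fc.items()}
            for t, fc in entry.get("fold_changes", {}).items()
        },
    )
    syn = SyntheticConfig(
        seed=cfg.seed + sum(name.encode()) % 1000,  # distinct stream per matrix
        treatments=cfg.treatments,
        n_replicates=cfg.n_replicates,
        count_spec=spec,
    )
    return generate_count_matrix(syn)


def run_all(config: PipelineConfig, out_dir) -> RunReport:
    """Execute all enabled stages; abort naming the failing stage."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        outputs.setdefault(stage, {})
        for p in paths:
            outputs[stage][p.name] = _sha256(p)

    soil_table: pd.DataFrame | None = None
    matrices: dict[str, CountMatrix] = {}
    diversity_tables: dict[str, pd.DataFrame] = {}

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        if "table" in config.soil:
            soil_table = pd.read_csv(config.soil["table"], sep="\t")
            _validate_soil_table(soil_table)
        else:
            specs = _soil_specs(config)
            syn = SyntheticConfig(
                seed=config.seed,
                treatments=config.treatments,
                n_replicates=config.n_replicates,
                variable_specs=specs,
            )
            soil_table = generate_soil_table(syn)
        for name, entry in config.counts.items():
            matrices[name] = _count_matrix_from_entry(name, entry, config)
        if stage in config.stages:
            p = out / "soil_table.tsv"
            soil_table.to_csv(p, sep="\t", index=False)
            written = [p]
            for name, m in matrices.items():
                cp, mp = out / f"counts_{name}.tsv", out / f"samples_{name}.tsv"
                m.to_tsv(cp, mp)
                written += [cp, mp]
            record(stage, *written)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stats --------------------------------------------------------
    if "stats" in config.stages:
        stage = "stats"
        try:
            report = soil_stats.stats_report(soil_table, alpha=config.alpha)
            p = out / "stats.json"
            _write_json(p, report)
            record(stage, p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stoich -------------------------------------------------------
    stoich_table: pd.DataFrame | None = None
    if "stoich" in config.stages:
        stage = "stoich"
        try:
            stoich_table = enzyme_stoich.stoichiometry_table(soil_table)
            p = out / "stoich.tsv"
            stoich_table.to_csv(p, sep="\t", index=False)
            record(stage, p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- community ----------------------------------------------------
    if "community" in config.stages:
        stage = "community"
        try:
            written = []
            for name, m in matrices.items():
                div = community.alpha_diversity(m)
                diversity_tables[name] = div
                dm = community.bray_curtis(m)
                ord_res = community.pcoa(dm)
                perm = community.permanova(
                    dm,
                    m.sample_treatments,
                    n_permutations=int(config.community.get("permutations", 999)),
                    seed=config.seed,
                )
                p1 = out / f"diversity_{name}.tsv"
                div.to_csv(p1, sep="\t")
                p2 = out / f"distance_{name}.tsv"
                dm.data.to_csv(p2, sep="\t")
                p3 = out / f"pcoa_{name}.tsv"
                ord_res.coordinates.to_csv(p3, sep="\t")
                p4 = out / f"permanova_{name}.json"
                _write_json(
                    p4,
                    {
                        "F": perm.F,
                        "R2": perm.R2,
                        "p": perm.p,
                        "n_permutations": perm.n_permutations,
                        "seed": perm.seed,
                        "pcoa_correction": ord_res.correction,
                        "proportion_explained": ord_res.proportion_explained[:2],
                    },
                )
                written += [p1, p2, p3, p4]
            record(stage, *written)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- network ------------------------------------------------------
    if "network" in config.stages:
        stage = "network"
        try:
            written = []
            top = config.network.get("top")
            for name, m in matrices.items():
                if top is not None:
                    keep = (
                        m.counts.sum(axis=1)
                        .sort_values(ascending=False)
                        .index[: int(top)]
                    )
                    m = CountMatrix(
                        counts=m.counts.loc[keep],
                        sample_treatments=m.sample_treatments,
                    )
                est = network.sparcc_correlations(m, seed=config.seed)
                network.permutation_pvalues(
                    m, est,
                    n_permutations=int(config.network.get("permutations", 99)),
                    seed=config.seed,
                )
                net = network.build_network(
                    est,
                    rho_min=float(config.network.get("rho_min", 0.6)),
                    q_max=float(config.network.get("q_max", 0.01)),
                )
                topo = network.topology(net)
                edges = pd.DataFrame(
                    [
                        {
                            "taxon_a": a,
                            "taxon_b": b,
                            "rho": d["rho"],
                            "q": d["q"],
                            "sign": d["sign"],
                        }
                        for a, b, d in net.edges(data=True)
                    ],
                    columns=["taxon_a", "taxon_b", "rho", "q", "sign"],
                )
                p1 = out / f"edges_{name}.tsv"
                edges.to_csv(p1, sep="\t", index=False)
                p2 = out / f"network_{name}.graphml"
                nx.write_graphml(net, p2)
                p3 = out / f"topology_{name}.json"
                _write_json(p3, vars(topo))
                written += [p1, p2, p3]
            record(stage, *written)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- plspm --------------------------------------------------------
    if "plspm" in config.stages:
        stage = "plspm"
        try:
            merged = _merged_table(config, soil_table, stoich_table, diversity_tables)
            model_entry = config.plspm.get("model", "bundled")
            if model_entry == "bundled":
                model_path = resources.files("rotastoich.data").joinpath(
                    "model_sros2.yaml"
                )
                spec = plspm.load_model_spec(str(model_path))
            else:
                spec = plspm.load_model_spec(model_entry)
            if "scheme" in config.plspm:
                spec = plspm.PathModelSpec(
                    latents=spec.latents, blocks=spec.blocks, inner=spec.inner,
                    scheme=config.plspm["scheme"],
                )
            fit = plspm.fit_plspm(merged, spec)
            boot = plspm.bootstrap_paths(
                merged, spec,
                n_boot=int(config.plspm.get("n_boot", 200)),
                seed=config.seed,
            )
            payload = {
                "scheme": spec.scheme,
                "iterations": fit.iterations,
                "path_coefficients": {
                    f"{p}->{r}": v for (r, p), v in fit.path_coefficients.items()
                },
                "r2": fit.r2,
                "ave": fit.ave,
                "loadings": fit.loadings,
                "outer_weights": fit.outer_weights,
                "gof": fit.gof,
                "excellent_fit": fit.excellent_fit,
                "bootstrap": {
                    f"{p}->{r}": stats for (r, p), stats in boot.paths.items()
                },
                "n_boot": boot.n_boot,
            }
            p = out / "plspm.json"
            _write_json(p, payload)
            merged_path = out / "merged.tsv"
            merged.to_csv(merged_path, sep="\t", index=False)
            record(stage, p, merged_path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        config=_config_dict(config),
        version=__version__,
        outputs=outputs,
        wall_time_s=time.perf_counter() - t0,
    )
    report.to_json(out / "report.json")
    return report


def _soil_specs(config: PipelineConfig) -> list[VariableSpec]:
    soil = config.soil
    if soil.get("bundled_params", True):
        return load_sros2_params(soil.get("include_micronutrients", True))
    specs = []
    for name, entry in soil["variables"].items():
        specs.append(
            VariableSpec(
                name=name,
                means={t: float(v) for t, v in entry["means"].items()},
                sds={t: float(v) for t, v in entry["sds"].items()},
            )
        )
    return specs


def _validate_soil_table(table: pd.DataFrame) -> None:
    required = {"treatment", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"soil table missing columns {sorted(missing)}; expected schema: "
            "treatment, replicate, <numeric variables>"
        )
    value_cols = [c for c in table.columns if c not in required]
    bad = [c for c in value_cols if not pd.api.types.is_numeric_dtype(table[c])]
    if bad:
        raise ValueError(f"non-numeric variable columns: {bad}")


def _merged_table(
    config: PipelineConfig,
    soil_table: pd.DataFrame,
    stoich_table: pd.DataFrame | None,
    diversity_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    merged = soil_table.copy()
    merged["treatment"] = merged["treatment"].astype(str)
    order = {t: i + 1 for i, t in enumerate(config.treatments)}
    merged["treatment_ordinal"] = merged["treatment"].map(order)
    if stoich_table is None:
        stoich_table = enzyme_stoich.stoichiometry_table(soil_table)
    ratio_cols = ["ratio_cn", "ratio_nagl", "ratio_cp", "ratio_cppo"]
    ratios = stoich_table[["treatment", "replicate", *ratio_cols]].copy()
    ratios["treatment"] = ratios["treatment"].astype(str)
    merged = merged.merge(ratios, on=["treatment", "replicate"])
    for name, div in diversity_tables.items():
        d = div.copy()
        # sample ids are "<treatment>_r<replicate>"
        d["treatment"] = [s.rsplit("_r", 1)[0] for s in d.index]
        d["replicate"] = [int(s.rsplit("_r", 1)[1]) for s in d.index]
        d = d.rename(columns={"chao1": f"{name}_chao1", "simpson": f"{name}_simpson"})
        merged = merged.merge(
            d[["treatment", "replicate", f"{name}_chao1", f"{name}_simpson"]],
            on=["treatment", "replicate"],
        )
    return merged


def _config_dict(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "treatments": list(config.treatments),
        "n_replicates": config.n_replicates,
        "alpha": config.alpha,
        "stages": list(config.stages),
        "soil": config.soil,
        "counts": config.counts,
        "community": config.community,
        "network": config.network,
        "plspm": config.plspm,
    }
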