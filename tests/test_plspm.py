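"""PLS path modeling: OLS reduction, recovery, fit indices, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from rotastoich.plspm import (
    PathModelFit,
    PathModelSpec,
    ave,
    bootstrap_paths,
    fit_plspm,
    gof,
)
from rotastoich.synthetic import LatentSpec, SyntheticConfig, generate_latent_dataset


def _single_indicator_spec(names, edges, scheme="path"):
    return PathModelSpec(
        latents=tuple(names),
        blocks={n: (f"{n}_x",) for n in names},
        inner=tuple(edges),
        scheme=scheme,
    )


RECOVERY_MODEL = PathModelSpec(
    latents=("X", "Y"),
    blocks={"X": ("x1", "x2", "x3"), "Y": ("y1", "y2", "y3")},
    inner=(("Y", "X"),),
)


class TestFit:
    def test_two_single_indicator_latents_give_pearson_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = 0.6 * x + rng.normal(size=100)
        data = pd.DataFrame({"A_x": x, "B_x": y})
        fit = fit_plspm(data, _single_indicator_spec(["A", "B"], [("B", "A")]))
        r = np.corrcoef(x, y)[0, 1]
        assert fit.path_coefficients[("B", "A")] == pytest.approx(r, abs=1e-8)

    @pytest.mark.parametrize("scheme", ["centroid", "factorial", "path"])
    def test_single_indicator_chain_reduces_to_ols(self, scheme):
        # with single-indicator blocks PLS-PM is path analysis on
        # standardized observed variables: betas must equal OLS
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = 0.7 * a + rng.normal(scale=0.7, size=200)
        c = 0.5 * a - 0.6 * b + rng.normal(scale=0.5, size=200)
        data = pd.DataFrame({"A_x": a, "B_x": b, "C_x": c})
        spec = _single_indicator_spec(
            ["A", "B", "C"], [("B", "A"), ("C", "A"), ("C", "B")], scheme=scheme
        )
        fit = fit_plspm(data, spec)

        z = (data - data.mean()) / data.std(ddof=1)
        za, zb, zc = (z[c_].to_numpy() for c_ in ("A_x", "B_x", "C_x"))
        beta_b = np.linalg.lstsq(za[:, None], zb, rcond=None)[0]
        beta_c = np.linalg.lstsq(np.column_stack([za, zb]), zc, rcond=None)[0]
        assert fit.path_coefficients[("B", "A")] == pytest.approx(beta_b[0], abs=1e-8)
        assert fit.path_coefficients[("C", "A")] == pytest.approx(beta_c[0], abs=1e-8)
        assert fit.path_coefficients[("C", "B")] == pytest.approx(beta_c[1], abs=1e-8)

    def test_parameter_recovery(self, latent_recovery_dataset):
        fit = fit_plspm(latent_recovery_dataset.data, RECOVERY_MODEL)
        assert fit.path_coefficients[("Y", "X")] == pytest.approx(0.8, abs=0.1)
        for lam in fit.loadings.values():
            assert lam == pytest.approx(0.9, abs=0.1)

    def test_null_paths_stay_small(self):
        spec = LatentSpec(
            latents=["X", "Y"],
            blocks={"X": ["x1", "x2", "x3"], "Y": ["y1", "y2", "y3"]},
            loadings={k: 0.9 for k in ("x1", "x2", "x3", "y1", "y2", "y3")},
            paths={("Y", "X"): 0.0},
            n_samples=500,
        )
        ds = generate_latent_dataset(SyntheticConfig(seed=31, latent_spec=spec))
        fit = fit_plspm(ds.data, RECOVERY_MODEL)
        assert abs(fit.path_coefficients[("Y", "X")]) < 0.1

    def test_scores_have_unit_variance(self, latent_recovery_dataset):
        fit = fit_plspm(latent_recovery_dataset.data, RECOVERY_MODEL)
        for lv in fit.scores:
            assert fit.scores[lv].std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_scheme_agreement_on_well_conditioned_data(self, latent_recovery_dataset):
        fits = {
            s: fit_plspm(latent_recovery_dataset.data,
                         PathModelSpec(latents=RECOVERY_MODEL.latents,
                                       blocks=RECOVERY_MODEL.blocks,
                                       inner=RECOVERY_MODEL.inner, scheme=s))
            for s in ("centroid", "factorial", "path")
        }
        betas = [f.path_coefficients[("Y", "X")] for f in fits.values()]
        assert np.sign(betas[0]) == np.sign(betas[1]) == np.sign(betas[2])
        assert max(betas) - min(betas) < 0.05

    def test_constant_indicator_rejected(self):
        data = pd.DataFrame({"A_x": [1.0] * 20, "B_x": np.arange(20.0)})
        with pytest.raises(ValueError, match="constant"):
            fit_plspm(data, _single_indicator_spec(["A", "B"], [("B", "A")]))

    def test_missing_column_rejected(self):
        data = pd.DataFrame({"A_x": np.arange(20.0)})
        with pytest.raises(ValueError, match="indicator columns"):
            fit_plspm(data, _single_indicator_spec(["A", "B"], [("B", "A")]))


class TestSpecValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="lower-triangular"):
            _single_indicator_spec(["A", "B"], [("B", "A"), ("A", "B")])

    def test_unknown_latent_rejected(self):
        with pytest.raises(ValueError, match="unknown latent"):
            _single_indicator_spec(["A", "B"], [("B", "Z")])

    def test_disconnected_latent_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            _single_indicator_spec(["A", "B", "C"], [("B", "A")])

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError, match="empty indicator block"):
            PathModelSpec(latents=("A", "B"), blocks={"A": ("a",), "B": ()},
                          inner=(("B", "A"),))


class TestFitIndices:
    def _manual_fit(self, loadings, r2):
        return PathModelFit(
            spec=None, outer_weights={}, loadings=dict(loadings),
            communalities={k: v**2 for k, v in loadings.items()},
            scores=pd.DataFrame(), path_coefficients={("Y", "X"): 0.7},
            r2=dict(r2),
            ave={}, gof=0.0, iterations=1, tolerance_reached=0.0,
        )

    def test_gof_closed_form_cases(self):
        perfect = self._manual_fit({"a": 1.0, "b": 1.0}, {"Y": 1.0})
        assert gof(perfect) == pytest.approx(1.0)
        single = self._manual_fit({"a": 1.0, "b": 1.0}, {"Y": 0.49})
        assert gof(single) == pytest.approx(0.7)

    def test_gof_identity_with_stored_value(self, latent_recovery_dataset):
        fit = fit_plspm(latent_recovery_dataset.data, RECOVERY_MODEL)
        assert gof(fit) == pytest.approx(fit.gof, abs=1e-12)

    def test_gof_r2_exact_correlation_construction(self):
        # exact R^2 = 0.49 by orthogonal construction: y = 0.7 x + sqrt(0.51) e
        # with e orthogonalized against x
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        x = (x - x.mean()) / x.std(ddof=1)
        e = rng.normal(size=400)
        e -= e.mean()
        e -= x * (e @ x) / (x @ x)
        e /= e.std(ddof=1)
        y = 0.7 * x + np.sqrt(0.51) * e
        data = pd.DataFrame({"A_x": x, "B_x": y})
        fit = fit_plspm(data, _single_indicator_spec(["A", "B"], [("B", "A")]))
        assert fit.r2["B"] == pytest.approx(0.49, abs=1e-10)
        assert fit.gof == pytest.approx(0.7, abs=1e-10)

    def test_excellent_fit_threshold(self):
        good = self._manual_fit({"a": 1.0}, {"Y": 0.5})
        good.gof = gof(good)
        assert good.excellent_fit  # sqrt(0.5) ~ 0.707 > 0.6
        poor = self._manual_fit({"a": 1.0}, {"Y": 0.25})
        poor.gof = gof(poor)
        assert not poor.excellent_fit

    def test_no_endogenous_latent_rejected(self):
        fit = self._manual_fit({"a": 1.0}, {})
        with pytest.raises(ValueError, match="endogenous"):
            gof(fit)

    def test_ave(self, latent_recovery_dataset):
        fit = fit_plspm(latent_recovery_dataset.data, RECOVERY_MODEL)
        vals = ave(fit)
        for lv in ("X", "Y"):
            expected = np.mean(
                [fit.loadings[i] ** 2 for i in RECOVERY_MODEL.blocks[lv]]
            )
            assert vals[lv] == pytest.approx(expected, abs=1e-12)
            assert 0 <= vals[lv] <= 1

    def test_ave_single_indicator_is_one(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({"A_x": rng.normal(size=50),
                             "B_x": rng.normal(size=50)})
        fit = fit_plspm(data, _single_indicator_spec(["A", "B"], [("B", "A")]))
        assert fit.ave["A"] == pytest.approx(1.0)


class TestBootstrap:
    def test_seed_determinism(self, latent_recovery_dataset):
        b1 = bootstrap_paths(latent_recovery_dataset.data, RECOVERY_MODEL,
                             n_boot=100, seed=5)
        b2 = bootstrap_paths(latent_recovery_dataset.data, RECOVERY_MODEL,
                             n_boot=100, seed=5)
        assert b1.paths == b2.paths

    def test_strong_path_ci_excludes_zero(self, latent_recovery_dataset):
        b = bootstrap_paths(latent_recovery_dataset.data, RECOVERY_MODEL,
                            n_boot=200, seed=1)
        ci = b.paths[("Y", "X")]
        assert ci["ci_low"] > 0
        assert ci["p"] < 0.05

    def test_minimum_boot_enforced(self, latent_recovery_dataset):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_paths(latent_recovery_dataset.data, RECOVERY_MODEL, n_boot=50)
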