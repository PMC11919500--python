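"""Contextual-analysis models: GLMM estimation, VIF screening, FDR, summaries."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oracles import bh_stepup
from socsel.records import PredationRecord
from socsel.selection import (
    PAIR_COLUMNS,
    compute_vif,
    fdr_adjust,
    fit_contextual_model,
    fit_glmm_pql,
    mean_gradient_summary,
    predation_index,
    run_all_models,
    screen_collinearity,
)
from socsel.synthetic import scenario, simulate_model_data


class TestPredationIndex:
    def test_rate(self):
        idx = predation_index([PredationRecord("colA", 2010, 4, 20.0)])
        assert idx["predation_index"].iloc[0] == pytest.approx(0.2)

    def test_zero_predators(self):
        idx = predation_index([PredationRecord("colA", 2010, 0, 10.0)])
        assert idx["predation_index"].iloc[0] == 0.0

    def test_ratio_invariance(self):
        a = predation_index([PredationRecord("c", 2010, 3, 15.0)])
        b = predation_index([PredationRecord("c", 2010, 6, 30.0)])
        assert a["predation_index"].iloc[0] == b["predation_index"].iloc[0]


class TestVIF:
    def test_orthogonal_predictors_are_one(self, rng):
        n = 400
        design = pd.DataFrame(
            np.linalg.qr(rng.normal(size=(n, 3)))[0], columns=list("abc")
        )
        vifs = compute_vif(design)
        assert np.allclose(vifs, 1.0, atol=1e-3)

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.normal(size=200)
        design = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=200)})
        vifs = compute_vif(design)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_matches_closed_form_for_known_covariance(self, rng):
        # x3 = a*x1 + b*x2 + e with unit-variance components:
        # R2 of x3 on (x1,x2) -> a^2+b^2 over a^2+b^2+s2
        a, b, s = 0.8, 0.5, 0.4
        n = 200_000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        x3 = a * x1 + b * x2 + s * rng.normal(size=n)
        design = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        vifs = compute_vif(design)
        r2 = (a**2 + b**2) / (a**2 + b**2 + s**2)
        assert vifs["x3"] == pytest.approx(1 / (1 - r2), rel=0.02)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        n = 500
        base = rng.normal(size=(n, 3))
        design = pd.DataFrame(
            np.column_stack([base, base @ [0.5, 0.4, 0.0] + 0.3 * rng.normal(size=n)]),
            columns=list("abcd"),
        )
        mine = compute_vif(design)
        X = np.column_stack([np.ones(n), design.to_numpy()])
        for j, col in enumerate(design.columns):
            ref = variance_inflation_factor(X, j + 1)
            assert mine[col] == pytest.approx(ref, rel=1e-6)


class TestScreen:
    def make_design(self, rng, collinear=False):
        n = 400
        cols = {}
        for icol, gcol in PAIR_COLUMNS:
            cols[icol] = rng.normal(size=n)
            cols[gcol] = rng.normal(size=n)
        if collinear:
            cols["dPg_density"] = (
                0.8 * cols["dPg_avg_path_length"]
                + 0.55 * cols["dPg_transitivity"]
                + 0.2 * rng.normal(size=n)
            )
        return pd.DataFrame(cols)

    def test_clean_design_unchanged(self, rng):
        design = self.make_design(rng)
        out, removed, _ = screen_collinearity(design)
        assert removed == [] and list(out.columns) == list(design.columns)

    def test_offending_pair_removed_as_unit(self, rng):
        design = self.make_design(rng, collinear=True)
        vifs = compute_vif(design)
        assert vifs["dPg_density"] > 5
        out, removed, final_vifs = screen_collinearity(design)
        assert removed == [("dPi_degree", "dPg_density")]
        assert "dPi_degree" not in out.columns and "dPg_density" not in out.columns
        assert final_vifs.drop(["dPi_degree", "dPg_density"], errors="ignore").max() <= 5


class TestGLMM:
    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=50)})
        with pytest.raises(ValueError, match="degenerate"):
            fit_glmm_pql(np.ones(50), X, np.arange(50), np.zeros(50))

    def test_glm_limit_without_random_effects(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        eta = X @ [0.2, -0.6, 0.9]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = fit_glmm_pql(
            y, pd.DataFrame(X, columns=["intercept", "a", "b"]),
            np.arange(n), rng.integers(0, 8, n),
        )
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.params.to_numpy() - glm.params)) < 1e-3
        assert np.max(np.abs(fit.se.to_numpy() - glm.bse)) < 1e-3
        # at least one variance component collapses and is flagged, not silent
        assert fit.boundary
        assert max(fit.vcomp.values()) < 0.05

    def test_poisson_glm_limit(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 1))])
        y = rng.poisson(np.exp(X @ [1.0, 0.4]))
        fit = fit_glmm_pql(
            y, pd.DataFrame(X, columns=["intercept", "a"]),
            np.arange(n), rng.integers(0, 5, n), family="poisson",
        )
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.params.to_numpy() - glm.params)) < 1e-3

    def test_agrees_with_lme4_glmer_on_fixture(self):
        """Independent-oracle check: same small dataset fitted with lme4."""
        rng = np.random.default_rng(42)
        G, m, years = 60, 6, 5
        rows = []
        yr_eff = rng.normal(0, 0.3, years)
        for g in range(G):
            dpg = rng.normal()
            dpi = rng.normal(size=m)
            dpi = (dpi - dpi.mean()) / dpi.std(ddof=1)
            for j in range(m):
                rows.append((f"i{g}_{j}", 2000 + g % years, dpi[j], dpg))
        df = pd.DataFrame(rows, columns=["id", "year", "dpi", "dpg"])
        uniq = df.drop_duplicates(subset=["dpg"])
        df["dpg"] = (df["dpg"] - uniq["dpg"].mean()) / uniq["dpg"].std(ddof=1)
        u = rng.normal(0, 0.3, len(df))
        eta = (
            0.4 - 0.5 * df.dpi + 0.8 * df.dpg + u
            + np.array([yr_eff[y - 2000] for y in df.year])
        )
        df["y"] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = fit_glmm_pql(
            df.y.to_numpy(dtype=float),
            pd.DataFrame({"intercept": 1.0, "dpi": df.dpi, "dpg": df.dpg}),
            df.id.to_numpy(), df.year.to_numpy(),
        )
        script = (
            "d <- read.csv('data.csv');"
            "suppressMessages(library(lme4));"
            "m <- glmer(y ~ dpi + dpg + (1|id) + (1|year), data=d,"
            " family=binomial, control=glmerControl(optimizer='bobyqa',"
            " optCtrl=list(maxfun=10000)));"
            "cat(fixef(m), sep='\\n')"
        )
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            df.to_csv(os.path.join(d, "data.csv"), index=False)
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, cwd=d,
                timeout=300,
            )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.strip().split("\n")])
        assert np.max(np.abs(fit.params.to_numpy() - ref)) < 0.05


@pytest.fixture(scope="module")
def population_data():
    """Trait-level data covering all cohorts and responses."""
    rng = np.random.default_rng(7)
    cfg = scenario("null", seed=7)
    data = simulate_model_data(cfg, n_groups=80, mean_size=8, rng=rng)
    # spread rows over cohorts to populate every model
    n = len(data)
    data["sex"] = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    data["age_class"] = rng.choice(["adult", "yearling"], size=n, p=[0.6, 0.4])
    data["weaned"] = np.where(
        (data["sex"] == "F") & (data["age_class"] == "adult"),
        rng.binomial(1, 0.5, n), np.nan,
    )
    data["n_weaned"] = np.where(data["weaned"] == 1, rng.poisson(3, n) + 1, np.nan)
    data["summer_survival"] = np.where(
        data["age_class"] == "adult", rng.binomial(1, 0.9, n), np.nan
    )
    return data


class TestModelSuite:
    def test_eight_models_with_correct_cohorts(self, population_data):
        results, manifest = run_all_models(population_data)
        fitted = {r.spec.name for r in results}
        assert len(manifest["models"]) == 8
        repro = {n for n in fitted if n.startswith(("weaned", "n_weaned"))}
        assert repro <= {"weaned:adult_F", "n_weaned:adult_F"}
        assert not any("yearling" in n for n in fitted if "summer" in n)

    def test_hibernation_models_exclude_degree_density(self, population_data):
        results, _ = run_all_models(population_data)
        for res in results:
            if res.spec.response == "hibernation_survival":
                assert "dPi_degree" not in res.table.index
                assert "dPg_density" not in res.table.index
                assert ("dPi_degree", "dPg_density") in res.removed_pairs

    def test_fdr_column_dominates_raw_p(self, population_data):
        results, _ = run_all_models(population_data)
        for res in results:
            ok = res.table["p_fdr"].notna()
            assert (res.table.loc[ok, "p_fdr"] >= res.table.loc[ok, "p"] - 1e-12).all()


class TestFDR:
    def test_worked_example_all_point_oh_eight(self):
        p = [0.01 * k for k in range(1, 9)]
        adj = fdr_adjust(p)
        assert np.allclose(adj, 0.08)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_dominance_and_reference_agreement(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            adj = fdr_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
            assert np.allclose(adj, bh_stepup(p))

    def test_nan_preserved(self):
        adj = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestSummary:
    def _result(self, betas):
        from socsel.selection import ModelSpec, SelectionResult

        table = pd.DataFrame(
            {
                "beta": list(betas.values()),
                "se": 0.1, "z": 1.0, "p": 0.3, "vif": 1.0,
                "level": [
                    "individual" if k.startswith("dPi_") else "group"
                    for k in betas
                ],
            },
            index=list(betas),
        )
        spec = ModelSpec("hibernation_survival", "adult_F", "binomial")
        return SelectionResult(spec, table, True, [], 10, 10)

    def test_opposite_signs_give_magnitude_mean(self):
        res = self._result({"dPi_degree": 1.0, "dPi_closeness": -1.0})
        out = mean_gradient_summary([res])
        assert out["individual_mean"] == pytest.approx(1.0)

    def test_single_gradient_has_na_se(self):
        res = self._result({"dPg_density": 0.7})
        out = mean_gradient_summary([res])
        assert np.isnan(out["group_se"]) and out["group_mean"] == pytest.approx(0.7)

    def test_matches_direct_recomputation(self, rng):
        results = [
            self._result(
                {
                    "dPi_degree": rng.normal(),
                    "dPg_density": rng.normal(),
                    "dPi_closeness": rng.normal(),
                }
            )
            for _ in range(4)
        ]
        out = mean_gradient_summary(results)
        ind = np.abs(
            [r.table.loc[k, "beta"] for r in results
             for k in r.table.index if k.startswith("dPi_")]
        )
        assert out["individual_mean"] == pytest.approx(ind.mean())
        assert out["individual_se"] == pytest.approx(
            ind.std(ddof=1) / np.sqrt(len(ind))
        )


def test_sign_flip_equivariance_of_gradients(rng):
    """Negating a predictor column negates its fitted gradient exactly."""
    cfg = scenario("antagonistic_between", seed=11)
    data = simulate_model_data(cfg, n_groups=60, mean_size=7, rng=rng)
    from socsel.selection import ModelSpec

    spec = ModelSpec("hibernation_survival", "adult_F", "binomial", ("august_mass",))
    base = fit_contextual_model(spec, data)
    flipped_data = data.copy()
    flipped_data["dPg_avg_path_length"] = -flipped_data["dPg_avg_path_length"]
    flipped = fit_contextual_model(spec, flipped_data)
    assert flipped.table.loc["dPg_avg_path_length", "beta"] == pytest.approx(
        -base.table.loc["dPg_avg_path_length", "beta"], abs=1e-6
    )
    assert flipped.table.loc["dPi_closeness", "beta"] == pytest.approx(
        base.table.loc["dPi_closeness", "beta"], abs=1e-6
    )
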