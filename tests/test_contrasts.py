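import numpy as np
import pandas as pd
import pytest

import guildquant as gq
from guildquant.contrasts import (
    fit_glm_irls,
    one_vs_rest_rotation,
    significance_stars,
    summarize_table,
)
from guildquant.errors import ConfigError, InsufficientDataError


def ols_oracle(y, X):
    """Independent normal-equations solution: (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestGLMFit:
    def test_irls_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            y = rng.normal(size=n)
            fit = fit_glm_irls(y, X)
            worst = max(worst, float(np.max(np.abs(fit.params - ols_oracle(y, X)))))
        assert worst < 1e-8

    def test_noiseless_binary_design_is_exact(self):
        x = np.array([0.0, 1.0] * 10)
        y = 0.3 - 0.25 * x
        fit = fit_glm_irls(y, np.column_stack([np.ones_like(x), x]))
        assert fit.params[0] == pytest.approx(0.3, abs=1e-12)
        assert fit.params[1] == pytest.approx(-0.25, abs=1e-12)

    def test_intercept_only_model_is_the_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = fit_glm_irls(y, np.ones((4, 1)))
        assert fit.params[0] == pytest.approx(y.mean())
        assert fit.metrics.deviance == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_metrics_are_well_formed(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = 1.0 + 0.5 * X[:, 1] + rng.normal(0, 0.3, 50)
        m = fit_glm_irls(y, X).metrics
        assert m.deviance >= 0
        assert m.pearson_chi2 >= 0
        assert 0.0 <= m.pseudo_r2_cragg_uhler <= 1.0

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ConfigError):
            fit_glm_irls(np.zeros(10), X)

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_glm_irls(np.zeros(2), np.eye(2, 3))


def score_frame(categories, values, gene="amt"):
    rows = []
    for cat, vals in zip(categories, values):
        for v in vals:
            rows.append((gene, "T", cat, "epipelagic", 1.0, 1, 1.0, np.exp(v), np.exp(v), v, v))
    return pd.DataFrame(rows, columns=gq.scores_to_frame([]).columns.tolist() or [
        "gene", "taxon", "station_class", "layer", "A", "d_obs", "d_exp",
        "delta", "k", "log_delta", "log_k",
    ])


class TestRotation:
    def test_two_categories_have_opposite_coefficients(self):
        rng = np.random.default_rng(2)
        df = score_frame(["OMZ", "NAtl"], [rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)])
        out = one_vs_rest_rotation(df, axes=("station",), by_guild_class=False)
        a = next(c for c in out if c.focal_context == "OMZ")
        b = next(c for c in out if c.focal_context == "NAtl")
        assert a.coef == pytest.approx(-b.coef, abs=1e-12)
        assert a.std_err == pytest.approx(b.std_err, rel=1e-9)

    def test_coefficients_reconstruct_category_means(self):
        rng = np.random.default_rng(3)
        cats = ["OMZ", "NAtl", "SAtl"]
        vals = [rng.normal(m, 0.5, 40) for m in (0.0, 0.3, -0.2)]
        df = score_frame(cats, vals)
        out = one_vs_rest_rotation(df, axes=("station",), by_guild_class=False)
        y = df["log_delta"].to_numpy()
        for c in out:
            focal = df["station_class"] == c.focal_context
            expected = y[focal].mean() - y[~focal].mean()
            assert c.coef == pytest.approx(expected, abs=1e-10)

    def test_recovery_of_injected_shift_within_3_se(self, small_cruise_cfg):
        cfg = gq.SimulationConfig(
            **{**small_cruise_cfg.__dict__, "delta_multipliers": {"OMZ": 0.8}, "seed": 31}
        )
        strata = gq.simulate_strata(cfg)
        res = gq.RichnessAbundanceModel.from_dataframe(strata).fit()
        out = one_vs_rest_rotation(
            res.score_frame(), axes=("station",), by_guild_class=False
        )
        c = next(x for x in out if x.focal_context == "OMZ")
        assert abs(c.coef - np.log(0.8)) < 3 * c.std_err

    def test_tiny_category_skipped_others_emitted(self):
        rng = np.random.default_rng(4)
        df = score_frame(
            ["OMZ", "NAtl", "SAtl"],
            [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(0, 1, 1)],
        )
        out = one_vs_rest_rotation(df, axes=("station",), by_guild_class=False)
        assert {c.focal_context for c in out} == {"OMZ", "NAtl"}

    def test_empty_scores_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_vs_rest_rotation(pd.DataFrame())


class TestSummary:
    def make(self, p):
        return gq.ContrastResult("OMZ", "station", "N_uptake", -0.2, 0.07, p, 100, 20)

    def test_star_thresholds(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.002) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(1e-5) == "****"

    def test_p_0002_is_significant_at_alpha_005(self):
        tab = summarize_table([self.make(0.002)], alpha=0.05)
        row = tab.iloc[0]
        assert row["significant"] and row["stars"] != ""

    def test_p_02_is_not_starred(self):
        tab = summarize_table([self.make(0.2)])
        assert tab.iloc[0]["stars"] == "" and not tab.iloc[0]["significant"]

    def test_stations_ordered_before_layers(self):
        contrasts = [
            gq.ContrastResult("mesopelagic", "layer", "N_uptake", 0.1, 0.05, 0.1, 50, 10),
            gq.ContrastResult("OMZ", "station", "N_uptake", -0.2, 0.05, 0.01, 50, 10),
        ]
        tab = summarize_table(contrasts)
        assert list(tab["axis"]) == ["station", "layer"]

    def test_empty_contrast_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_table([])


def test_model_results_roundtrip(null_cruise):
    _, (_, _, _, _, _, scores) = null_cruise
    res = gq.DeltaContrastModel.from_scores(scores).fit()
    # 4 station classes + 3 layers, per guild class
    assert len(res.contrasts) == 2 * (4 + 3)
    text = res.summary()
    assert "OMZ" in text and "bathypelagic" in text
    omz = res.get("OMZ", "N_uptake")
    assert omz.axis == "station" and omz.n_focal > 0
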