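import numpy as np
import pandas as pd
import pytest

import guildquant as gq
from guildquant.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ReferenceLookupError,
)
from guildquant.simulate import exact_power_law_strata


class TestFit:
    def test_exact_recovery_on_noiseless_points(self):
        df = exact_power_law_strata(2.0, 0.5, range(5, 51))
        fit = gq.fit_diversity_model(df)
        assert fit.c == pytest.approx(2.0, rel=1e-9)
        assert fit.gamma == pytest.approx(0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_richness_fits_flat(self):
        df = pd.DataFrame(
            {"gene": "g", "taxon": "t", "station_class": "average_ocean",
             "layer": "epipelagic", "A": [10.0, 100.0, 1000.0], "d_obs": [7, 7, 7]}
        )
        fit = gq.fit_diversity_model(df)
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert fit.c == pytest.approx(7.0, rel=1e-12)

    def test_noisy_recovery_within_3_se(self):
        df = gq.simulate_power_law_strata(500, 3.0, 0.4, noise_sigma=0.2, seed=11)
        fit = gq.fit_diversity_model(df)
        assert abs(fit.gamma - 0.4) < 3 * fit.se_gamma
        assert abs(np.log(fit.c) - np.log(3.0)) < 3 * fit.se_log_c

    def test_gamma_estimator_unbiased_across_replicates(self):
        """Mean bias of γ̂ within ±0.02 over 20 seeded replicates."""
        gammas = [
            gq.fit_diversity_model(
                gq.simulate_power_law_strata(500, 3.0, 0.4, noise_sigma=0.2, seed=s)
            ).gamma
            for s in range(20)
        ]
        assert abs(np.mean(gammas) - 0.4) < 0.02

    def test_too_few_strata_rejected(self):
        df = exact_power_law_strata(2.0, 0.5, [5, 10])
        with pytest.raises(InsufficientDataError):
            gq.fit_diversity_model(df)

    def test_zero_abundance_variance_rejected(self):
        df = pd.DataFrame(
            {"gene": "g", "taxon": list("abc"), "station_class": "average_ocean",
             "layer": "epipelagic", "A": [5.0, 5.0, 5.0], "d_obs": [3, 4, 5]}
        )
        with pytest.raises(DegenerateInputError):
            gq.fit_diversity_model(df)


class TestScores:
    FIT = gq.DiversityFit("g", c=2.0, gamma=0.5, n_points=10, r_squared=1.0,
                          resid_sd=0.0, se_log_c=0.01, se_gamma=0.01)

    def stratum(self, d_obs):
        return pd.DataFrame(
            {"gene": "g", "taxon": "t", "station_class": "OMZ",
             "layer": "mesopelagic", "A": [100.0], "d_obs": [d_obs]}
        )

    def test_on_curve_stratum_has_delta_one(self):
        (s,) = gq.score_strata(self.stratum(20), {"g": self.FIT})
        assert s.d_exp == pytest.approx(20.0)
        assert s.delta == pytest.approx(1.0)
        assert s.log_delta == pytest.approx(0.0, abs=1e-12)
        assert s.k == pytest.approx(100.0)

    def test_doubled_richness_doubles_delta_and_k(self):
        (s,) = gq.score_strata(self.stratum(40), {"g": self.FIT})
        assert s.delta == pytest.approx(2.0)
        assert s.k == pytest.approx(200.0)

    def test_delta_rewards_and_penalizes_k_monotonically(self):
        over = gq.score_strata(self.stratum(30), {"g": self.FIT})[0]
        under = gq.score_strata(self.stratum(10), {"g": self.FIT})[0]
        assert over.k > over.A and under.k < under.A

    def test_missing_fit_names_gene(self):
        with pytest.raises(ReferenceLookupError, match="g"):
            gq.score_strata(self.stratum(20), {})

    def test_k_over_A_is_delta_identically(self, null_cruise):
        _, (_, _, _, _, _, scores) = null_cruise
        for s in scores[::97]:
            assert s.k / s.A == pytest.approx(s.delta, rel=1e-12)

    def test_scoring_commutes_with_permutation(self):
        df = gq.simulate_power_law_strata(50, 2.0, 0.5, noise_sigma=0.3, seed=2)
        fit = gq.fit_diversity_model(df)
        fwd = gq.score_strata(df, {"gene": fit})
        rev = gq.score_strata(df.iloc[::-1], {"gene": fit})
        assert [s.delta for s in fwd] == pytest.approx([s.delta for s in reversed(rev)], rel=1e-12)


def test_injected_multiplier_shifts_mean_log_delta(small_cruise_cfg):
    cfg = gq.SimulationConfig(
        **{**small_cruise_cfg.__dict__, "delta_multipliers": {"OMZ": 0.8}, "seed": 17}
    )
    strata = gq.simulate_strata(cfg)
    res = gq.RichnessAbundanceModel.from_dataframe(strata).fit()
    sf = res.score_frame()
    shift = (
        sf.loc[sf.station_class == "OMZ", "log_delta"].mean()
        - sf.loc[sf.station_class != "OMZ", "log_delta"].mean()
    )
    assert shift == pytest.approx(np.log(0.8), abs=0.08)


class TestRadialExport:
    @staticmethod
    def scores(n_taxa):
        df = pd.DataFrame(
            {"gene": "amt", "taxon": [f"T{i:03d}" for i in range(n_taxa)],
             "station_class": "average_ocean", "layer": "epipelagic",
             "A": np.linspace(10, 100, n_taxa), "d_obs": 5}
        )
        fit = gq.DiversityFit("amt", 2.0, 0.5, 10, 1.0, 0.0, 0.01, 0.01)
        return gq.score_strata(df, {"amt": fit})

    def test_top25_of_30_taxa_gives_26_rows_per_gene_cell(self):
        out = gq.radial_export(self.scores(30), top_n=25)
        assert len(out) == 26
        assert (out["taxon"] == "Others").sum() == 1
        assert set(out["guild_class"]) == {"N_uptake"}

    def test_single_taxon_is_identity(self):
        (score,) = self.scores(1)
        out = gq.radial_export([score], top_n=25)
        assert len(out) == 1
        assert out["log_k"].iloc[0] == pytest.approx(score.log_k)

    def test_export_roundtrips_log_k_at_full_precision(self, tmp_path):
        from guildquant import io as gio

        out = gq.radial_export(self.scores(30), top_n=25)
        p = tmp_path / "radial.tsv"
        gio.write_table(out, p)
        back = gio.read_table(p)
        assert list(back["log_k"]) == list(out["log_k"])

    def test_unknown_gene_grouping_is_config_error(self):
        from guildquant.errors import ConfigError

        with pytest.raises(ConfigError):
            gq.radial_export(self.scores(3), top_n=2, gene_order={"nirK": "N_redox"})


class TestModelObjects:
    def test_results_params_and_summary(self, null_cruise):
        _, (_, _, _, _, results, _) = null_cruise
        params = results.params
        assert set(params["gene"]) == set(gq.MARKER_GENES)
        assert (params["c"] > 0).all()
        text = results.summary()
        assert "gamma" in text and "amt" in text

    def test_per_taxon_fits_are_finer(self):
        df = pd.concat(
            [
                gq.simulate_power_law_strata(60, 2.0, 0.5, 0.2, seed=s, gene="amt")
                for s in (1, 2)
            ]
        )
        df["taxon"] = ["X"] * 60 + ["Y"] * 60
        res = gq.RichnessAbundanceModel.from_dataframe(df, per_taxon=True).fit()
        assert set(res.fits) == {"amt|X", "amt|Y"}
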