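import numpy as np
import pandas as pd
import pytest

import guildquant as gq
from guildquant.errors import ConfigError
from guildquant.simulate import round_half_away


def test_same_seed_identical_output(small_cruise_cfg):
    r1, m1, t1 = gq.simulate_dataset(small_cruise_cfg)
    r2, m2, t2 = gq.simulate_dataset(small_cruise_cfg)
    assert r1 == r2
    assert m1 == m2
    pd.testing.assert_frame_equal(t1, t2)
    r3, _, _ = gq.simulate_dataset(gq.with_seed(small_cruise_cfg, 6))
    assert r1 != r3


def test_noiseless_richness_sits_on_the_curve(small_cruise_cfg):
    cfg = gq.SimulationConfig(**{**small_cruise_cfg.__dict__, "noise_sigma_ln": 0.0})
    truth = gq.simulate_strata(cfg)
    expect = np.maximum(
        round_half_away(truth["c"] * truth["A"] ** truth["gamma"]), 1
    ).astype(int)
    assert (truth["d_obs"] == expect).all()


def test_context_multiplier_halves_on_curve_richness(small_cruise_cfg):
    base = {**small_cruise_cfg.__dict__, "noise_sigma_ln": 0.0}
    cfg = gq.SimulationConfig(**{**base, "delta_multipliers": {"OMZ": 0.5}})
    truth = gq.simulate_strata(cfg)
    omz = truth[truth["station_class"] == "OMZ"]
    expect = np.maximum(
        round_half_away(0.5 * omz["c"] * omz["A"] ** omz["gamma"]), 1
    ).astype(int)
    assert (omz["d_obs"] == expect).all()
    assert (truth.loc[truth["station_class"] != "OMZ", "multiplier"] == 1.0).all()


def test_total_abundance_is_one_million_fpm(null_cruise):
    _, (_, _, truth, strata, _, _) = null_cruise
    assert truth["A"].sum() == pytest.approx(1e6, rel=1e-9)
    assert sum(s.A for s in strata) == pytest.approx(1e6, rel=1e-6)


def test_aggregation_reproduces_generator_truth(null_cruise):
    """Expanding strata to ORF rows and re-aggregating is exact bookkeeping."""
    _, (_, _, truth, strata, _, _) = null_cruise
    key = ["gene", "taxon", "station_class", "layer"]
    obs = gq.strata_to_frame(strata).set_index(key).sort_index()
    exp = truth.set_index(key).sort_index()
    assert len(obs) == len(exp)
    assert np.allclose(obs["A"], exp["A"], rtol=1e-9)
    assert (obs["d_obs"] == exp["d_obs"]).all()


def test_loglog_regression_recovers_truth_within_3_se():
    df = gq.simulate_power_law_strata(200, 2.5, 0.55, noise_sigma=0.25, seed=9)
    fit = gq.fit_diversity_model(df)
    assert abs(fit.gamma - 0.55) < 3 * fit.se_gamma
    assert abs(np.log(fit.c) - np.log(2.5)) < 3 * fit.se_log_c


def test_taxon_turnover_matches_configured_fraction():
    cfg = gq.SimulationConfig(n_taxa_per_layer=120, turnover_shared_frac=0.4, seed=3)
    records, metadata, truth = (None, None, gq.simulate_strata(cfg))
    by_layer = {
        layer: set(truth.loc[truth["layer"] == layer, "taxon"]) for layer in gq.LAYERS
    }
    for a, b in [("epipelagic", "mesopelagic"), ("mesopelagic", "bathypelagic")]:
        shared = len(by_layer[a] & by_layer[b]) / cfg.n_taxa_per_layer
        assert abs(shared - 0.4) <= 0.05


class TestNPProfiles:
    def test_omz_peak_depth_and_value(self, null_cruise):
        cfg, (_, metadata, *_3) = null_cruise
        profiles = {p.station_id: p for p in gq.profiles_from_metadata(metadata)}
        depth, value = gq.mesopelagic_maximum(profiles["st120"])
        assert (depth, value) == (210.0, pytest.approx(12.4, abs=1e-9))

    def test_natl_peak_value(self, null_cruise):
        cfg, (_, metadata, *_3) = null_cruise
        profiles = {p.station_id: p for p in gq.profiles_from_metadata(metadata)}
        _, value = gq.mesopelagic_maximum(profiles["st141"])
        assert value == pytest.approx(18.96, abs=1e-9)

    def test_average_maxima_strictly_between_extremes(self, null_cruise):
        cfg, (_, metadata, *_3) = null_cruise
        special = {"st120", "st141"}
        for p in gq.profiles_from_metadata(metadata):
            if p.station_id in special:
                continue
            _, value = gq.mesopelagic_maximum(p)
            assert 12.4 < value < 18.96


class TestPlacementSimulation:
    CLADES = (
        gq.CladeSpec("cladeA", "functional", n_queries=10),
        gq.CladeSpec("cladeB", "non_functional", n_queries=5),
    )

    def test_truth_split_matches_config(self):
        _, ps, truth = gq.simulate_placements(
            gq.PlacementSimConfig("nifH", self.CLADES, seed=1)
        )
        assert truth["label"].value_counts().to_dict() == {
            "functional": 10,
            "non_functional": 5,
        }
        assert len(ps.by_query()) == 15

    def test_determinism(self):
        out1 = gq.simulate_placements(gq.PlacementSimConfig("nifH", self.CLADES, seed=1))
        out2 = gq.simulate_placements(gq.PlacementSimConfig("nifH", self.CLADES, seed=1))
        assert [(p.query_id, p.edge_ref, p.like_weight_ratio) for p in out1[1].placements] == [
            (p.query_id, p.edge_ref, p.like_weight_ratio) for p in out2[1].placements
        ]

    def test_zero_queries_is_fine(self):
        clades = (
            gq.CladeSpec("cladeA", "functional"),
            gq.CladeSpec("cladeB", "non_functional"),
        )
        _, ps, truth = gq.simulate_placements(gq.PlacementSimConfig("nifH", clades))
        assert ps.placements == [] and truth.empty

    def test_requires_a_non_functional_clade(self):
        with pytest.raises(ConfigError):
            gq.PlacementSimConfig(
                "nifH",
                (gq.CladeSpec("a", "functional"), gq.CladeSpec("b", "functional")),
            )


def test_config_validation():
    with pytest.raises(ConfigError):
        gq.SimulationConfig(delta_multipliers={"OMZ": 0.0})
    with pytest.raises(ConfigError):
        gq.SimulationConfig(turnover_shared_frac=1.5)
    with pytest.raises(ConfigError):
        gq.GeneSpec("amt", c=-1.0, gamma=0.5)


def test_config_yaml_roundtrip(tmp_path):
    p = tmp_path / "sim.yaml"
    p.write_text(
        "seed: 9\nn_taxa_per_layer: 7\nnoise_sigma_ln: 0.1\n"
        "stations:\n  - {station_id: stA, station_class: OMZ, np_shape: omz_like}\n"
        "  - {station_id: stB}\n  - {station_id: stC}\n"
        "genes:\n  - {gene: amt, c: 2.0, gamma: 0.5}\n"
        "depths_m: [70, 430, 2000]\n"
    )
    cfg = gq.SimulationConfig.from_yaml(p)
    assert cfg.seed == 9 and cfg.n_taxa_per_layer == 7
    assert cfg.stations[0].station_class == "OMZ"
    assert cfg.genes[0].c == 2.0
    gq.simulate_strata(cfg)  # usable end to end
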