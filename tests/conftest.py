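import pytest

import guildquant as gq


def run_pipeline(cfg):
    """Full analysis chain on one synthetic cruise: simulate, normalize,
    aggregate, fit the power law, score."""
    records, metadata, truth = gq.simulate_dataset(cfg)
    strata = gq.aggregate_strata(
        gq.normalize_fpm(records), metadata, gq.station_class_map(cfg)
    )
    results = gq.RichnessAbundanceModel.from_strata(strata).fit()
    scores = results.score()
    return records, metadata, truth, strata, results, scores


@pytest.fixture(scope="session")
def null_cruise():
    """Default study conditions, no injected effects, seed fixed."""
    cfg = gq.SimulationConfig(seed=42)
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_cruise_cfg():
    """A lean cruise for fast per-test simulation."""
    return gq.SimulationConfig(
        stations=(
            gq.StationSpec("st120", "OMZ", "omz_like"),
            gq.StationSpec("st141", "NAtl", "natl_like"),
            gq.StationSpec("st001"),
            gq.StationSpec("st002"),
            gq.StationSpec("st003"),
        ),
        depths_m=(70.0, 430.0, 2000.0),
        genes=(gq.GeneSpec("amt", 3.0, 0.45), gq.GeneSpec("nirK", 2.6, 0.46)),
        n_taxa_per_layer=12,
        seed=5,
    )
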