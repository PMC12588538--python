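"""Synthetic cruise generator with known ground truth.

Emulates the statistical structure the guild analysis assumes, so every
downstream stage can be validated against a known truth:

* a multi-station, multi-depth cruise (default: 11 stations × 7 depths,
  one oxygen-minimum-zone-like column, one high-N:P column, one otherwise
  anomalous column, eight average ones);
* N:P vertical profiles per station shape (surface-depleted, mesopelagic
  maximum, convergence near Redfield at depth);
* per-layer taxon pools with configurable turnover between adjacent layers;
* per-stratum abundances drawn lognormally (heavy-tailed, spanning orders
  of magnitude) and globally rescaled to one million FPM;
* observed richness drawn on the power law d = c·A^γ, times an injectable
  per-context δ multiplier and multiplicative lognormal noise with unit
  median, rounded half-away-from-zero with a floor of one;
* per-ORF feature rows whose distinct ids and summed counts reproduce each
  stratum's (d_obs, A) exactly;
* labelled reference trees with placements drawn from known clades.

One seed fixes the full output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .datatypes import FeatureRecord, MARKER_GENES, SampleMetadata, assign_layer, LAYERS
from .errors import ConfigError
from .io import Placement, PlacementSet, ReferenceTree
import dendropy

FPM_TOTAL = 1_000_000.0

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationSpec:
    station_id: str
    station_class: str = "average_ocean"  # OMZ | NAtl | SAtl | average_ocean
    np_shape: str = "average"  # average | omz_like | natl_like


@dataclass(frozen=True)
class GeneSpec:
    """True power-law constants of one marker gene."""

    gene: str
    c: float
    gamma: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ConfigError(f"{self.gene}: c must be > 0")
        if not 0.0 < self.gamma <= 1.5:
            raise ConfigError(f"{self.gene}: gamma must be in (0, 1.5]")


@dataclass(frozen=True)
class NPShape:
    """Piecewise vertical N:P profile: linear rise from the surface value to
    a mesopelagic peak, then exponential relaxation to the deep value."""

    surface: float
    peak_depth_m: float
    peak_value: float
    deep_value: float
    relax_m: float = 700.0

    def value(self, depth_m: float) -> float:
        if depth_m <= self.peak_depth_m:
            f = depth_m / self.peak_depth_m if self.peak_depth_m > 0 else 1.0
            return self.surface + (self.peak_value - self.surface) * f
        return self.deep_value + (self.peak_value - self.deep_value) * math.exp(
            -(depth_m - self.peak_depth_m) / self.relax_m
        )


#: Default station shapes.  The average ocean peaks just past 400 m and
#: converges marginally below the Redfield ratio (16) at depth; the
#: OMZ-like column peaks low (12.4) and shallow (210 m) and stays the
#: lowest at depth; the high-N:P column peaks at 18.96 and stays highest.
NP_SHAPES: dict[str, NPShape] = {
    "average": NPShape(surface=8.0, peak_depth_m=430.0, peak_value=16.3, deep_value=15.5),
    "omz_like": NPShape(surface=6.0, peak_depth_m=210.0, peak_value=12.4, deep_value=11.5),
    "natl_like": NPShape(surface=8.5, peak_depth_m=430.0, peak_value=18.96, deep_value=16.8),
}


def _default_stations() -> tuple[StationSpec, ...]:
    avg = [StationSpec(f"st{n:03d}") for n in (10, 20, 43, 62, 74, 88, 103, 131)]
    return tuple(
        [
            StationSpec("st120", "OMZ", "omz_like"),
            StationSpec("st141", "NAtl", "natl_like"),
            StationSpec("st030", "SAtl", "average"),
        ]
        + avg
    )


def _default_genes() -> tuple[GeneSpec, ...]:
    # realistic per-gene constants: richness a few-to-tens of variants at
    # typical FPM, sublinear growth with abundance
    table = [
        ("amt", 3.0, 0.45), ("nrtA", 2.0, 0.50), ("tauA", 2.5, 0.45),
        ("potF", 2.2, 0.48), ("livJ", 2.8, 0.42), ("bztA", 3.2, 0.44),
        ("ilvC", 3.5, 0.40), ("amoA", 1.8, 0.52), ("nifH", 1.5, 0.55),
        ("nirK", 2.6, 0.46), ("ureC", 3.0, 0.43), ("uca", 1.6, 0.50),
        ("nxrA", 1.7, 0.52), ("nirS", 2.0, 0.48), ("nasA", 2.1, 0.47),
        ("narG", 2.4, 0.46), ("nosZ", 2.2, 0.47), ("hzsA", 1.4, 0.55),
    ]
    return tuple(GeneSpec(g, c, gm) for g, c, gm in table)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cruise.

    Defaults emulate the analysed survey: 11 stations with full vertical
    profiles (7 depths from 3 to 4000 m), the 18 nitrogen-cycle marker
    genes, 25 taxa per layer with half the taxa shared between adjacent
    layers, lognormal FPM spanning orders of magnitude, and multiplicative
    richness noise of σ = 0.2 on the natural-log scale.
    """

    stations: tuple[StationSpec, ...] = field(default_factory=_default_stations)
    depths_m: tuple[float, ...] = (3.0, 70.0, 210.0, 430.0, 850.0, 2000.0, 4000.0)
    genes: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    n_taxa_per_layer: int = 25
    turnover_shared_frac: float = 0.5
    abundance_median_fpm: float = 50.0
    abundance_sigma_ln: float = 1.5
    noise_sigma_ln: float = 0.2
    #: injected δ effects, multiplicative on expected richness.  Keys may be
    #: a station class ("OMZ"), a layer ("mesopelagic") or a
    #: "class:layer" cell, optionally restricted to one guild class with a
    #: "N_uptake@" / "N_redox@" prefix; matching multipliers compound.
    delta_multipliers: dict[str, float] = field(default_factory=dict)
    total_reads: float = 5e7
    np_jitter_sd: float = 0.15
    np_shapes: dict[str, NPShape] = field(default_factory=lambda: dict(NP_SHAPES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.turnover_shared_frac <= 1.0:
            raise ConfigError("turnover_shared_frac must be in [0, 1]")
        if self.noise_sigma_ln < 0 or self.abundance_sigma_ln < 0:
            raise ConfigError("noise/abundance sigmas must be >= 0")
        if any(m <= 0 for m in self.delta_multipliers.values()):
            raise ConfigError("delta multipliers must be > 0")
        ids = [s.station_id for s in self.stations]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate station ids")

    def multiplier(self, station_class: str, layer: str, gene: str | None = None) -> float:
        m = 1.0
        for key, val in self.delta_multipliers.items():
            ctx_key = key
            if "@" in key:
                gclass, ctx_key = key.split("@", 1)
                if gene is None or MARKER_GENES.get(gene) != gclass:
                    continue
            if ctx_key in (station_class, layer, f"{station_class}:{layer}"):
                m *= val
        return m

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kw = {}
        if "stations" in doc:
            kw["stations"] = tuple(StationSpec(**s) for s in doc.pop("stations"))
        if "genes" in doc:
            kw["genes"] = tuple(GeneSpec(**g) for g in doc.pop("genes"))
        if "np_shapes" in doc:
            kw["np_shapes"] = {k: NPShape(**v) for k, v in doc.pop("np_shapes").items()}
        if "depths_m" in doc:
            kw["depths_m"] = tuple(doc.pop("depths_m"))
        kw.update(doc)
        return cls(**kw)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# Richness law
# ---------------------------------------------------------------------------


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, 1.5 -> 2)."""
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def richness_from_abundance(
    A: np.ndarray, c: np.ndarray, gamma: np.ndarray, mult: np.ndarray, eps: np.ndarray
) -> np.ndarray:
    """d_obs = round(c·A^γ · m · ε), floored at one distinct ORF for A > 0."""
    d = round_half_away(c * A**gamma * mult * eps)
    return np.where(A > 0, np.maximum(d, 1.0), 0.0).astype(int)


# ---------------------------------------------------------------------------
# Metadata / N:P profiles
# ---------------------------------------------------------------------------


def simulate_np_profiles(config: SimulationConfig) -> list[SampleMetadata]:
    """Per-sample metadata with N:P structure by station shape.

    The anomalous shapes hit their configured peaks exactly; average
    stations carry small lognormal-free Gaussian jitter so that their
    profiles differ but stay strictly between the two extremes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out: list[SampleMetadata] = []
    for st in config.stations:
        try:
            shape = config.np_shapes[st.np_shape]
        except KeyError:
            raise ConfigError(f"unknown np_shape {st.np_shape!r} for {st.station_id}")
        for depth in config.depths_m:
            np_val = shape.value(depth)
            if st.np_shape == "average" and config.np_jitter_sd > 0:
                np_val = max(np_val + rng.normal(0.0, config.np_jitter_sd), 0.0)
            po4 = 1.0 + 1.3 * (1.0 - math.exp(-depth / 300.0))
            oxy = None
            if st.np_shape == "omz_like":
                oxy = 5.0 if 200 < depth <= 1000 else 180.0
            out.append(
                SampleMetadata(
                    sample_id=f"{st.station_id}_{int(depth)}m",
                    station_id=st.station_id,
                    depth_m=float(depth),
                    nox_um=np_val * po4,
                    po4_um=po4,
                    oxygen=oxy,
                )
            )
    return out


def station_class_map(config: SimulationConfig) -> dict[str, str]:
    return {s.station_id: s.station_class for s in config.stations}


# ---------------------------------------------------------------------------
# Taxa and strata
# ---------------------------------------------------------------------------


def _layer_taxa(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Taxon pool per layer with the configured shared fraction between
    adjacent layers."""
    n = config.n_taxa_per_layer
    n_shared = int(round(config.turnover_shared_frac * n))
    counter = 0

    def fresh(k: int) -> list[str]:
        nonlocal counter
        out = [f"T{counter + i:04d}" for i in range(k)]
        counter += k
        return out

    taxa: dict[str, list[str]] = {}
    prev: list[str] = []
    for layer in LAYERS:
        if not prev:
            taxa[layer] = fresh(n)
        else:
            kept = sorted(rng.choice(prev, size=min(n_shared, len(prev)), replace=False))
            taxa[layer] = list(kept) + fresh(n - len(kept))
        prev = taxa[layer]
    return taxa


def simulate_strata(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth stratum table: one row per (gene, taxon, context).

    Columns: gene, taxon, station_class, layer, A (FPM, globally rescaled
    to sum 10^6), d_obs, multiplier (the injected δ effect), c, gamma.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    taxa = _layer_taxa(config, rng)
    classes = sorted({s.station_class for s in config.stations})
    layers = sorted({assign_layer(d) for d in config.depths_m}, key=LAYERS.index)

    rows = []
    for gene_spec in config.genes:
        for sc in classes:
            for layer in layers:
                for taxon in taxa[layer]:
                    rows.append((gene_spec.gene, gene_spec.c, gene_spec.gamma, sc, layer, taxon))
    df = pd.DataFrame(rows, columns=["gene", "c", "gamma", "station_class", "layer", "taxon"])

    lnA = rng.normal(math.log(config.abundance_median_fpm), config.abundance_sigma_ln, len(df))
    A = np.exp(lnA)
    A *= FPM_TOTAL / A.sum()
    mult = np.array(
        [
            config.multiplier(sc, ly, g)
            for sc, ly, g in zip(df["station_class"], df["layer"], df["gene"])
        ]
    )
    eps = (
        np.exp(rng.normal(0.0, config.noise_sigma_ln, len(df)))
        if config.noise_sigma_ln > 0
        else np.ones(len(df))
    )
    d_obs = richness_from_abundance(
        A, df["c"].to_numpy(), df["gamma"].to_numpy(), mult, eps
    )
    out = df[["gene", "taxon", "station_class", "layer"]].copy()
    out["A"] = A
    out["d_obs"] = d_obs
    out["multiplier"] = mult
    out["c"] = df["c"]
    out["gamma"] = df["gamma"]
    return out


def simulate_power_law_strata(
    n: int,
    c: float,
    gamma: float,
    noise_sigma: float = 0.0,
    abundance_median_fpm: float = 100.0,
    abundance_sigma_ln: float = 1.0,
    seed: int = 0,
    gene: str = "gene",
) -> pd.DataFrame:
    """Minimal stratum table on a single power law, for fit validation.

    Abundances are lognormal (not rescaled); d_obs = round(c·A^γ·ε) with
    lognormal unit-median noise ε, floored at 1.
    """
    rng = np.random.default_rng(seed)
    A = np.exp(rng.normal(math.log(abundance_median_fpm), abundance_sigma_ln, n))
    eps = np.exp(rng.normal(0.0, noise_sigma, n)) if noise_sigma > 0 else np.ones(n)
    d_obs = richness_from_abundance(A, np.full(n, c), np.full(n, gamma), np.ones(n), eps)
    return pd.DataFrame(
        {
            "gene": gene,
            "taxon": [f"T{i:04d}" for i in range(n)],
            "station_class": "average_ocean",
            "layer": "epipelagic",
            "A": A,
            "d_obs": d_obs,
        }
    )


def exact_power_law_strata(
    c: float, gamma: float, d_values, gene: str = "gene"
) -> pd.DataFrame:
    """Strata lying *exactly* on d = c·A^γ (no rounding, no noise).

    Built by inverting the law at integer richness values:
    A = (d/c)^(1/γ).  Useful for analytic identities (fits recover (c, γ)
    to machine precision and every δ is exactly 1).
    """
    d = np.asarray(list(d_values), dtype=float)
    if np.any(d < 1):
        raise ConfigError("d_values must be >= 1")
    A = (d / c) ** (1.0 / gamma)
    return pd.DataFrame(
        {
            "gene": gene,
            "taxon": [f"T{i:04d}" for i in range(d.size)],
            "station_class": "average_ocean",
            "layer": "epipelagic",
            "A": A,
            "d_obs": d,
        }
    )


# ---------------------------------------------------------------------------
# Full feature-table simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[FeatureRecord], list[SampleMetadata], pd.DataFrame]:
    """Emit (feature records, metadata, truth table).

    Each stratum of :func:`simulate_strata` is expanded into ``d_obs``
    distinct ORF rows whose raw counts sum to the stratum's reads
    (Dirichlet-split), each assigned to one sample of the stratum's
    context.  Global FPM renormalization of the emitted table reproduces
    each stratum's A exactly, because the strata already sum to 10^6 FPM.
    """
    metadata = simulate_np_profiles(config)
    strata = simulate_strata(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    by_context: dict[tuple[str, str], list[str]] = {}
    classes = station_class_map(config)
    for m in metadata:
        by_context.setdefault((classes[m.station_id], m.layer), []).append(m.sample_id)

    reads_per_fpm = config.total_reads / FPM_TOTAL
    records: list[FeatureRecord] = []
    for idx, row in enumerate(strata.itertuples(index=False)):
        d = int(row.d_obs)
        if d == 0:
            continue
        weights = rng.dirichlet(np.ones(d)) if d > 1 else np.ones(1)
        samples = by_context[(row.station_class, row.layer)]
        picks = rng.integers(0, len(samples), size=d)
        for j in range(d):
            records.append(
                FeatureRecord(
                    orf_id=f"{row.gene}|{row.taxon}|{row.station_class}|{row.layer}|{j:04d}",
                    gene=row.gene,
                    taxon=row.taxon,
                    sample_id=samples[picks[j]],
                    raw_count=float(row.A * weights[j] * reads_per_fpm),
                )
            )
    return records, metadata, strata


# ---------------------------------------------------------------------------
# Placement simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeSpec:
    name: str
    label: str  # functional | non_functional
    n_leaves: int = 4
    n_queries: int = 0


@dataclass
class PlacementSimConfig:
    gene: str
    clades: tuple[CladeSpec, ...]
    query_weight: float = 1.0  # like_weight_ratio on the true clade
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ConfigError("need >= 2 labelled clades")
        if not any(c.label == "non_functional" for c in self.clades):
            raise ConfigError("need >= 1 non_functional clade")
        if not 0.0 < self.query_weight <= 1.0:
            raise ConfigError("query_weight must be in (0, 1]")


def simulate_placements(
    config: PlacementSimConfig,
) -> tuple[ReferenceTree, PlacementSet, pd.DataFrame]:
    """Labelled reference tree plus queries drawn from known clades.

    Each query is placed on a leaf of its true clade with the configured
    like_weight_ratio; any remaining weight goes to a random other clade.
    Returns (tree, placements, truth) where truth has one row per query:
    query_id, clade, label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    clade_strs = []
    for clade in config.clades:
        leaves = ",".join(
            f"{clade.name}_ref{i}:1.0" for i in range(max(clade.n_leaves, 1))
        )
        clade_strs.append(f"({leaves}){clade.name}:1.0")
    newick = "(" + ",".join(clade_strs) + ")root;"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True
    )
    ref = ReferenceTree(
        gene=config.gene,
        tree=tree,
        clade_labels={c.name: c.label for c in config.clades},
    )
    ps = PlacementSet(gene=config.gene)
    truth_rows = []
    qidx = 0
    names = [c.name for c in config.clades]
    for clade in config.clades:
        for _ in range(clade.n_queries):
            qid = f"{config.gene}_q{qidx:04d}"
            qidx += 1
            leaf = f"{clade.name}_ref{rng.integers(0, max(clade.n_leaves, 1))}"
            ps.placements.append(Placement(qid, leaf, config.query_weight))
            if config.query_weight < 1.0:
                others = [n for n in names if n != clade.name]
                alt = others[rng.integers(0, len(others))]
                ps.placements.append(
                    Placement(qid, f"{alt}_ref0", 1.0 - config.query_weight)
                )
            truth_rows.append((qid, clade.name, clade.label))
    truth = pd.DataFrame(truth_rows, columns=["query_id", "clade", "label"])
    return ref, ps, truth
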