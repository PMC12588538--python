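"""Shared domain types for gene-centric guild quantification.

The analysis operates on annotated ORF observations (one row per predicted
open reading frame per sample), sample metadata for an oceanographic cruise,
and aggregated *strata*: the (gene, taxon, context) cells on which abundance
``A`` (in features per million, FPM) and observed sequence richness
``d_obs`` are measured.  A context is the cross of a station class (an
oxygen-minimum-zone station, anomalous North/South Atlantic stations, or the
pooled "average ocean") with a depth layer (epipelagic, mesopelagic,
bathypelagic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import RangeError

# ---------------------------------------------------------------------------
# Marker-gene registry
# ---------------------------------------------------------------------------

#: The 18 nitrogen-cycle marker genes and their guild class.  Redox markers
#: cover nitrification, denitrification, dissimilatory nitrate reduction,
#: urea hydrolysis and anammox; uptake markers are substrate-binding
#: transporter subunits for inorganic and organic nitrogen sources, plus the
#: branched-chain amino-acid biosynthesis marker ilvC which the two-way
#: uptake/redox display groups with acquisition.
MARKER_GENES: dict[str, str] = {
    # N redox transformations
    "amoA": "N_redox",
    "nifH": "N_redox",
    "nirK": "N_redox",
    "ureC": "N_redox",
    "uca": "N_redox",
    "nxrA": "N_redox",
    "nirS": "N_redox",
    "nasA": "N_redox",
    "narG": "N_redox",
    "nosZ": "N_redox",
    "hzsA": "N_redox",
    # N acquisition (transport substrate-binding proteins + ilvC)
    "amt": "N_uptake",
    "nrtA": "N_uptake",
    "tauA": "N_uptake",
    "potF": "N_uptake",
    "livJ": "N_uptake",
    "bztA": "N_uptake",
    "ilvC": "N_uptake",
}

GUILD_CLASSES = ("N_uptake", "N_redox")

#: Depth layers, shallow to deep.
LAYERS = ("epipelagic", "mesopelagic", "bathypelagic")

#: Station classes; "average_ocean" pools every station that is not one of
#: the three named anomalous water columns.
STATION_CLASSES = ("OMZ", "NAtl", "SAtl", "average_ocean")

MAX_DEPTH_M = 4000.0


def guild_class_of(gene: str) -> str:
    """Guild class (N_uptake / N_redox) for a marker gene; unknown genes
    default to N_uptake only if explicitly registered — otherwise raise."""
    try:
        return MARKER_GENES[gene]
    except KeyError:
        raise KeyError(f"gene {gene!r} is not a registered marker gene")


def assign_layer(depth_m: float) -> str:
    """Map a depth in metres to its pelagic layer.

    Boundaries follow the conventional 0–200 / 200–1000 / 1000–4000 m
    stratification.  The upper bound of each layer is inclusive:
    [0, 200] epipelagic, (200, 1000] mesopelagic, (1000, 4000] bathypelagic.
    """
    if not math.isfinite(depth_m) or depth_m < 0 or depth_m > MAX_DEPTH_M:
        raise RangeError(f"depth {depth_m!r} m outside [0, {MAX_DEPTH_M:g}]")
    if depth_m <= 200:
        return "epipelagic"
    if depth_m <= 1000:
        return "mesopelagic"
    return "bathypelagic"


# ---------------------------------------------------------------------------
# Record-level types
# ---------------------------------------------------------------------------


@dataclass
class FeatureRecord:
    """One annotated ORF observation in one sample.

    ``raw_count`` is the (possibly coverage-weighted, hence fractional)
    number of reads mapped to the ORF; ``fpm`` is absent until global
    normalization.
    """

    orf_id: str
    gene: str
    taxon: str
    sample_id: str
    raw_count: float
    fpm: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.raw_count < 0:
            raise ValueError(f"raw_count {self.raw_count} < 0 for {self.orf_id}")


@dataclass
class SampleMetadata:
    """Per-sample station/depth/chemistry metadata; ``layer`` is derived."""

    sample_id: str
    station_id: str
    depth_m: float
    nox_um: float
    po4_um: float
    oxygen: Optional[float] = None
    layer: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        derived = assign_layer(self.depth_m)
        if self.layer and self.layer != derived:
            raise ValueError(
                f"layer {self.layer!r} inconsistent with depth {self.depth_m} m"
            )
        self.layer = derived
        if self.nox_um < 0 or self.po4_um < 0:
            raise ValueError(f"negative nutrient concentration in {self.sample_id}")


@dataclass(frozen=True)
class Context:
    """One analysis cell: station class × depth layer."""

    station_class: str
    layer: str

    def __post_init__(self) -> None:
        if self.station_class not in STATION_CLASSES:
            raise ValueError(f"unknown station class {self.station_class!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def key(self) -> str:
        return f"{self.station_class}:{self.layer}"


def all_contexts() -> list[Context]:
    """Enumerate the full cross of station classes × layers."""
    return [Context(s, l) for s in STATION_CLASSES for l in LAYERS]


# ---------------------------------------------------------------------------
# Aggregated / fitted types
# ---------------------------------------------------------------------------


@dataclass
class Stratum:
    """The (gene, taxon, context) aggregation unit carrying A and d_obs."""

    gene: str
    taxon: str
    station_class: str
    layer: str
    A: float
    d_obs: int

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("abundance A must be >= 0")
        if self.A > 0 and self.d_obs < 1:
            raise ValueError("d_obs must be >= 1 when A > 0")


@dataclass
class GuildScore:
    """Per-stratum guild score: δ = d_obs/d_exp and k = δ·A.

    ``log_delta`` and ``log_k`` are natural logarithms.
    """

    gene: str
    taxon: str
    station_class: str
    layer: str
    A: float
    d_obs: float
    d_exp: float
    delta: float
    k: float
    log_delta: float
    log_k: float

    @property
    def guild_class(self) -> str:
        return guild_class_of(self.gene)


@dataclass
class DiversityFit:
    """Per-gene power-law fit d_exp = c · A^gamma (least squares in log–log)."""

    gene: str
    c: float
    gamma: float
    n_points: int
    r_squared: float
    resid_sd: float
    se_log_c: float
    se_gamma: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")

    def expected_richness(self, A) -> float:
        """d_exp = c · A^gamma."""
        return self.c * A**self.gamma


# ---------------------------------------------------------------------------
# Frame converters — pandas is the working container for bulk operations
# ---------------------------------------------------------------------------

STRATUM_COLUMNS = ["gene", "taxon", "station_class", "layer", "A", "d_obs"]
SCORE_COLUMNS = [
    "gene",
    "taxon",
    "station_class",
    "layer",
    "A",
    "d_obs",
    "d_exp",
    "delta",
    "k",
    "log_delta",
    "log_k",
]


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    cols = {
        "orf_id": [r.orf_id for r in records],
        "gene": [r.gene for r in records],
        "taxon": [r.taxon for r in records],
        "sample_id": [r.sample_id for r in records],
        "raw_count": [r.raw_count for r in records],
    }
    if any(r.fpm is not None for r in records):
        cols["fpm"] = [r.fpm for r in records]
    return pd.DataFrame(cols)


def strata_to_frame(strata: list[Stratum]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene, s.taxon, s.station_class, s.layer, s.A, s.d_obs) for s in strata],
        columns=STRATUM_COLUMNS,
    )


def frame_to_strata(df: pd.DataFrame) -> list[Stratum]:
    return [
        Stratum(r.gene, r.taxon, r.station_class, r.layer, float(r.A), int(r.d_obs))
        for r in df.itertuples(index=False)
    ]


def scores_to_frame(scores: list[GuildScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.gene,
                s.taxon,
                s.station_class,
                s.layer,
                s.A,
                s.d_obs,
                s.d_exp,
                s.delta,
                s.k,
                s.log_delta,
                s.log_k,
            )
            for s in scores
        ],
        columns=SCORE_COLUMNS,
    )


def frame_to_scores(df: pd.DataFrame) -> list[GuildScore]:
    return [
        GuildScore(
            r.gene,
            r.taxon,
            r.station_class,
            r.layer,
            float(r.A),
            float(r.d_obs),
            float(r.d_exp),
            float(r.delta),
            float(r.k),
            float(r.log_delta),
            float(r.log_k),
        )
        for r in df.itertuples(index=False)
    ]
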