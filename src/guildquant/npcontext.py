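"""N:P stoichiometric context of the sampled water columns.

The N:P ratio (NOx:PO4, mol:mol) is a rough index of nitrogen limitation:
the Redfield ratio 16:1 is considered neither N- nor P-limiting, lower
values indicate N scarcity.  Vertical profiles of N:P typically rise from
N-depleted surface waters to a mesopelagic maximum and converge near
Redfield at depth.  This module computes per-station profiles, locates the
mesopelagic maximum, and flags stations whose deep values sit strictly
outside the envelope of the rest of the cruise — the selection logic that
singles out an oxygen-minimum-zone column (persistently low N:P) and a
high-N:P open-ocean column.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import SampleMetadata
from .errors import DegenerateInputError, InsufficientDataError

MESOPELAGIC_FLOOR_M = 1000.0


def np_ratio(nox_um: float, po4_um: float) -> float:
    """NOx:PO4 molar ratio; undefined (error) when PO4 is zero."""
    if po4_um <= 0:
        raise DegenerateInputError("N:P undefined for PO4 <= 0")
    if nox_um < 0:
        raise ValueError("NOx concentration must be >= 0")
    return nox_um / po4_um


@dataclass
class NPProfile:
    """Ordered vertical N:P profile of one station."""

    station_id: str
    depths_m: list[float]
    np_ratios: list[float]

    def __post_init__(self) -> None:
        if len(self.depths_m) != len(self.np_ratios):
            raise ValueError("depths and ratios differ in length")
        if any(b <= a for a, b in zip(self.depths_m, self.depths_m[1:])):
            raise ValueError(f"depths of {self.station_id} not strictly increasing")
        if any(r < 0 for r in self.np_ratios):
            raise ValueError("np_ratio must be >= 0")

    @property
    def meso_max(self) -> tuple[float, float]:
        return mesopelagic_maximum(self)


@dataclass
class StationFlag:
    station_id: str
    flag: str  # low_np_anomaly | high_np_anomaly | typical
    evidence_depths_m: list[float]


def profiles_from_metadata(metadata: list[SampleMetadata]) -> list[NPProfile]:
    """One profile per station, ordered by depth."""
    by_station: dict[str, list[SampleMetadata]] = {}
    for m in metadata:
        by_station.setdefault(m.station_id, []).append(m)
    profiles = []
    for sid in sorted(by_station):
        rows = sorted(by_station[sid], key=lambda m: m.depth_m)
        profiles.append(
            NPProfile(
                station_id=sid,
                depths_m=[m.depth_m for m in rows],
                np_ratios=[np_ratio(m.nox_um, m.po4_um) for m in rows],
            )
        )
    return profiles


def mesopelagic_maximum(profile: NPProfile) -> tuple[float, float]:
    """(depth, value) of the N:P maximum over depths <= 1000 m.

    Ties break toward the shallower depth.
    """
    pts = [
        (d, r)
        for d, r in zip(profile.depths_m, profile.np_ratios)
        if d <= MESOPELAGIC_FLOOR_M
    ]
    if not pts:
        raise InsufficientDataError(
            f"{profile.station_id}: no points at or above {MESOPELAGIC_FLOOR_M:g} m"
        )
    best = max(pts, key=lambda p: (p[1], -p[0]))
    return best


def _value_at(profile: NPProfile, depth: float, tol_m: float) -> float | None:
    """Profile value at the nearest sampled depth within ±tol_m, else None."""
    best = None
    for d, r in zip(profile.depths_m, profile.np_ratios):
        gap = abs(d - depth)
        if gap <= tol_m and (best is None or gap < best[0]):
            best = (gap, r)
    return None if best is None else best[1]


def flag_stations(
    profiles: list[NPProfile],
    deep_threshold_m: float = 600.0,
    match_tol_m: float = 50.0,
) -> list[StationFlag]:
    """Flag stations strictly outside the deep N:P envelope of the rest.

    A station is a low_np_anomaly if at *every* of its sampled depths below
    ``deep_threshold_m`` its ratio is strictly below the minimum of all
    other stations at comparable depths (nearest sampled depth within
    ±``match_tol_m``); high_np_anomaly is symmetric against the maximum.
    Order of the input profiles does not affect the outcome.
    """
    if len(profiles) < 3:
        raise InsufficientDataError("flagging needs >= 3 stations")
    flags = []
    for prof in sorted(profiles, key=lambda p: p.station_id):
        others = [p for p in profiles if p.station_id != prof.station_id]
        deep = [
            (d, r) for d, r in zip(prof.depths_m, prof.np_ratios) if d > deep_threshold_m
        ]
        evidence_low, evidence_high = [], []
        all_low = all_high = bool(deep)
        for d, r in deep:
            comps = [v for p in others if (v := _value_at(p, d, match_tol_m)) is not None]
            if not comps:
                continue
            if r < min(comps):
                evidence_low.append(d)
            else:
                all_low = False
            if r > max(comps):
                evidence_high.append(d)
            else:
                all_high = False
        if all_low and evidence_low:
            flags.append(StationFlag(prof.station_id, "low_np_anomaly", evidence_low))
        elif all_high and evidence_high:
            flags.append(StationFlag(prof.station_id, "high_np_anomaly", evidence_high))
        else:
            flags.append(StationFlag(prof.station_id, "typical", []))
    return flags
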