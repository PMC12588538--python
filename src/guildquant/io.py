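"""Readers and writers for the package's delimited tables, reference trees
and placement files.

Tables are tab-separated with a header by default (``dialect="csv"`` for
comma-separated).  Reference trees are newick with labelled internal nodes;
placements are a documented jplace-style JSON subset in which each placement
references a node or clade name of the companion tree.  Numeric result
columns round-trip at full double precision (written with ``repr``-faithful
``%.17g`` formatting).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .datatypes import (
    FeatureRecord,
    GuildScore,
    SampleMetadata,
    Stratum,
    frame_to_scores,
    frame_to_strata,
    scores_to_frame,
    strata_to_frame,
)
from .errors import FormatError, ReferenceLookupError, ValidationError

_SEP = {"tsv": "\t", "csv": ","}

FLOAT_FMT = "%.17g"


def _sep(dialect: str) -> str:
    try:
        return _SEP[dialect]
    except KeyError:
        raise FormatError(f"unknown table dialect {dialect!r}; use 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# Feature tables and metadata
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["orf_id", "gene", "taxon", "sample_id", "raw_count"]
_METADATA_COLUMNS = ["sample_id", "station_id", "depth_m", "nox_um", "po4_um"]


def read_feature_table(path, dialect: str = "tsv") -> list[FeatureRecord]:
    """Parse a per-ORF annotated feature table.

    Mandatory columns: orf_id, gene, taxon, sample_id, raw_count.  Unknown
    columns are preserved on each record's ``extra`` dict.  Row order is
    stable.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} missing column(s): {', '.join(missing)}")
    extras = [c for c in df.columns if c not in _FEATURE_COLUMNS]
    records: list[FeatureRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        try:
            count = float(d["raw_count"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path} line {i}: raw_count {d['raw_count']!r} is not numeric")
        if count < 0:
            raise ValidationError(f"{path} line {i}: negative raw_count {count}")
        fpm = d.get("fpm")
        key = (d["orf_id"], d["sample_id"])
        if key in seen:
            raise ValidationError(f"{path} line {i}: duplicate (orf_id, sample_id) {key}")
        seen.add(key)
        records.append(
            FeatureRecord(
                orf_id=d["orf_id"],
                gene=d["gene"],
                taxon=d["taxon"],
                sample_id=d["sample_id"],
                raw_count=count,
                fpm=float(fpm) if fpm is not None and fpm == fpm else None,
                extra={k: d[k] for k in extras if k != "fpm"},
            )
        )
    return records


def write_feature_table(records: list[FeatureRecord], path, dialect: str = "tsv") -> None:
    if not records:
        raise ValidationError("refusing to write an empty feature table")
    df = pd.DataFrame(
        {
            "orf_id": [r.orf_id for r in records],
            "gene": [r.gene for r in records],
            "taxon": [r.taxon for r in records],
            "sample_id": [r.sample_id for r in records],
            "raw_count": [r.raw_count for r in records],
        }
    )
    if any(r.fpm is not None for r in records):
        df["fpm"] = [r.fpm for r in records]
    for key in records[0].extra:
        df[key] = [r.extra.get(key) for r in records]
    df.to_csv(path, sep=_sep(dialect), index=False, float_format=FLOAT_FMT)


def read_metadata(path, dialect: str = "tsv") -> list[SampleMetadata]:
    """Parse sample metadata (station, depth, NOx, PO4, optional oxygen)."""
    df = pd.read_csv(path, sep=_sep(dialect))
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} missing column(s): {', '.join(missing)}")
    extras = [c for c in df.columns if c not in _METADATA_COLUMNS + ["oxygen", "layer"]]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        oxy = d.get("oxygen")
        out.append(
            SampleMetadata(
                sample_id=str(d["sample_id"]),
                station_id=str(d["station_id"]),
                depth_m=float(d["depth_m"]),
                nox_um=float(d["nox_um"]),
                po4_um=float(d["po4_um"]),
                oxygen=float(oxy) if oxy is not None and oxy == oxy else None,
                extra={k: d[k] for k in extras},
            )
        )
    return out


def write_metadata(metadata: list[SampleMetadata], path, dialect: str = "tsv") -> None:
    if not metadata:
        raise ValidationError("refusing to write empty metadata")
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "station_id": [m.station_id for m in metadata],
            "depth_m": [m.depth_m for m in metadata],
            "nox_um": [m.nox_um for m in metadata],
            "po4_um": [m.po4_um for m in metadata],
            "oxygen": [m.oxygen for m in metadata],
            "layer": [m.layer for m in metadata],
        }
    )
    df.to_csv(path, sep=_sep(dialect), index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Strata / score / result tables
# ---------------------------------------------------------------------------


def _write_numeric_table(df: pd.DataFrame, path, dialect: str) -> None:
    df.to_csv(path, sep=_sep(dialect), index=False, float_format=FLOAT_FMT)


def write_strata(strata: list[Stratum], path, dialect: str = "tsv") -> None:
    if not strata:
        raise ValidationError("refusing to write an empty stratum table")
    _write_numeric_table(strata_to_frame(strata), path, dialect)


def read_strata(path, dialect: str = "tsv") -> list[Stratum]:
    return frame_to_strata(pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip"))


def write_scores(scores: list[GuildScore], path, dialect: str = "tsv") -> None:
    """Export guild scores; refuses non-finite δ, naming the stratum."""
    if not scores:
        raise ValidationError("refusing to write an empty score table")
    for s in scores:
        if not (math.isfinite(s.delta) and math.isfinite(s.k)):
            raise ValidationError(
                f"non-finite score in stratum ({s.gene}, {s.taxon}, "
                f"{s.station_class}:{s.layer})"
            )
    _write_numeric_table(scores_to_frame(scores), path, dialect)


def read_scores(path, dialect: str = "tsv") -> list[GuildScore]:
    return frame_to_scores(pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip"))


def write_table(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Generic full-precision table export for densities/contrasts/exports."""
    if df is None or len(df) == 0:
        raise ValidationError("refusing to write an empty table")
    _write_numeric_table(df, path, dialect)


def read_table(path, dialect: str = "tsv") -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")


# ---------------------------------------------------------------------------
# Reference trees and placements
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTree:
    """A rooted, leaf-named reference tree whose labelled internal clades
    carry a functional / non_functional annotation."""

    gene: str
    tree: dendropy.Tree
    clade_labels: dict[str, str]  # clade name -> {"functional", "non_functional"}

    def __post_init__(self) -> None:
        for name, label in self.clade_labels.items():
            if label not in ("functional", "non_functional"):
                raise ValidationError(f"clade {name!r}: unknown label {label!r}")
        self._nodes = {}
        for node in self.tree.preorder_node_iter():
            name = node.taxon.label if node.taxon is not None else node.label
            if name:
                self._nodes[name] = node
        for name in self.clade_labels:
            if name not in self._nodes:
                raise ReferenceLookupError(f"labelled clade {name!r} not in tree for {self.gene}")
        # every leaf must sit under at least one labelled clade
        uncovered = [
            lf.taxon.label
            for lf in self.tree.leaf_node_iter()
            if not any(self._is_labelled(a) for a in self._ancestry(lf))
        ]
        if uncovered:
            raise ValidationError(
                f"{self.gene} tree: leaves not covered by any labelled clade: {uncovered[:5]}"
            )

    def _is_labelled(self, node) -> bool:
        name = node.taxon.label if node.taxon is not None else node.label
        return bool(name) and name in self.clade_labels

    @staticmethod
    def _ancestry(node):
        while node is not None:
            yield node
            node = node.parent_node

    def resolve(self, ref: str):
        """Node named ``ref`` (leaf taxon or internal clade label)."""
        try:
            return self._nodes[ref]
        except KeyError:
            raise ReferenceLookupError(f"edge/clade {ref!r} not found in {self.gene} tree")

    def smallest_labelled_clade(self, ref: str) -> str:
        """Name of the smallest labelled clade containing the edge above
        the node ``ref`` resolves to."""
        for anc in self._ancestry(self.resolve(ref)):
            name = anc.taxon.label if anc.taxon is not None else anc.label
            if name and name in self.clade_labels:
                return name
        raise ReferenceLookupError(f"no labelled clade contains {ref!r} in {self.gene} tree")


@dataclass
class Placement:
    """One query placed on the reference tree: (edge/clade ref, weight)."""

    query_id: str
    edge_ref: str
    like_weight_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.like_weight_ratio <= 1.0:
            raise ValidationError(
                f"like_weight_ratio {self.like_weight_ratio} outside [0,1] for {self.query_id}"
            )


@dataclass
class PlacementSet:
    gene: str
    placements: list[Placement] = field(default_factory=list)

    def by_query(self) -> dict[str, list[Placement]]:
        out: dict[str, list[Placement]] = {}
        for p in self.placements:
            out.setdefault(p.query_id, []).append(p)
        return out


def read_reference_tree(path, gene: str, labels: dict[str, str]) -> ReferenceTree:
    """Load a newick tree and attach clade labels (name -> verdict class)."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True
    )
    return ReferenceTree(gene=gene, tree=tree, clade_labels=labels)


def read_placements(path) -> PlacementSet:
    """Read a jplace-style JSON file.

    Expected shape::

        {"gene": "hzsA",
         "placements": [{"name": "q1", "p": [["hzsA-I", 0.93], ...]}, ...]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "gene" not in doc or "placements" not in doc:
        raise FormatError(f"{path}: placement file needs 'gene' and 'placements' keys")
    ps = PlacementSet(gene=doc["gene"])
    for entry in doc["placements"]:
        name = entry.get("name") or (entry.get("nm") or [None])[0]
        if name is None:
            raise FormatError(f"{path}: placement entry without a query name")
        for p in entry["p"]:
            ps.placements.append(Placement(str(name), str(p[0]), float(p[1])))
    return ps


def write_placements(ps: PlacementSet, path) -> None:
    by_query = ps.by_query()
    doc = {
        "gene": ps.gene,
        "placements": [
            {"name": q, "p": [[p.edge_ref, p.like_weight_ratio] for p in plist]}
            for q, plist in by_query.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def validate_feature_table(path, dialect: str = "tsv") -> int:
    """Parse-validate a feature table; returns the number of rows."""
    return len(read_feature_table(path, dialect))
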