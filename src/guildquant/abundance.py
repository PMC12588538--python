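"""Global FPM normalization and aggregation of ORF records into strata.

FPM (features per million) is a whole-dataset normalization: every raw count
is divided by the grand total across *all* samples and multiplied by 10^6,
so that the sum of all functional features across the dataset is exactly one
million FPM.  Aggregation then collapses records to (gene, taxon, context)
strata, where a context is station class × depth layer; a stratum's
abundance ``A`` is the sum of its members' FPM and its observed richness
``d_obs`` the number of distinct ORF ids it contains.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import (
    FeatureRecord,
    GuildScore,
    SampleMetadata,
    Stratum,
    records_to_frame,
)
from .errors import DegenerateInputError, ReferenceLookupError

FPM_TOTAL = 1_000_000.0


def normalize_fpm(records: list[FeatureRecord]) -> list[FeatureRecord]:
    """Attach globally normalized FPM to every record.

    fpm_i = raw_count_i / Σ raw_count × 10^6, with the sum taken over the
    whole dataset (all samples), so Σ fpm = 10^6.
    """
    total = sum(r.raw_count for r in records)
    if total <= 0:
        raise DegenerateInputError("cannot normalize a table whose counts sum to zero")
    return [
        FeatureRecord(
            orf_id=r.orf_id,
            gene=r.gene,
            taxon=r.taxon,
            sample_id=r.sample_id,
            raw_count=r.raw_count,
            fpm=r.raw_count / total * FPM_TOTAL,
            extra=dict(r.extra),
        )
        for r in records
    ]


def aggregate_strata(
    records: list[FeatureRecord],
    metadata: list[SampleMetadata],
    station_classes: dict[str, str],
) -> list[Stratum]:
    """Collapse normalized records into (gene, taxon, station_class, layer)
    strata.

    ``station_classes`` maps station_id -> station class; stations absent
    from the map fall into "average_ocean".  Strata with zero abundance are
    omitted.  Records must be normalized first (fpm present).
    """
    meta = {m.sample_id: m for m in metadata}
    df = records_to_frame(records)
    if "fpm" not in df.columns:
        raise DegenerateInputError("records carry no fpm; run normalize_fpm first")
    orphans = set(df["sample_id"]) - set(meta)
    if orphans:
        raise ReferenceLookupError(
            f"sample_id(s) without metadata: {sorted(orphans)[:5]}"
        )
    df = df.assign(
        station_class=[
            station_classes.get(meta[s].station_id, "average_ocean")
            for s in df["sample_id"]
        ],
        layer=[meta[s].layer for s in df["sample_id"]],
    )
    grouped = (
        df.groupby(["gene", "taxon", "station_class", "layer"], sort=True)
        .agg(A=("fpm", "sum"), d_obs=("orf_id", "nunique"))
        .reset_index()
    )
    grouped = grouped[grouped["A"] > 0]
    return [
        Stratum(r.gene, r.taxon, r.station_class, r.layer, float(r.A), int(r.d_obs))
        for r in grouped.itertuples(index=False)
    ]


def top_taxa(scores: list[GuildScore], n: int) -> list[GuildScore]:
    """Pool minor taxa into a single "Others" entry per gene.

    Taxa are ranked by their summed k across the given score set (one
    display cell); ranks beyond ``n`` are pooled, per gene, into an "Others"
    score whose k (and A) are the sums of its members.  Ties in summed k
    break lexicographically by taxon name.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals: dict[str, float] = {}
    for s in scores:
        totals[s.taxon] = totals.get(s.taxon, 0.0) + s.k
    ranked = sorted(totals, key=lambda t: (-totals[t], t))
    keep = set(ranked[:n])
    kept = [s for s in scores if s.taxon in keep]
    pooled: dict[tuple[str, str, str], list[GuildScore]] = {}
    for s in scores:
        if s.taxon not in keep:
            pooled.setdefault((s.gene, s.station_class, s.layer), []).append(s)
    import math

    for (gene, sc, layer), members in sorted(pooled.items()):
        A = sum(m.A for m in members)
        k = sum(m.k for m in members)
        d_obs = sum(m.d_obs for m in members)
        d_exp = sum(m.d_exp for m in members)
        delta = k / A if A > 0 else float("nan")
        kept.append(
            GuildScore(
                gene=gene,
                taxon="Others",
                station_class=sc,
                layer=layer,
                A=A,
                d_obs=d_obs,
                d_exp=d_exp,
                delta=delta,
                k=k,
                log_delta=math.log(delta) if delta > 0 else float("nan"),
                log_k=math.log(k) if k > 0 else float("nan"),
            )
        )
    return kept


def strata_total_abundance(strata: list[Stratum]) -> float:
    return float(sum(s.A for s in strata))


def renormalize(records: list[FeatureRecord]) -> list[FeatureRecord]:
    """Re-run global normalization (e.g. after paralog filtering), restoring
    the 10^6 FPM invariant over the surviving records."""
    return normalize_fpm(records)
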