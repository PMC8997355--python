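"""Span/flank region extraction and summary-statistic feature engineering.

Each SV is turned into a fixed-length named feature vector.  Deletions and
duplications are summarised over their full span; insertions over a 1-bp site
window at the integration point.  In addition, fixed-width flanks immediately
up- and downstream of the breakpoints (default 100 bp) are summarised to
capture the genomic context left intact by the event.

Track statistics
----------------
max
    maximum overlapping track value (0 when nothing overlaps).
mean
    length-weighted mean over the region, uncovered bases counting as zero,
    so that sparse functional coverage is penalised and mean <= max on
    nonnegative tracks.
sum
    sum of value x covered bases.
count_above_p90
    number of covered bases at or above the track's genome-wide per-base
    90th-percentile value ("high-impact" bases).

Catalog statistics
------------------
overlap_count
    number of catalog elements overlapping the region.
nearest_distance
    gap in bases from the SV *span* edges to the closest element.  Distance
    features are measured once from the span and fed to both the span and the
    flank model.

The two flanks are pooled into one value per statistic (max of maxes, pooled
mean over the combined flank length, summed sums and counts).  Any value that
is undefined — empty overlap, missing chromosome — is imputed with zero
before normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    NO_ELEMENT_DISTANCE,
    AnnotationTrack,
    DataError,
    ElementCatalog,
    GenomicInterval,
    SVRecord,
)

TRACK_STATISTICS = ("max", "mean", "sum", "count_above_p90")
CATALOG_STATISTICS = ("overlap_count", "nearest_distance")
STATISTICS = TRACK_STATISTICS + CATALOG_STATISTICS

DEFAULT_FLANK_SIZE = 100


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a source (track or catalog), a region kind, a statistic."""

    name: str
    source: str
    region_kind: str  # "span" | "flank"
    statistic: str

    def __post_init__(self) -> None:
        if self.region_kind not in ("span", "flank"):
            raise DataError(f"bad region kind {self.region_kind!r} for {self.name!r}")
        if self.statistic not in STATISTICS:
            raise DataError(f"unknown statistic {self.statistic!r} for {self.name!r}")


@dataclass
class FeatureCatalog:
    """An ordered list of feature definitions plus the flank width."""

    entries: list[FeatureSpec]
    flank_size: int = DEFAULT_FLANK_SIZE

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DataError(f"duplicate feature names: {sorted(dupes)}")
        if self.flank_size <= 0:
            raise DataError("flank_size must be positive")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "flank_size": self.flank_size,
            "features": [
                {
                    "name": e.name,
                    "source": e.source,
                    "region": e.region_kind,
                    "statistic": e.statistic,
                }
                for e in self.entries
            ],
        }
        with open(Path(path), "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureCatalog":
        with open(Path(path)) as fh:
            payload = yaml.safe_load(fh)
        entries = [
            FeatureSpec(d["name"], d["source"], d["region"], d["statistic"])
            for d in payload["features"]
        ]
        return cls(entries, flank_size=int(payload.get("flank_size", DEFAULT_FLANK_SIZE)))


@dataclass
class FeatureMatrix:
    """SVs x named features, dense, with a provenance tag per feature.

    Tags are ``span``, ``flank`` or ``distance`` (distance features are
    region-independent, measured from the span edges).
    """

    df: pd.DataFrame
    region_tags: dict[str, str] = field(default_factory=dict)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.df.loc[list(ids)], dict(self.region_tags))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(Path(path), sep="\t", index_label="sv_id")

    @classmethod
    def from_tsv(cls, path: str | Path, region_tags: dict[str, str] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col="sv_id")
        df.index = df.index.astype(str)
        return cls(df, region_tags or {})


def extract_regions(
    sv: SVRecord,
    flank_size: int = DEFAULT_FLANK_SIZE,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[GenomicInterval, tuple[GenomicInterval, GenomicInterval]]:
    """Span and (upstream, downstream) flank regions for one SV.

    Flanks are clipped at chromosome bounds; clipping never fails, an SV at a
    chromosome edge simply gets a shorter (possibly empty) flank.
    """
    if flank_size <= 0:
        raise DataError("flank_size must be positive")
    chrom = sv.interval.chrom
    if sv.sv_type == "INS":
        span = GenomicInterval(chrom, sv.interval.start, sv.interval.start + 1)
    else:
        span = sv.interval
    size = None if chrom_sizes is None else chrom_sizes.get(chrom)
    up_start = max(0, span.start - flank_size)
    down_end = span.end + flank_size
    if size is not None:
        down_end = min(down_end, size)
        span = GenomicInterval(chrom, span.start, min(span.end, size))
    up = GenomicInterval(chrom, up_start, span.start)
    down = GenomicInterval(chrom, min(span.end, down_end), down_end)
    return span, (up, down)


def _stats_from_clips(
    covs: np.ndarray,
    vals: np.ndarray,
    total_length: int,
    p90: float,
    wanted: Sequence[str],
) -> dict[str, float]:
    out: dict[str, float] = {}
    weighted = float((covs * vals).sum()) if covs.size else 0.0
    for stat in wanted:
        if stat == "max":
            out[stat] = float(vals.max()) if vals.size else 0.0
        elif stat == "sum":
            out[stat] = weighted
        elif stat == "mean":
            out[stat] = weighted / total_length if total_length > 0 else 0.0
        elif stat == "count_above_p90":
            out[stat] = float(covs[vals >= p90].sum()) if covs.size else 0.0
    return out


def summarize(track: AnnotationTrack, region: GenomicInterval, statistic: str) -> float:
    """One track summary statistic over one region (zero when undefined)."""
    if statistic not in TRACK_STATISTICS:
        raise DataError(f"statistic {statistic!r} does not apply to tracks")
    cov, val = track.clipped(region)
    return _stats_from_clips(cov, val, region.length, track.p90_threshold, [statistic])[
        statistic
    ]


def summarize_pooled(
    track: AnnotationTrack, regions: Sequence[GenomicInterval], statistic: str
) -> float:
    """A track statistic pooled over several regions (used for the two flanks)."""
    if statistic not in TRACK_STATISTICS:
        raise DataError(f"statistic {statistic!r} does not apply to tracks")
    covs, vals = [], []
    for region in regions:
        c, v = track.clipped(region)
        covs.append(c)
        vals.append(v)
    cov = np.concatenate(covs) if covs else np.empty(0, dtype=np.int64)
    val = np.concatenate(vals) if vals else np.empty(0)
    total = sum(r.length for r in regions)
    return _stats_from_clips(cov, val, total, track.p90_threshold, [statistic])[statistic]


def build_default_catalog(
    tracks: Mapping[str, AnnotationTrack],
    element_catalogs: Mapping[str, ElementCatalog],
    flank_size: int = DEFAULT_FLANK_SIZE,
    distance_sources: Sequence[str] | None = None,
    count_sources: Sequence[str] | None = None,
) -> FeatureCatalog:
    """A feature catalog covering every track and catalog with the stock statistics.

    Per track: max/mean/count_above_p90 on the span, max/mean on the flanks.
    Per element catalog: overlap counts on span and flanks, plus one distance
    feature (measured from the span edges, shared by both models).
    """
    entries: list[FeatureSpec] = []
    for name in tracks:
        for stat in ("max", "mean", "count_above_p90"):
            entries.append(FeatureSpec(f"{name}.{stat}.span", name, "span", stat))
        for stat in ("max", "mean"):
            entries.append(FeatureSpec(f"{name}.{stat}.flank", name, "flank", stat))
    count_sources = list(element_catalogs if count_sources is None else count_sources)
    distance_sources = list(
        element_catalogs if distance_sources is None else distance_sources
    )
    for name in count_sources:
        entries.append(
            FeatureSpec(f"{name}.overlap_count.span", name, "span", "overlap_count")
        )
        entries.append(
            FeatureSpec(f"{name}.overlap_count.flank", name, "flank", "overlap_count")
        )
    for name in distance_sources:
        entries.append(FeatureSpec(f"{name}.dist", name, "span", "nearest_distance"))
    return FeatureCatalog(entries, flank_size=flank_size)


def annotate_set(
    svs: Sequence[SVRecord],
    catalog: FeatureCatalog,
    tracks: Mapping[str, AnnotationTrack],
    element_catalogs: Mapping[str, ElementCatalog],
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Annotate SVs against a feature catalog -> (span matrix, flank matrix).

    Distance features are computed once from the span edges and appear in both
    matrices.  Every undefined value becomes 0, so the output is guaranteed
    finite.
    """
    dist_entries = [e for e in catalog.entries if e.statistic == "nearest_distance"]
    span_entries = [
        e
        for e in catalog.entries
        if e.region_kind == "span" and e.statistic != "nearest_distance"
    ]
    flank_entries = [
        e
        for e in catalog.entries
        if e.region_kind == "flank" and e.statistic != "nearest_distance"
    ]
    for e in catalog.entries:
        pool = element_catalogs if e.statistic in CATALOG_STATISTICS else tracks
        if e.source not in pool:
            raise DataError(
                f"feature {e.name!r} references unknown source {e.source!r}"
            )

    # group track features by source so each region is queried once per track
    def by_source(entries: list[FeatureSpec]) -> dict[str, list[FeatureSpec]]:
        grouped: dict[str, list[FeatureSpec]] = {}
        for e in entries:
            grouped.setdefault(e.source, []).append(e)
        return grouped

    span_by_src = by_source(span_entries)
    flank_by_src = by_source(flank_entries)

    span_cols = [e.name for e in span_entries] + [e.name for e in dist_entries]
    flank_cols = [e.name for e in flank_entries] + [e.name for e in dist_entries]
    span_rows = np.zeros((len(svs), len(span_cols)))
    flank_rows = np.zeros((len(svs), len(flank_cols)))
    span_idx = {name: i for i, name in enumerate(span_cols)}
    flank_idx = {name: i for i, name in enumerate(flank_cols)}

    for r, sv in enumerate(svs):
        span, flanks = extract_regions(sv, catalog.flank_size, chrom_sizes)
        for source, entries in span_by_src.items():
            track_stats = [e for e in entries if e.statistic in TRACK_STATISTICS]
            if track_stats:
                track = tracks[source]
                cov, val = track.clipped(span)
                stats = _stats_from_clips(
                    cov, val, span.length, track.p90_threshold,
                    [e.statistic for e in track_stats],
                )
                for e in track_stats:
                    span_rows[r, span_idx[e.name]] = stats[e.statistic]
            for e in entries:
                if e.statistic == "overlap_count":
                    span_rows[r, span_idx[e.name]] = element_catalogs[
                        e.source
                    ].overlap_count(span)
        for source, entries in flank_by_src.items():
            track_stats = [e for e in entries if e.statistic in TRACK_STATISTICS]
            if track_stats:
                track = tracks[source]
                covs, vals = [], []
                for region in flanks:
                    c, v = track.clipped(region)
                    covs.append(c)
                    vals.append(v)
                stats = _stats_from_clips(
                    np.concatenate(covs),
                    np.concatenate(vals),
                    sum(f.length for f in flanks),
                    track.p90_threshold,
                    [e.statistic for e in track_stats],
                )
                for e in track_stats:
                    flank_rows[r, flank_idx[e.name]] = stats[e.statistic]
            for e in entries:
                if e.statistic == "overlap_count":
                    flank_rows[r, flank_idx[e.name]] = sum(
                        element_catalogs[e.source].overlap_count(region)
                        for region in flanks
                    )
        for e in dist_entries:
            d = element_catalogs[e.source].nearest_distance(span)
            span_rows[r, span_idx[e.name]] = d
            flank_rows[r, flank_idx[e.name]] = d

    ids = [sv.id for sv in svs]
    span_tags = {e.name: "span" for e in span_entries}
    span_tags.update({e.name: "distance" for e in dist_entries})
    flank_tags = {e.name: "flank" for e in flank_entries}
    flank_tags.update({e.name: "distance" for e in dist_entries})

    def finish(rows: np.ndarray, cols: list[str], tags: dict[str, str]) -> FeatureMatrix:
        rows = np.nan_to_num(rows, nan=0.0, posinf=0.0, neginf=0.0)
        return FeatureMatrix(pd.DataFrame(rows, index=ids, columns=cols), tags)

    return finish(span_rows, span_cols, span_tags), finish(
        flank_rows, flank_cols, flank_tags
    )
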