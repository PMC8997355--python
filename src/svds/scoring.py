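"""Scoring of novel SVs: model routing, max-composition, Phred rank scaling.

Each SV type routes to one span model and one flank model, exploiting which
training events leave the reference annotations intact:

=====  ===========  ============
type   span model   flank model
=====  ===========  ============
DEL    chimp_DEL    human_DEL
INS    chimp_INS    human_INS
DUP    chimp_DEL    human_INS
=====  ===========  ============

The raw score is the maximum (more deleterious) of the two model outputs.
For interpretation it is Phred-scaled against the per-type raw-score
distribution of a healthy reference cohort: with p the proportion of cohort
variants scoring at least as high, the reported score is ``-10 log10(p)`` —
about 3 marks the top 50%, 10 the top 10%, 20 the top 1%, 30 the top 0.1%.
A raw score exceeding every cohort score is capped at ``p = 1/N`` so the
scale stays finite.  Phred values of different SV types are ranked against
different reference distributions and are not comparable across types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import annotate_set
from .intervals import DataError, ElementCatalog, AnnotationTrack, SVRecord
from .models import ModelBundle
from .normalize import OUTLIER_Z, apply_zscore

#: sv_type -> (span model origin, flank model origin); fixed by construction.
ROUTING: Mapping[str, tuple[str, str]] = MappingProxyType(
    {
        "DEL": ("chimp_DEL", "human_DEL"),
        "INS": ("chimp_INS", "human_INS"),
        "DUP": ("chimp_DEL", "human_INS"),
    }
)


@dataclass
class ScoreResult:
    """Scores for one SV plus its Z-valued features for interpretation."""

    sv_id: str
    sv_type: str
    span_score: float
    flank_score: float
    raw_score: float
    phred_score: float
    z_values: pd.Series
    outliers: pd.Series

    def __post_init__(self) -> None:
        assert self.raw_score == max(self.span_score, self.flank_score)


def phred_scale(raw_score: float, reference_scores: Sequence[float]) -> float:
    """Phred-scaled relative rank of a raw score in a reference distribution.

    ``p = #(reference >= raw) / N`` (ties count, so a variant matching the
    cohort maximum still gets a finite high value); a zero count is capped at
    ``1/N``.  Returns ``-10 log10(p) >= 0``.
    """
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size == 0:
        raise DataError("empty reference score distribution")
    ref = np.sort(ref)
    count = ref.size - int(np.searchsorted(ref, raw_score, side="left"))
    p = count / ref.size if count > 0 else 1.0 / ref.size
    return -10.0 * math.log10(p)


def score_svs(
    svs: Sequence[SVRecord],
    bundle: ModelBundle,
    tracks: Mapping[str, AnnotationTrack],
    element_catalogs: Mapping[str, ElementCatalog],
    reference_scores: Mapping[str, Sequence[float]] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    outlier_z: float = OUTLIER_Z,
) -> list[ScoreResult]:
    """Score SVs through the routed span/flank models of their type.

    ``reference_scores`` defaults to the cohort distributions stored in the
    bundle.  Inversions/translocations are rejected upstream by the SV table
    reader; an SV type without routing raises an explicit error here.
    """
    if reference_scores is None:
        reference_scores = bundle.reference_scores
    for sv in svs:
        if sv.sv_type not in ROUTING:
            raise DataError(f"unsupported SV type {sv.sv_type!r} for {sv.id!r}")
    raw = raw_scores(svs, bundle, tracks, element_catalogs, chrom_sizes)
    results: list[ScoreResult] = []
    for sv in svs:
        span_s, flank_s, z_row = raw[sv.id]
        raw_s = max(span_s, flank_s)
        ref = np.asarray(reference_scores.get(sv.sv_type, ()), dtype=float)
        if ref.size == 0:
            raise DataError(f"no reference score distribution for {sv.sv_type}")
        results.append(
            ScoreResult(
                sv_id=sv.id,
                sv_type=sv.sv_type,
                span_score=span_s,
                flank_score=flank_s,
                raw_score=raw_s,
                phred_score=phred_scale(raw_s, ref),
                z_values=z_row,
                outliers=z_row.abs() >= outlier_z,
            )
        )
    return results


def raw_scores(
    svs: Sequence[SVRecord],
    bundle: ModelBundle,
    tracks: Mapping[str, AnnotationTrack],
    element_catalogs: Mapping[str, ElementCatalog],
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, tuple[float, float, pd.Series]]:
    """Span/flank model outputs (plus the Z-valued feature row) per SV id.

    SVs are grouped by type so each group is annotated and Z-transformed
    against its own type's cohort statistics in one pass.
    """
    out: dict[str, tuple[float, float, pd.Series]] = {}
    by_type: dict[str, list[SVRecord]] = {}
    for sv in svs:
        if sv.sv_type not in ROUTING:
            raise DataError(f"unsupported SV type {sv.sv_type!r} for {sv.id!r}")
        by_type.setdefault(sv.sv_type, []).append(sv)
    for sv_type, group in by_type.items():
        span_origin, flank_origin = ROUTING[sv_type]
        for origin in (span_origin, flank_origin):
            if origin not in bundle.models:
                raise DataError(f"bundle lacks the {origin} model")
        span_m, flank_m = annotate_set(
            group, bundle.catalog, tracks, element_catalogs, chrom_sizes
        )
        z_span = apply_zscore(span_m, bundle.stats[(sv_type, "span")])
        z_flank = apply_zscore(flank_m, bundle.stats[(sv_type, "flank")])
        span_scores = bundle.models[span_origin].predict(z_span)
        flank_scores = bundle.models[flank_origin].predict(z_flank)
        z_all = pd.concat(
            [z_span.df.add_prefix("span:"), z_flank.df.add_prefix("flank:")], axis=1
        )
        for i, sv in enumerate(group):
            out[sv.id] = (
                float(span_scores[i]),
                float(flank_scores[i]),
                z_all.iloc[i],
            )
    return out


def cohort_reference_scores(
    cohort: Mapping[str, Sequence[SVRecord]],
    bundle: ModelBundle,
    tracks: Mapping[str, AnnotationTrack],
    element_catalogs: Mapping[str, ElementCatalog],
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Sorted per-type raw-score distributions of the reference cohort."""
    out: dict[str, np.ndarray] = {}
    for sv_type, records in cohort.items():
        raw = raw_scores(records, bundle, tracks, element_catalogs, chrom_sizes)
        out[sv_type] = np.sort(
            [max(raw[r.id][0], raw[r.id][1]) for r in records]
        )
    return out


def results_to_frame(
    svs: Sequence[SVRecord], results: Sequence[ScoreResult]
) -> pd.DataFrame:
    """Tabular output: coordinates, scores, then one column per Z-scored feature."""
    by_id = {r.sv_id: r for r in results}
    rows = []
    for sv in svs:
        r = by_id[sv.id]
        row = {
            "id": sv.id,
            "chrom": sv.interval.chrom,
            "start": sv.interval.start,
            "end": sv.interval.end,
            "type": sv.sv_type,
            "span_score": r.span_score,
            "flank_score": r.flank_score,
            "raw": r.raw_score,
            "phred": r.phred_score,
        }
        row.update({k: float(v) for k, v in r.z_values.items()})
        rows.append(row)
    return pd.DataFrame(rows)
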