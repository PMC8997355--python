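"""Genomic interval primitives and BED-like input/output.

All coordinates are BED-style 0-based half-open, so ``length == end - start``.
Strand is ignored throughout: every summary statistic downstream is
strand-symmetric.

Three on-disk dialects are supported, all plain tab-separated text:

* SV tables: ``chrom  start  end  name  type[  allele_count[  allele_frequency]]``
  with ``type`` one of DEL/INS/DUP; a header line is optional and detected by a
  non-numeric second column.
* annotation tracks: BED4 with a numeric value column;
* element catalogs: BED3.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

SV_TYPES = ("DEL", "INS", "DUP")

#: distance reported when a catalog has no element on the query chromosome.
#: A large finite constant rather than NaN so that downstream zero imputation
#: after Z-scoring does not silently turn "far from everything" into "average".
NO_ELEMENT_DISTANCE = 10_000_000


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SVRecord:
    """One structural variant with optional cohort allele statistics.

    DEL/DUP records cover an extent (``end > start``); INS records mark an
    integration site, normalised at load time to a 1-bp window ``[pos, pos+1)``.
    ``allele_count == 1`` defines a singleton.
    """

    interval: GenomicInterval
    sv_type: str
    id: str
    allele_count: int | None = None
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise DataError(f"unknown SV type {self.sv_type!r} for {self.id!r}")
        if self.sv_type in ("DEL", "DUP") and self.interval.length == 0:
            raise DataError(f"{self.sv_type} {self.id!r} has zero length")
        if self.allele_count is not None and self.allele_count < 0:
            raise DataError(f"negative allele count for {self.id!r}")

    @property
    def is_singleton(self) -> bool:
        return self.allele_count == 1


def length_weighted_percentile(
    values: Sequence[float], weights: Sequence[int], q: float
) -> float:
    """Percentile of a per-base value distribution given (value, n_bases) pairs.

    Equivalent to ``np.percentile(np.repeat(values, weights), q)`` with the
    default linear-interpolation method, without materialising the expansion.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=np.int64)
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    if values.size == 0:
        raise DataError("empty value distribution")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order])
    n = int(cum[-1])
    h = (n - 1) * q / 100.0
    i0 = int(np.floor(h))
    frac = h - i0

    def base_value(i: int) -> float:
        # value of the i-th base (0-based) of the sorted expanded array
        return float(v[np.searchsorted(cum, i, side="right")])

    x0 = base_value(i0)
    if frac == 0.0:
        return x0
    return x0 + frac * (base_value(min(i0 + 1, n - 1)) - x0)


def _resolve_overlaps(
    rows: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Resolve overlapping (start, end, value) rows by per-base maximum."""
    rows = sorted(rows)
    bounds = sorted({b for s, e, _ in rows for b in (s, e)})
    out: list[tuple[int, int, float]] = []
    heap: list[tuple[float, int]] = []  # (-value, end)
    i = 0
    for s, e in zip(bounds, bounds[1:]):
        while i < len(rows) and rows[i][0] <= s:
            heapq.heappush(heap, (-rows[i][2], rows[i][1]))
            i += 1
        while heap and heap[0][1] <= s:
            heapq.heappop(heap)
        if not heap:
            continue
        val = -heap[0][0]
        if out and out[-1][1] == s and out[-1][2] == val:
            out[-1] = (out[-1][0], e, val)
        else:
            out.append((s, e, val))
    return out


class AnnotationTrack:
    """A named numeric interval track with a precomputed 90th-percentile cut.

    Overlapping input intervals are resolved to the per-base maximum value
    (conservative toward deleteriousness, and deterministic).
    ``p90_threshold`` is the 90th percentile of the track's per-base value
    distribution over covered bases, by linear interpolation.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[tuple[str, int, int, float]],
        group: str = "ungrouped",
    ) -> None:
        self.name = name
        self.group = group
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if not np.isfinite(value):
                raise DataError(f"non-finite value in track {name!r}")
            if end <= start:
                continue
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        all_values: list[float] = []
        all_weights: list[int] = []
        for chrom, rows in per_chrom.items():
            resolved = _resolve_overlaps(rows)
            starts = np.array([r[0] for r in resolved], dtype=np.int64)
            ends = np.array([r[1] for r in resolved], dtype=np.int64)
            values = np.array([r[2] for r in resolved], dtype=float)
            self._chroms[chrom] = (starts, ends, values)
            all_values.extend(values.tolist())
            all_weights.extend((ends - starts).tolist())
        if not all_values:
            raise DataError(f"empty track {name!r}")
        self.p90_threshold = length_weighted_percentile(all_values, all_weights, 90.0)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._chroms))

    def iter_intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._chroms):
            starts, ends, values = self._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def clipped(self, region: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        """Base coverage and value of every track interval overlapping *region*."""
        arr = self._chroms.get(region.chrom)
        if arr is None or region.length == 0:
            return np.empty(0, dtype=np.int64), np.empty(0)
        starts, ends, values = arr
        i = int(np.searchsorted(ends, region.start, side="right"))
        j = int(np.searchsorted(starts, region.end, side="left"))
        if j <= i:
            return np.empty(0, dtype=np.int64), np.empty(0)
        cov = np.minimum(ends[i:j], region.end) - np.maximum(starts[i:j], region.start)
        keep = cov > 0
        return cov[keep], values[i:j][keep]

    def overlap_values(self, region: GenomicInterval) -> list[tuple[int, float]]:
        cov, val = self.clipped(region)
        return [(int(c), float(v)) for c, v in zip(cov, val)]


class ElementCatalog:
    """A named set of genomic elements supporting overlap and distance queries."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]) -> None:
        self.name = name
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._n = 0
        for chrom, rows in per_chrom.items():
            rows.sort()
            self._chroms[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
            )
            self._n += len(rows)

    def __len__(self) -> int:
        return self._n

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._chroms))

    def iter_intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._chroms):
            starts, ends = self._chroms[chrom]
            for s, e in zip(starts, ends):
                yield chrom, int(s), int(e)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        return self._chroms.get(chrom)

    def overlap_count(self, region: GenomicInterval) -> int:
        arr = self._chroms.get(region.chrom)
        if arr is None:
            return 0
        starts, ends = arr
        return int(np.sum((starts < region.end) & (ends > region.start)))

    def overlaps_any(self, region: GenomicInterval) -> bool:
        return self.overlap_count(region) > 0

    def nearest_distance(
        self, region: GenomicInterval, sentinel: int = NO_ELEMENT_DISTANCE
    ) -> int:
        arr = self._chroms.get(region.chrom)
        if arr is None or arr[0].size == 0:
            return sentinel
        starts, ends = arr
        gap = np.maximum(
            np.maximum(starts - region.end, region.start - ends), 0
        )
        return int(gap.min())


def nearest_distance(
    query: GenomicInterval,
    catalog: ElementCatalog,
    sentinel: int = NO_ELEMENT_DISTANCE,
) -> int:
    """Gap in bases between *query* and the closest catalog element (0 on overlap)."""
    return catalog.nearest_distance(query, sentinel=sentinel)


def overlap_values(
    query: GenomicInterval, track: AnnotationTrack
) -> list[tuple[int, float]]:
    """Every track interval clipped to *query* as (covered_bases, value) pairs."""
    return track.overlap_values(query)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_sv_table(path: str | Path) -> list[SVRecord]:
    """Read a tab-separated SV table.

    Columns: chrom, start, end, name, type[, allele_count[, allele_frequency]].
    A header line is detected by a non-numeric second column.  Insertion rows
    with ``end == start`` are normalised to the 1-bp site window
    ``[pos, pos+1)``.
    """
    path = Path(path)
    records: list[SVRecord] = []
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            if len(fields) >= 2 and not _is_int(fields[1]):
                continue  # header
        if len(fields) < 5:
            raise DataError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
        chrom, start_s, end_s, name, sv_type = fields[:5]
        if not (_is_int(start_s) and _is_int(end_s)):
            raise DataError(f"{path}:{lineno}: non-integer coordinates")
        start, end = int(start_s), int(end_s)
        if start > end:
            raise DataError(f"{path}:{lineno}: start > end ({start} > {end})")
        if sv_type not in SV_TYPES:
            raise DataError(
                f"{path}:{lineno}: unknown SV type {sv_type!r} "
                f"(expected one of {', '.join(SV_TYPES)})"
            )
        if sv_type == "INS" and end == start:
            end = start + 1
        allele_count = None
        allele_frequency = None
        if len(fields) >= 6 and fields[5] not in ("", "."):
            if not _is_int(fields[5]):
                raise DataError(f"{path}:{lineno}: non-integer allele count")
            allele_count = int(fields[5])
        if len(fields) >= 7 and fields[6] not in ("", "."):
            try:
                allele_frequency = float(fields[6])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric allele frequency")
            if not 0.0 <= allele_frequency <= 1.0:
                raise DataError(f"{path}:{lineno}: allele frequency outside [0, 1]")
        try:
            records.append(
                SVRecord(
                    GenomicInterval(chrom, start, end),
                    sv_type,
                    name,
                    allele_count,
                    allele_frequency,
                )
            )
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from None
    return records


def write_sv_table(records: Iterable[SVRecord], path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("chrom\tstart\tend\tname\ttype\tallele_count\tallele_frequency\n")
        for rec in records:
            iv = rec.interval
            ac = "." if rec.allele_count is None else str(rec.allele_count)
            af = "." if rec.allele_frequency is None else repr(rec.allele_frequency)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.id}\t{rec.sv_type}\t{ac}\t{af}\n"
            )


def read_track(path: str | Path, name: str, group: str = "ungrouped") -> AnnotationTrack:
    """Read a BED4 annotation track (chrom, start, end, value)."""
    path = Path(path)
    rows: list[tuple[str, int, int, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise DataError(f"{path}:{lineno}: expected >=4 columns")
        chrom, start_s, end_s, value_s = fields[:4]
        if not (_is_int(start_s) and _is_int(end_s)):
            if not rows and lineno == 1:
                continue  # header
            raise DataError(f"{path}:{lineno}: non-integer coordinates")
        try:
            value = float(value_s)
        except ValueError:
            raise DataError(f"{path}:{lineno}: non-numeric score {value_s!r}") from None
        rows.append((chrom, int(start_s), int(end_s), value))
    if not rows:
        raise DataError(f"{path}: empty track")
    return AnnotationTrack(name, rows, group=group)


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for chrom, start, end, value in track.iter_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_catalog(path: str | Path, name: str) -> ElementCatalog:
    """Read a BED3 element catalog."""
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: expected >=3 columns")
        chrom, start_s, end_s = fields[:3]
        if not (_is_int(start_s) and _is_int(end_s)):
            if first:
                first = False
                continue
            raise DataError(f"{path}:{lineno}: non-integer coordinates")
        first = False
        rows.append((chrom, int(start_s), int(end_s)))
    return ElementCatalog(name, rows)


def write_catalog(catalog: ElementCatalog, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for chrom, start, end in catalog.iter_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")
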