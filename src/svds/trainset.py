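"""Proxy-deleterious training sets by matched shuffling, and holdout splits.

Evolutionarily fixed SVs survived purifying selection and serve as
proxy-neutral examples.  The contrasting proxy-deleterious set is built by
redistributing the same SVs — matched exactly in length and number — uniformly
over the alignable portion of the genome, where a considerable fraction will
hit functional sequence by chance.  Placement is uniform over *all* valid
genome-wide start positions: an alignable interval is chosen with probability
proportional to the number of valid starts it offers, then a start is drawn
uniformly inside it.  Shuffled SVs may overlap each other and the source SVs.

Sex chromosomes are excluded from placement by default (their comparative
annotation quality is poor); the exclusion list is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import DataError, ElementCatalog, GenomicInterval, SVRecord

LABELS = ("proxy_neutral", "proxy_deleterious")
ORIGINS = ("human_DEL", "human_INS", "chimp_DEL", "chimp_INS", "simulated")

DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class LabeledSVSet:
    """A homogeneous set of SVs with a proxy label and an origin tag."""

    records: list[SVRecord]
    label: str
    origin: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise DataError(f"unknown label {self.label!r}")
        kinds = {"INS" if r.sv_type == "INS" else "EXTENT" for r in self.records}
        if len(kinds) > 1:
            raise DataError("mixed span semantics (INS points vs DEL/DUP extents)")

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> list[int]:
        return [r.interval.length for r in self.records]


def shuffle_matched(
    svs: Sequence[SVRecord],
    alignable: ElementCatalog,
    seed: int,
    exclude_chroms: Iterable[str] = DEFAULT_SEX_CHROMS,
    origin: str = "simulated",
) -> LabeledSVSet:
    """Length- and count-matched random redistribution within alignable regions.

    The output has exactly the same number of records and the same multiset of
    lengths as the input; every placed interval lies entirely inside one
    alignable interval.  An SV longer than every alignable interval is a hard
    error.
    """
    excluded = set(exclude_chroms)
    ivs = [
        (chrom, start, end)
        for chrom, start, end in alignable.iter_intervals()
        if chrom not in excluded
    ]
    if not ivs:
        raise DataError("no alignable intervals outside the excluded chromosomes")
    chroms = [iv[0] for iv in ivs]
    starts = np.array([iv[1] for iv in ivs], dtype=np.int64)
    ends = np.array([iv[2] for iv in ivs], dtype=np.int64)
    lens = ends - starts

    rng = np.random.default_rng(seed)
    out: list[SVRecord] = []
    for rec in svs:
        length = rec.interval.length if rec.sv_type != "INS" else 1
        caps = lens - length + 1
        caps[caps < 0] = 0
        total = int(caps.sum())
        if total == 0:
            raise DataError(
                f"SV {rec.id!r} (length {length}) does not fit in any alignable interval"
            )
        k = int(rng.choice(len(ivs), p=caps / total))
        pos = int(starts[k] + rng.integers(0, caps[k]))
        out.append(
            SVRecord(
                GenomicInterval(chroms[k], pos, pos + length),
                rec.sv_type,
                f"{rec.id}_shuf",
            )
        )
    return LabeledSVSet(out, "proxy_deleterious", origin)


def _split_indices(n: int, frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_hold = min(n, math.ceil(frac * n)) if n else 0
    perm = rng.permutation(n)
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])


def train_holdout_split(
    pos: LabeledSVSet,
    neg: LabeledSVSet,
    holdout_frac: float,
    seed: int,
) -> tuple[LabeledSVSet, LabeledSVSet, LabeledSVSet, LabeledSVSet]:
    """Label-stratified random split -> (train_pos, train_neg, holdout_pos, holdout_neg).

    The holdout size is ``ceil(frac * n)`` per label, so a nonempty input never
    yields an empty holdout.  Deterministic under the seed; no record appears
    in both partitions.
    """
    if not 0.0 < holdout_frac < 1.0:
        raise DataError("holdout_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def cut(s: LabeledSVSet) -> tuple[LabeledSVSet, LabeledSVSet]:
        tr, ho = _split_indices(len(s), holdout_frac, rng)
        return (
            LabeledSVSet([s.records[i] for i in tr], s.label, s.origin),
            LabeledSVSet([s.records[i] for i in ho], s.label, s.origin),
        )

    train_pos, hold_pos = cut(pos)
    train_neg, hold_neg = cut(neg)
    return train_pos, train_neg, hold_pos, hold_neg
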