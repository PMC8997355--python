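"""Z-score feature transformation against a reference population cohort.

Every feature is centred and scaled using the value distribution of same-type
SVs drawn from a healthy reference cohort (at most ``cap`` of them, default
20,000).  The transformation serves interpretability: after it, a feature
value of 4 reads as "four standard deviations beyond the cohort mean".  It is
applied identically to both training class labels, so it cannot leak label
information into the models.

The standard deviation uses ``ddof=1`` (the reference is a sample of the
cohort); features that are constant in the reference are flagged degenerate
and map to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .intervals import DataError

DEFAULT_CAP = 20_000
OUTLIER_Z = 2.0


@dataclass
class TransformStats:
    """Per-feature reference mean/SD plus provenance."""

    means: pd.Series
    sds: pd.Series
    n_used: int
    sv_type: str
    cohort_id: str = ""

    @property
    def feature_names(self) -> list[str]:
        return list(self.means.index)

    @property
    def degenerate(self) -> list[str]:
        return list(self.sds.index[self.sds == 0.0])

    def to_dict(self) -> dict:
        return {
            "sv_type": self.sv_type,
            "cohort_id": self.cohort_id,
            "n_used": self.n_used,
            "features": self.feature_names,
            "means": [float(x) for x in self.means],
            "sds": [float(x) for x in self.sds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformStats":
        idx = pd.Index(d["features"])
        return cls(
            means=pd.Series(d["means"], index=idx, dtype=float),
            sds=pd.Series(d["sds"], index=idx, dtype=float),
            n_used=int(d["n_used"]),
            sv_type=d["sv_type"],
            cohort_id=d.get("cohort_id", ""),
        )

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformStats":
        with open(Path(path)) as fh:
            return cls.from_dict(json.load(fh))


def fit_transform_stats(
    reference_matrix: FeatureMatrix,
    sv_type: str,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
    cohort_id: str = "",
) -> TransformStats:
    """Per-feature mean and sample SD from (a subsample of) the reference cohort."""
    df = reference_matrix.df
    if len(df) < 2:
        raise DataError("need at least 2 reference rows to fit transform statistics")
    if len(df) > cap:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(df), size=cap, replace=False))
        df = df.iloc[keep]
    return TransformStats(
        means=df.mean(axis=0),
        sds=df.std(axis=0, ddof=1),
        n_used=len(df),
        sv_type=sv_type,
        cohort_id=cohort_id,
    )


def apply_zscore(matrix: FeatureMatrix, stats: TransformStats) -> FeatureMatrix:
    """Transform every value to (value - ref_mean) / ref_SD.

    Degenerate features (reference SD of zero) map to zero.  The matrix must
    carry exactly the features the statistics were fitted on.
    """
    have = set(matrix.feature_names)
    want = set(stats.feature_names)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise DataError(
            f"feature mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
        )
    df = matrix.df[stats.feature_names]
    sds = stats.sds.replace(0.0, np.inf)  # degenerate -> 0 after division
    z = (df - stats.means) / sds
    return FeatureMatrix(z, dict(matrix.region_tags))


def outlier_flags(zmatrix: FeatureMatrix, threshold: float = OUTLIER_Z) -> pd.DataFrame:
    """Boolean mask of |z| >= threshold, used to highlight extreme annotations."""
    return zmatrix.df.abs() >= threshold
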