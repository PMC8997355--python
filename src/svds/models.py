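"""Classifier training, one-at-a-time hyperparameter search, model bundles.

Four classifiers are trained — human DEL, chimp DEL, human INS, chimp INS —
each contrasting a proxy-neutral set against its matched shuffled
proxy-deleterious set.  Random forests are the default (logistic regression is
kept as the simpler alternative); the raw model output is the predicted
probability of the proxy-deleterious class, so higher means more deleterious.

The hyperparameter protocol sweeps each of the three forest parameters —
number of trees, minimum node size, maximum leaf nodes — one at a time with
the other two fixed at 100, over the grids
``n_trees in {25, 50, 75, 100, 200, 500, 1000}`` and
``min_node_size, max_leaf_nodes in {10, 50, 100, 250, 500, 1000}``
(19 settings in total), selecting per parameter by holdout AUROC with ties
broken toward the cheaper value.  One fixed 10% holdout is reused across all
settings so the sweep is comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .evaluation import auroc
from .features import FeatureCatalog, FeatureMatrix
from .intervals import DataError
from .normalize import TransformStats

MODEL_KINDS = ("random_forest", "logistic_regression")

DEFAULT_GRID: dict[str, tuple[int, ...]] = {
    "n_trees": (25, 50, 75, 100, 200, 500, 1000),
    "min_node_size": (10, 50, 100, 250, 500, 1000),
    "max_leaf_nodes": (10, 50, 100, 250, 500, 1000),
}


@dataclass(frozen=True)
class ModelSpec:
    """Model kind plus forest hyperparameters (defaults: 100/100/100)."""

    model_kind: str = "random_forest"
    n_trees: int = 100
    min_node_size: int = 100
    max_leaf_nodes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise DataError(f"unknown model kind {self.model_kind!r}")
        if min(self.n_trees, self.min_node_size, self.max_leaf_nodes) <= 0:
            raise DataError("hyperparameters must be positive")


def _make_estimator(spec: ModelSpec):
    if spec.model_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            min_samples_leaf=spec.min_node_size,
            max_leaf_nodes=spec.max_leaf_nodes,
            random_state=spec.seed,
            n_jobs=1,
        )
    return LogisticRegression(max_iter=2000, random_state=spec.seed)


@dataclass
class TrainedModel:
    """A fitted classifier bound to the exact ordered feature list it saw."""

    estimator: object
    feature_names: tuple[str, ...]
    spec: ModelSpec
    region: str = ""  # which matrix it consumes: "span" or "flank"

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        """Proxy-deleterious probability per SV, in [0, 1]."""
        if tuple(matrix.feature_names) != self.feature_names:
            if set(matrix.feature_names) == set(self.feature_names):
                X = matrix.df[list(self.feature_names)].to_numpy()
            else:
                missing = sorted(set(self.feature_names) - set(matrix.feature_names))
                raise DataError(f"matrix is missing model features: {missing}")
        else:
            X = matrix.df.to_numpy()
        return self.estimator.predict_proba(X)[:, 1]

    @property
    def fingerprint(self) -> str:
        return hashlib.sha256("\n".join(self.feature_names).encode()).hexdigest()[:16]


def train(pos: FeatureMatrix, neg: FeatureMatrix, spec: ModelSpec) -> TrainedModel:
    """Fit a classifier of proxy-deleterious (pos, label 1) vs proxy-neutral (neg).

    Class balance is expected by construction (matched counts), so no class
    weighting is applied.  Deterministic under ``spec.seed``.
    """
    if len(pos.df) == 0 or len(neg.df) == 0:
        raise DataError("both classes must be non-empty")
    if list(pos.feature_names) != list(neg.feature_names):
        raise DataError("pos/neg feature names differ")
    X = np.vstack([pos.df.to_numpy(), neg.df.to_numpy()])
    y = np.concatenate([np.ones(len(pos.df)), np.zeros(len(neg.df))])
    est = _make_estimator(spec)
    est.fit(X, y)
    return TrainedModel(est, tuple(pos.feature_names), spec)


def hyperparameter_search(
    pos: FeatureMatrix,
    neg: FeatureMatrix,
    grid: Mapping[str, Sequence[int]] | None = None,
    seed: int = 0,
    holdout_frac: float = 0.1,
) -> tuple[ModelSpec, pd.DataFrame]:
    """One-at-a-time sweep -> (best spec, full metric table).

    Returns the per-parameter winners composed into one spec, and a table with
    one row per evaluated setting (parameter, value, holdout AUROC).
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    rng = np.random.default_rng(seed)

    def split(m: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
        n = len(m.df)
        n_hold = max(1, int(np.ceil(holdout_frac * n)))
        perm = rng.permutation(n)
        hold = np.sort(perm[:n_hold])
        tr = np.sort(perm[n_hold:])
        return (
            FeatureMatrix(m.df.iloc[tr], dict(m.region_tags)),
            FeatureMatrix(m.df.iloc[hold], dict(m.region_tags)),
        )

    pos_tr, pos_ho = split(pos)
    neg_tr, neg_ho = split(neg)

    rows = []
    best: dict[str, int] = {}
    for param, values in grid.items():
        best_val, best_auc = None, -np.inf
        for value in values:
            spec = ModelSpec(seed=seed, **{param: int(value)})
            model = train(pos_tr, neg_tr, spec)
            auc = auroc(model.predict(pos_ho), model.predict(neg_ho))
            rows.append({"parameter": param, "value": int(value), "auroc": auc})
            if auc > best_auc:  # strict: ties keep the earlier (smaller) value
                best_val, best_auc = int(value), auc
        best[param] = best_val
    table = pd.DataFrame(rows)
    best_spec = ModelSpec(seed=seed, **best)
    return best_spec, table


def feature_importance(model: TrainedModel) -> pd.Series:
    """Nonnegative importances, normalised to sum 1, sorted descending.

    Random forests report impurity-based importances; logistic models report
    absolute coefficients instead (the series is named accordingly).
    """
    est = model.estimator
    if isinstance(est, RandomForestClassifier):
        raw = np.asarray(est.feature_importances_, dtype=float)
        name = "importance"
    else:
        raw = np.abs(np.asarray(est.coef_, dtype=float).ravel())
        name = "abs_coefficient"
    total = raw.sum()
    if total > 0:
        raw = raw / total
    series = pd.Series(raw, index=list(model.feature_names), name=name)
    return series.sort_values(ascending=False)


@dataclass
class ModelBundle:
    """The four trained models plus everything scoring needs.

    ``models`` is keyed by origin; chimp models consume span matrices, human
    models consume flank matrices.  ``stats`` holds the cohort transformation
    statistics per (sv_type, region) so scoring reuses training-time scaling
    exactly.  ``reference_scores`` holds the per-type raw-score distribution
    of the reference cohort for Phred scaling.
    """

    models: dict[str, TrainedModel]
    stats: dict[tuple[str, str], TransformStats]
    catalog: FeatureCatalog
    metrics: dict = field(default_factory=dict)
    importances: dict[str, pd.Series] = field(default_factory=dict)
    reference_scores: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "flank_size": self.catalog.flank_size,
            "features": [
                dataclasses.asdict(e) for e in self.catalog.entries
            ],
            "models": {},
            "metrics": self.metrics,
            "stats": {
                f"{t}:{r}": s.to_dict() for (t, r), s in self.stats.items()
            },
            "reference_scores": {
                t: [float(x) for x in v] for t, v in self.reference_scores.items()
            },
        }
        for origin, model in self.models.items():
            joblib.dump(model.estimator, outdir / f"model_{origin}.joblib")
            meta["models"][origin] = {
                "features": list(model.feature_names),
                "fingerprint": model.fingerprint,
                "region": model.region,
                "spec": dataclasses.asdict(model.spec),
            }
        for origin, imp in self.importances.items():
            meta.setdefault("importances", {})[origin] = {
                k: float(v) for k, v in imp.items()
            }
        with open(outdir / "bundle.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, outdir: str | Path) -> "ModelBundle":
        from .features import FeatureSpec

        outdir = Path(outdir)
        with open(outdir / "bundle.json") as fh:
            meta = json.load(fh)
        catalog = FeatureCatalog(
            [
                FeatureSpec(d["name"], d["source"], d["region_kind"], d["statistic"])
                for d in meta["features"]
            ],
            flank_size=int(meta["flank_size"]),
        )
        models: dict[str, TrainedModel] = {}
        for origin, m in meta["models"].items():
            est = joblib.load(outdir / f"model_{origin}.joblib")
            model = TrainedModel(
                est, tuple(m["features"]), ModelSpec(**m["spec"]), m["region"]
            )
            if model.fingerprint != m["fingerprint"]:
                raise DataError(f"feature fingerprint mismatch for {origin}")
            models[origin] = model
        stats = {}
        for key, d in meta["stats"].items():
            sv_type, region = key.split(":")
            stats[(sv_type, region)] = TransformStats.from_dict(d)
        importances = {
            origin: pd.Series(d, name="importance")
            for origin, d in meta.get("importances", {}).items()
        }
        reference = {
            t: np.asarray(v, dtype=float)
            for t, v in meta.get("reference_scores", {}).items()
        }
        return cls(models, stats, catalog, meta.get("metrics", {}), importances, reference)
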