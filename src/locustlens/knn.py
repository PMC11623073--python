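"""From-scratch K-nearest-neighbour classifier.

Distances are weighted Minkowski sums ``(sum_r w_r |x_r - z_r|^p)^(1/p)``
with ``p=1`` (Manhattan, the tuned metric), ``p=2`` (Euclidean) or a caller
``p``.  Prediction is the majority vote of the ``k`` nearest training
samples; the positive score is the (possibly distance-weighted) fraction of
presence-labelled neighbours, which is what the AUC is computed from.

Tie handling is fully deterministic: equal distances rank by smaller
training index, and an exactly tied class vote goes to the class of the
single nearest neighbour.  Features are z-scored with statistics from the
fitted rows only (constant columns get unit spread); a pre-computed scaler
can be injected to reproduce pre-split scaling.

Brute force only — exact at the scale this pipeline runs at; there is no
tree acceleration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GladDataset
from .errors import ContractError

FEATURE_NAMES = [
    "start_year",
    "start_month",
    "precipitation",
    "max_temperature",
    "soil_moisture",
]


@dataclass(frozen=True)
class KnnConfig:
    k: int = 7
    weights: str = "uniform"  # uniform | distance
    metric: str = "manhattan"  # manhattan | euclidean | minkowski
    p: float | None = None  # only for metric="minkowski"
    feature_weights: tuple[float, ...] | None = None  # default all ones

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ContractError("k must be >= 1")
        if self.weights not in ("uniform", "distance"):
            raise ContractError(f"unknown weights mode {self.weights!r}")
        if self.metric not in ("manhattan", "euclidean", "minkowski"):
            raise ContractError(f"unknown metric {self.metric!r}")
        if self.metric == "minkowski" and (self.p is None or self.p < 1):
            raise ContractError("minkowski metric needs p >= 1")
        if self.feature_weights is not None and any(
            w < 0 for w in self.feature_weights
        ):
            raise ContractError("feature weights must be non-negative")

    @property
    def order(self) -> float:
        return {"manhattan": 1.0, "euclidean": 2.0}.get(self.metric, self.p)


def encode_features(
    rows: GladDataset | pd.DataFrame,
    one_hot_region: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric design matrix in the fixed order (year, month, ppt, tmax,
    soil); labels map yes→1, no→0.  ``one_hot_region`` appends indicator
    columns for each region name (off by default: region strings are not
    distance features)."""
    df = rows.rows if isinstance(rows, GladDataset) else rows
    if len(df) == 0:
        raise ContractError("cannot encode an empty table")
    months = df["start_month"].to_numpy()
    if ((months < 1) | (months > 12)).any():
        raise ContractError("start_month outside 1..12")
    labels = df["locust_present"]
    bad = set(labels.unique()) - {"yes", "no"}
    if bad:
        raise ContractError(f"unknown label values: {sorted(bad)}")
    X = df[
        ["start_year", "start_month", "precipitation", "max_temperature",
         "soil_moisture"]
    ].to_numpy(dtype=float)
    names = list(FEATURE_NAMES)
    if one_hot_region:
        dummies = pd.get_dummies(df["region"], prefix="region")
        X = np.hstack([X, dummies.to_numpy(dtype=float)])
        names += list(dummies.columns)
    y = (labels == "yes").to_numpy().astype(int)
    return X, y, names


def manhattan_distance(x, z, w=None) -> float:
    """Weighted L1 distance ``sum_r w_r |x_r - z_r|`` (w defaults to ones)."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ContractError(f"dimension mismatch: {x.shape} vs {z.shape}")
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if w.shape != x.shape:
        raise ContractError("feature-weight dimension mismatch")
    return float(np.sum(w * np.abs(x - z)))


@dataclass
class FittedKnn:
    """Frozen training state: standardized matrix, labels, scaler, config."""

    X: np.ndarray  # standardized, (n, d)
    y: np.ndarray  # int labels, (n,)
    center: np.ndarray
    spread: np.ndarray
    config: KnnConfig

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.spread

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": {
                    "k": self.config.k,
                    "weights": self.config.weights,
                    "metric": self.config.metric,
                    "p": self.config.p,
                    "feature_weights": self.config.feature_weights,
                },
                "center": self.center.tolist(),
                "spread": self.spread.tolist(),
                "X": self.X.tolist(),
                "y": self.y.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedKnn":
        obj = json.loads(text)
        cfg = obj["config"]
        fw = cfg["feature_weights"]
        return cls(
            X=np.array(obj["X"], dtype=float),
            y=np.array(obj["y"], dtype=int),
            center=np.array(obj["center"], dtype=float),
            spread=np.array(obj["spread"], dtype=float),
            config=KnnConfig(
                k=cfg["k"],
                weights=cfg["weights"],
                metric=cfg["metric"],
                p=cfg["p"],
                feature_weights=tuple(fw) if fw is not None else None,
            ),
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: KnnConfig = KnnConfig(),
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> FittedKnn:
    """Store the standardized training matrix; K-NN is a lazy learner, so
    there is no iterative training step.

    ``scaler`` injects external (center, spread) statistics; by default they
    come from the fitted rows only, so no test information leaks in.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ContractError("training matrix must be (n >= 1, d)")
    if y.shape[0] != X.shape[0]:
        raise ContractError("label/sample count mismatch")
    if config.feature_weights is not None and len(config.feature_weights) != X.shape[1]:
        raise ContractError("feature-weight length must equal feature dimension")
    if scaler is None:
        center = X.mean(axis=0)
        spread = X.std(axis=0)
    else:
        center = np.asarray(scaler[0], dtype=float)
        spread = np.asarray(scaler[1], dtype=float).copy()
    spread = np.where(spread > 0, spread, 1.0)  # constant features: unit spread
    return FittedKnn(
        X=(X - center) / spread, y=y, center=center, spread=spread, config=config
    )


def _distances(model: FittedKnn, xs: np.ndarray) -> np.ndarray:
    d = model.X.shape[1]
    w = (
        np.ones(d)
        if model.config.feature_weights is None
        else np.asarray(model.config.feature_weights, dtype=float)
    )
    diff = np.abs(model.X - xs)  # (n, d)
    p = model.config.order
    if p == 1.0:
        return (diff * w).sum(axis=1)
    return np.power((w * np.power(diff, p)).sum(axis=1), 1.0 / p)


def nearest_neighbours(
    model: FittedKnn, x: np.ndarray, k: int | None = None
) -> list[tuple[int, float]]:
    """The ``k`` nearest training samples to the standardized query ``x``,
    ascending by distance, exact ties by smaller training index."""
    k = model.config.k if k is None else k
    if k > model.n:
        raise ContractError(f"k={k} exceeds training size n={model.n}")
    dist = _distances(model, np.asarray(x, dtype=float))
    order = np.argsort(dist, kind="stable")[:k]
    return [(int(i), float(dist[i])) for i in order]


def vote(
    labels: np.ndarray,
    distances: np.ndarray,
    weights: str = "uniform",
) -> tuple[int, float]:
    """Majority (or distance-weighted) vote over neighbour labels.

    Returns (class, positive score).  In distance mode any zero-distance
    neighbours dominate: the vote is restricted to them with equal weight.
    An exactly tied vote goes to the class of the nearest neighbour
    (``labels``/``distances`` are in ascending-distance order).
    """
    labels = np.asarray(labels, dtype=int)
    distances = np.asarray(distances, dtype=float)
    if labels.size == 0:
        raise ContractError("vote needs at least one neighbour")
    if weights == "uniform":
        w = np.ones_like(distances)
    elif weights == "distance":
        zero = distances == 0.0
        if zero.any():
            w = zero.astype(float)
        else:
            w = 1.0 / distances
    else:
        raise ContractError(f"unknown weights mode {weights!r}")
    classes = np.unique(labels)
    totals = {int(c): float(w[labels == c].sum()) for c in classes}
    best = max(totals.values())
    winners = [c for c, t in totals.items() if t == best]
    label = int(labels[0]) if len(winners) > 1 else winners[0]
    score = totals.get(1, 0.0) / w.sum()
    return label, float(score)


def predict(model: FittedKnn, x: np.ndarray) -> tuple[int, float]:
    """Scale the query, find neighbours (k capped at n), vote."""
    k = min(model.config.k, model.n)
    nn = nearest_neighbours(model, model.transform(x), k)
    idx = np.array([i for i, _ in nn])
    dist = np.array([d for _, d in nn])
    return vote(model.y[idx], dist, model.config.weights)
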