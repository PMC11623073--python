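"""Country-partitioned K-NN presence/absence model.

The core idea is divide-and-conquer: instead of one K-NN fitted on the whole
labelled table, each test sample is classified by a K-NN fitted only on
training rows from the same country, because the climate→attack relationship
differs between countries (and can even flip sign).  A pooled "global"
baseline is available for comparison and is provably identical on
single-country data.

The public surface follows the Model/Results convention: build a
:class:`LocustLens` from a labelled table, call :meth:`~LocustLens.fit` to
run the stratified cross-validation loop, and read estimates, per-country
diagnostics and timings off the returned :class:`LocustLensResults`
(``summary()`` renders the usual text table).  The functional layer
(:func:`stratified_split`, :func:`predict_locustlens`,
:func:`predict_global_baseline`, :func:`random_search`) underneath is what
the results object wraps.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import knn
from .containers import GladDataset
from .errors import ContractError, StratificationError
from .knn import FittedKnn, KnnConfig
from .metrics import MetricsReport, evaluate

RECORD_COLUMNS = [
    "y_true", "y_pred", "score", "country", "fold", "fallback",
    "fit_s", "predict_s",
]

#: Columns of a prediction record that are reproducible byte-for-byte
#: (wall-clock timings are not, so file outputs exclude them).
DETERMINISTIC_COLUMNS = ["y_true", "y_pred", "score", "country", "fold", "fallback"]


@dataclass
class PredictionRecord:
    y_true: int
    y_pred: int
    score: float
    country: str
    fit_s: float
    predict_s: float
    fold: int
    fallback: bool = False


def records_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.y_true, r.y_pred, r.score, r.country, r.fold, r.fallback,
             r.fit_s, r.predict_s)
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def stratified_split(
    data: pd.DataFrame,
    n_splits: int = 5,
    shuffle: bool = True,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold (train, test) index pairs over the labelled table.

    Folds partition the rows and preserve the class ratio to within one
    sample per fold.  Raises :class:`StratificationError` when a class has
    fewer members than ``n_splits``.
    """
    y = data["locust_present"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < n_splits).any():
        small = counts[counts < n_splits].to_dict()
        raise StratificationError(
            f"classes too small for {n_splits} folds: {small}"
        )
    skf = StratifiedKFold(
        n_splits=n_splits, shuffle=shuffle, random_state=seed if shuffle else None
    )
    return [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(len(y)), y)
    ]


def _fit_subset(
    train: pd.DataFrame,
    config: KnnConfig,
    scaler: tuple[np.ndarray, np.ndarray] | None,
) -> tuple[FittedKnn, float]:
    X, y, _ = knn.encode_features(train)
    t0 = time.perf_counter()
    model = knn.fit(X, y, config, scaler=scaler)
    return model, time.perf_counter() - t0


def predict_locustlens(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: KnnConfig = KnnConfig(),
    fold: int = 0,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[PredictionRecord]:
    """Classify each test row with a K-NN fitted on same-country training rows.

    One model is fitted (and timed) per country present in the test set and
    reused for all of that country's test rows — identical predictions to
    refitting per sample, at a fraction of the cost.  A test country absent
    from training falls back to the full training pool and is flagged.
    ``k`` is capped at the subset size when a country has fewer than ``k``
    training rows.
    """
    if train["locust_present"].nunique() < 2:
        raise ContractError("training rows must contain both classes")
    X_test, y_test, _ = knn.encode_features(test)
    train_countries = set(train["country"].unique())
    models: dict[str, tuple[FittedKnn, float]] = {}
    records: list[PredictionRecord] = []
    for pos, (row_country, x, truth) in enumerate(
        zip(test["country"].to_numpy(), X_test, y_test)
    ):
        country = str(row_country)
        fallback = country not in train_countries
        key = "\0global" if fallback else country
        if key not in models:
            subset = train if fallback else train[train["country"] == country]
            models[key] = _fit_subset(subset, config, scaler)
        model, fit_s = models[key]
        t0 = time.perf_counter()
        label, score = knn.predict(model, x)
        predict_s = time.perf_counter() - t0
        records.append(
            PredictionRecord(
                y_true=int(truth), y_pred=label, score=score, country=country,
                fit_s=fit_s, predict_s=predict_s, fold=fold, fallback=fallback,
            )
        )
    return records


def predict_global_baseline(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: KnnConfig = KnnConfig(),
    fold: int = 0,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[PredictionRecord]:
    """Pooled baseline: one K-NN fitted on all training rows."""
    X_test, y_test, _ = knn.encode_features(test)
    model, fit_s = _fit_subset(train, config, scaler)
    records = []
    for country, x, truth in zip(test["country"].to_numpy(), X_test, y_test):
        t0 = time.perf_counter()
        label, score = knn.predict(model, x)
        records.append(
            PredictionRecord(
                y_true=int(truth), y_pred=label, score=score,
                country=str(country), fit_s=fit_s,
                predict_s=time.perf_counter() - t0, fold=fold,
            )
        )
    return records


@dataclass
class SearchSpace:
    """Candidate hyperparameter grid for randomized search."""

    k: tuple[int, ...] = (3, 5, 7, 11)
    weights: tuple[str, ...] = ("uniform", "distance")
    metric: tuple[str, ...] = ("manhattan", "euclidean")
    n_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k and self.weights and self.metric):
            raise ContractError("empty candidate set in search space")
        if self.n_iter < 1:
            raise ContractError("n_iter must be >= 1")

    def sample(self, rng: np.random.Generator) -> KnnConfig:
        return KnnConfig(
            k=int(rng.choice(self.k)),
            weights=str(rng.choice(list(self.weights))),
            metric=str(rng.choice(list(self.metric))),
        )


def random_search(
    data: pd.DataFrame | GladDataset,
    space: SearchSpace,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[KnnConfig, pd.DataFrame]:
    """Uniform-with-replacement sampling of ``n_iter`` configurations, each
    scored by mean stratified-CV accuracy of the country-partitioned model;
    returns the argmax (first encountered on ties) and the score table."""
    df = data.rows if isinstance(data, GladDataset) else data
    rng = np.random.default_rng(space.seed)
    folds = stratified_split(df, n_splits=n_splits, shuffle=True, seed=seed)
    rows = []
    best: tuple[float, KnnConfig] | None = None
    for it in range(space.n_iter):
        config = space.sample(rng)
        accs = []
        for fold_id, (tr, te) in enumerate(folds):
            recs = predict_locustlens(
                df.iloc[tr], df.iloc[te], config, fold=fold_id
            )
            frame = records_frame(recs)
            accs.append(float((frame["y_true"] == frame["y_pred"]).mean()))
        score = float(np.mean(accs))
        rows.append(
            {
                "iteration": it, "k": config.k, "weights": config.weights,
                "metric": config.metric, "cv_accuracy": score,
            }
        )
        if best is None or score > best[0]:
            best = (score, config)
    return best[1], pd.DataFrame(rows)


class LocustLens:
    """Country-partitioned K-NN presence/absence model over a labelled table.

    Parameters
    ----------
    data : GladDataset or DataFrame
        Labelled table in the 8-column schema (7 features + locust_present).
    config : KnnConfig
        Neighbour count, vote weighting and distance metric; the tuned
        defaults are k=7, uniform weights, Manhattan distance.
    n_splits, shuffle, seed
        Stratified cross-validation protocol (default 5-fold, shuffled).
    mode : "partitioned" or "global"
        "global" evaluates the pooled baseline instead.
    paper_faithful_scaling : bool
        Standardize features on the full table before splitting (pre-split
        scaling leaks test statistics into training; off by default).
    """

    def __init__(
        self,
        data: GladDataset | pd.DataFrame,
        config: KnnConfig = KnnConfig(),
        n_splits: int = 5,
        shuffle: bool = True,
        seed: int = 0,
        mode: str = "partitioned",
        paper_faithful_scaling: bool = False,
    ) -> None:
        if mode not in ("partitioned", "global"):
            raise ContractError(f"unknown mode {mode!r}")
        self.data = data.rows if isinstance(data, GladDataset) else data.copy()
        if self.data["locust_present"].nunique() < 2:
            raise ContractError("model needs both presence and absence rows")
        self.config = config
        self.n_splits = n_splits
        self.shuffle = shuffle
        self.seed = seed
        self.mode = mode
        self.paper_faithful_scaling = paper_faithful_scaling

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LocustLens":
        return cls(df, **kwargs)

    def fit(self) -> "LocustLensResults":
        """Run the stratified-CV fit/predict loop and collect records."""
        scaler = None
        if self.paper_faithful_scaling:
            X_all, _, _ = knn.encode_features(self.data)
            scaler = (X_all.mean(axis=0), X_all.std(axis=0))
        folds = stratified_split(
            self.data, n_splits=self.n_splits, shuffle=self.shuffle, seed=self.seed
        )
        predictor = (
            predict_locustlens if self.mode == "partitioned"
            else predict_global_baseline
        )
        records: list[PredictionRecord] = []
        for fold_id, (tr, te) in enumerate(folds):
            records.extend(
                predictor(
                    self.data.iloc[tr], self.data.iloc[te], self.config,
                    fold=fold_id, scaler=scaler,
                )
            )
        return LocustLensResults(self, records)


class LocustLensResults:
    """Cross-validated predictions, metrics and diagnostics."""

    def __init__(self, model: LocustLens, records: list[PredictionRecord]) -> None:
        self.model = model
        self.records = records
        self.frame = records_frame(records)
        self.report: MetricsReport = evaluate(self.frame, per_country=True)

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def per_country(self) -> dict[str, MetricsReport]:
        return self.report.per_country

    def predictions_frame(self, deterministic: bool = True) -> pd.DataFrame:
        """Prediction records as a frame; ``deterministic`` drops wall-clock
        columns so the output reproduces byte-for-byte under a fixed seed."""
        return self.frame[DETERMINISTIC_COLUMNS] if deterministic else self.frame

    def summary(self) -> str:
        r = self.report
        name = (
            "LocustLens (country-partitioned K-NN)"
            if self.model.mode == "partitioned"
            else "Global K-NN baseline"
        )
        cfg = self.model.config
        lines = [
            name,
            "=" * len(name),
            f"rows: {len(self.model.data)}   folds: {self.model.n_splits}   "
            f"seed: {self.model.seed}",
            f"k={cfg.k}  weights={cfg.weights}  metric={cfg.metric}",
            "",
            f"accuracy : {r.accuracy:.4f}",
            f"precision: {r.precision:.4f}",
            f"recall   : {r.recall:.4f}",
            f"F1-score : {r.f1:.4f}",
            f"AUC      : {r.auc:.4f}" if r.auc is not None else "AUC      : n/a",
            f"mean fit time    : {r.mean_fit_s:.6f} s",
            f"mean predict time: {r.mean_predict_s:.6f} s",
            "",
            "per-country accuracy:",
        ]
        for country, rep in sorted(self.per_country.items()):
            auc_txt = f"{rep.auc:.3f}" if rep.auc is not None else "  n/a"
            lines.append(
                f"  {country}: acc={rep.accuracy:.3f}  recall={rep.recall:.3f}"
                f"  AUC={auc_txt}  (n={rep.counts.total})"
            )
        return "\n".join(lines)
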