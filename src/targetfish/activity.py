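"""Class-specific binding-activity regression from Avalon fingerprints.

Activities are modelled in -log M units (pKi/pKd/pIC50) by a random forest
on 512-bit Avalon descriptors.  Model assessment uses repeated *nested*
cross-validation: hyperparameters are selected by an inner CV loop run
strictly inside each outer training fold, so outer test folds never leak
into model selection.  Reported performance is the mean +/- SD of outer-fold
Pearson R and RMSE across repeats; the deployed model is refit on all data
with the most frequently selected hyperparameters.

SVR, gradient-boosted trees and K-nearest-neighbour regressors are available
behind the same interface as comparators; the random forest is the default.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .chem import FingerprintAlgorithm, MoleculeRecord, compute_fingerprints

logger = logging.getLogger(__name__)

AVALON_BITS = 512

#: Default nested-CV shape and random-forest hyperparameter grid.
DEFAULT_GRID = {
    "n_estimators": [100, 300, 500],
    "max_features": ["sqrt", 0.33, 1.0],
}


class MissingModelError(KeyError):
    """No trained activity model exists for the requested target class."""


def featurize_avalon(record: MoleculeRecord, n_bits: int = AVALON_BITS) -> np.ndarray:
    """Avalon fingerprint of one molecule as a 0/1 vector of length n_bits."""
    from rdkit import Chem
    from rdkit.Avalon import pyAvalonTools

    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"{record.id}: unparsable SMILES")
    bv = pyAvalonTools.GetAvalonFP(mol, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


@dataclass
class ActivityDataset:
    """Rows of (molecule id, descriptor bits, activity in -log M)."""

    molecule_ids: list[str]
    X: np.ndarray  # (n, n_bits) uint8
    y: np.ndarray  # (n,) float, -log M
    activity_kinds: list[str]
    class_label: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.molecule_ids) != len(set(self.molecule_ids)):
            raise ValueError("duplicate molecule_id in activity dataset")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need >= 2 distinct activity values for training")

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class NestedCVConfig:
    outer_k: int = 5
    inner_k: int = 3
    repeats: int = 10
    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 0
    algorithm: str = "rf"  # rf | svm | gbt | knn


@dataclass
class FoldOutcome:
    repeat: int
    fold: int
    test_indices: np.ndarray
    chosen_params: dict
    pearson_r: float  # NaN when undefined (zero-variance fold)
    rmse: float


@dataclass
class ModelPerformance:
    """Outer-CV performance aggregated as mean +/- SD over folds and repeats."""

    pearson_r: float
    rmse: float
    r_sd: float
    rmse_sd: float
    n_folds: int
    n_folds_r_undefined: int = 0
    fold_outcomes: list[FoldOutcome] = field(default_factory=list, repr=False)


@dataclass
class TrainedActivityModel:
    class_label: str
    estimator: object
    hyperparameters: dict
    config: NestedCVConfig
    n_training: int


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        return SVR(**params)
    if algorithm == "gbt":
        return GradientBoostingRegressor(random_state=seed, **params)
    if algorithm == "knn":
        return KNeighborsRegressor(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def pearson_r(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) when either side is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        logger.warning("Pearson R undefined: zero variance in predictions or labels")
        return float("nan")
    return float(stats.pearsonr(pred, obs)[0])


def evaluate_predictions(pred, obs) -> ModelPerformance:
    """Pearson R and RMSE of predicted vs observed activities (-log M)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    r = pearson_r(pred, obs)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return ModelPerformance(
        pearson_r=r, rmse=rmse, r_sd=0.0, rmse_sd=0.0, n_folds=1,
        n_folds_r_undefined=int(np.isnan(r)),
    )


def nested_cv_train(
    data: ActivityDataset, config: NestedCVConfig = NestedCVConfig()
) -> tuple[TrainedActivityModel, ModelPerformance]:
    """Train a class-specific activity model with repeated nested CV.

    Outer folds estimate generalisation; the inner GridSearchCV sees only
    the outer training fold, so outer test labels cannot influence
    hyperparameter selection.  Folds whose test labels or predictions have
    zero variance yield an undefined R, which is excluded from the mean with
    a warning (their RMSE still counts).
    """
    if len(data) < config.outer_k:
        raise ValueError("dataset smaller than outer_k")
    if not config.grid:
        raise ValueError("hyperparameter grid must be non-empty")
    outcomes: list[FoldOutcome] = []
    for rep in range(config.repeats):
        outer = KFold(n_splits=config.outer_k, shuffle=True, random_state=config.seed + rep)
        for fold, (train_idx, test_idx) in enumerate(outer.split(data.X)):
            inner = KFold(n_splits=config.inner_k, shuffle=True,
                          random_state=config.seed + 1000 * (rep + 1) + fold)
            search = GridSearchCV(
                _make_estimator(config.algorithm, {}, config.seed),
                param_grid=config.grid,
                cv=inner,
                scoring="neg_mean_squared_error",
                n_jobs=1,
            )
            search.fit(data.X[train_idx], data.y[train_idx])
            best = _make_estimator(config.algorithm, search.best_params_, config.seed)
            best.fit(data.X[train_idx], data.y[train_idx])
            pred = best.predict(data.X[test_idx])
            outcomes.append(
                FoldOutcome(
                    repeat=rep, fold=fold, test_indices=test_idx,
                    chosen_params=dict(search.best_params_),
                    pearson_r=pearson_r(pred, data.y[test_idx]),
                    rmse=float(np.sqrt(np.mean((pred - data.y[test_idx]) ** 2))),
                )
            )
    r_values = np.array([o.pearson_r for o in outcomes])
    rmse_values = np.array([o.rmse for o in outcomes])
    defined = ~np.isnan(r_values)
    performance = ModelPerformance(
        pearson_r=float(np.mean(r_values[defined])) if defined.any() else float("nan"),
        rmse=float(np.mean(rmse_values)),
        r_sd=float(np.std(r_values[defined])) if defined.any() else float("nan"),
        rmse_sd=float(np.std(rmse_values)),
        n_folds=len(outcomes),
        n_folds_r_undefined=int((~defined).sum()),
        fold_outcomes=outcomes,
    )
    # deploy: refit on all data with the modal hyperparameter choice
    modal_params = Counter(
        tuple(sorted(o.chosen_params.items())) for o in outcomes
    ).most_common(1)[0][0]
    final_params = dict(modal_params)
    final = _make_estimator(config.algorithm, final_params, config.seed)
    final.fit(data.X, data.y)
    model = TrainedActivityModel(
        class_label=data.class_label, estimator=final,
        hyperparameters=final_params, config=config, n_training=len(data),
    )
    return model, performance


def predict_activity(model: TrainedActivityModel, record: MoleculeRecord) -> float:
    """Predicted binding activity (-log M) for one molecule."""
    x = featurize_avalon(record)
    value = float(model.estimator.predict(x.reshape(1, -1))[0])
    if not np.isfinite(value):
        raise ValueError(f"non-finite activity prediction for {record.id}")
    return value


def dataset_from_records(
    records: list[MoleculeRecord],
    activities: list[float],
    class_label: str,
    activity_kinds: list[str] | None = None,
) -> ActivityDataset:
    """Featurize molecules with Avalon bits into an ActivityDataset."""
    X = np.stack([featurize_avalon(r) for r in records])
    return ActivityDataset(
        molecule_ids=[r.id for r in records],
        X=X,
        y=np.asarray(activities, dtype=float),
        activity_kinds=activity_kinds or ["Ki"] * len(records),
        class_label=class_label,
    )


def save_model(model: TrainedActivityModel, path: str | Path) -> None:
    path = Path(path)
    joblib.dump(model.estimator, path)
    meta = {
        "class_label": model.class_label,
        "hyperparameters": model.hyperparameters,
        "n_training": model.n_training,
        "algorithm": model.config.algorithm,
        "seed": model.config.seed,
        "grid": {k: list(v) for k, v in model.config.grid.items()},
        "outer_k": model.config.outer_k,
        "inner_k": model.config.inner_k,
        "repeats": model.config.repeats,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_model(path: str | Path) -> TrainedActivityModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    estimator = joblib.load(path)
    config = NestedCVConfig(
        outer_k=meta["outer_k"], inner_k=meta["inner_k"], repeats=meta["repeats"],
        grid=meta["grid"], seed=meta["seed"], algorithm=meta["algorithm"],
    )
    return TrainedActivityModel(
        class_label=meta["class_label"], estimator=estimator,
        hyperparameters=meta["hyperparameters"], config=config,
        n_training=meta["n_training"],
    )
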