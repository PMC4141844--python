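"""Probability-output kernel classifiers, the two-level stacked predictor,
and the difficulty-tier mapping.

Level-1 models are per-task SVMs (POLY/RBF/SIG kernels, probability
calibrated) trained on each task's selected feature subset.  Level-2 models
take the 5-vector of level-1 probabilities as input; their training
meta-features are produced out-of-fold so no row is scored by a model that
saw it.  The final crystallizability probability maps to one of five
difficulty tiers with cutoffs 0.6 / 0.55 / 0.45 / 0.2.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from crysprop.evaluate import auc as _auc
from crysprop.seqio import FeatureTable

TASKS = ("CLF", "MF", "PF", "CF", "CRYS")

_KERNEL_MAP = {"POLY": "poly", "RBF": "rbf", "SIG": "sigmoid"}

# SVC(probability=True) is the Platt-scaled probability machinery this module
# is built around; scikit-learn 1.9 deprecates the flag in favour of an
# external calibration wrapper.  Pin the current behaviour quietly.
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)


class MLError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SVMConfig:
    kernel: str = "RBF"
    C: float = 1.0
    gamma: float | str = "scale"
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_MAP:
            raise MLError(f"kernel must be one of {sorted(_KERNEL_MAP)}")
        if self.C <= 0:
            raise MLError("C must be positive")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise MLError("gamma must be positive")


def _make_pipeline(config: SVMConfig, probability: bool) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=_KERNEL_MAP[config.kernel],
                    C=config.C,
                    gamma=config.gamma,
                    # inhomogeneous polynomial / shifted sigmoid: keeps the
                    # linear term so low-degree kernels cannot flip sign
                    coef0=1.0 if config.kernel in ("POLY", "SIG") else 0.0,
                    probability=probability,
                    random_state=config.seed,
                ),
            ),
        ]
    )


@dataclasses.dataclass
class TrainedModel:
    """A fitted probability classifier plus its provenance."""

    pipeline: Pipeline
    config: SVMConfig
    feature_ids: tuple[str, ...]
    fingerprint: str

    def predict_proba(self, X: np.ndarray | FeatureTable) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.subset(list(self.feature_ids)).values
        X = np.asarray(X, dtype=float)
        proba = self.pipeline.predict_proba(X)
        positive = list(self.pipeline.classes_).index(1)
        return proba[:, positive]


def _fingerprint(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=int).tobytes())
    h.update(repr(config).encode())
    return h.hexdigest()[:16]


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a probability-calibrated SVM (features standardized inside the
    model with training statistics)."""
    config = config or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise MLError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise MLError("training features must be finite")
    pipeline = _make_pipeline(config, probability=True)
    pipeline.fit(X, y)
    return TrainedModel(
        pipeline=pipeline,
        config=config,
        feature_ids=tuple(feature_ids) if feature_ids is not None else tuple(
            f"f{i}" for i in range(X.shape[1])
        ),
        fingerprint=_fingerprint(X, y, config),
    )


def cv_auc_score(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold AUC using the SVM decision function (rank
    equivalent to the calibrated probability, much cheaper to fit)."""
    config = config or SVMConfig(seed=seed)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        try:
            pipe = _make_pipeline(config, probability=False)
            pipe.fit(X[train_idx], y[train_idx])
            scores = pipe.decision_function(X[test_idx])
            aucs.append(_auc(scores, y[test_idx]))
        except Exception as exc:
            raise MLError(f"cross-validation failed in fold {fold_no}: {exc}") from exc
    return float(np.mean(aucs))


@dataclasses.dataclass(frozen=True)
class GridSearchResult:
    best: SVMConfig
    table: tuple[tuple[str, float, float, float], ...]  # kernel, C, gamma, CV AUC


DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    kernels: Sequence[str] = ("POLY", "RBF", "SIG"),
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (kernel, C, gamma) search by mean 5-fold CV AUC; ties keep
    the first grid point."""
    if not kernels or not c_grid or not gamma_grid:
        raise MLError("grid must be non-empty")
    rows = []
    best: tuple[float, SVMConfig] | None = None
    for kernel in kernels:
        for C in c_grid:
            for gamma in gamma_grid:
                config = SVMConfig(kernel=kernel, C=C, gamma=gamma, folds=folds, seed=seed)
                score = cv_auc_score(X, y, config, folds=folds, seed=seed)
                rows.append((kernel, float(C), float(gamma), score))
                if best is None or score > best[0]:
                    best = (score, config)
    return GridSearchResult(best=best[1], table=tuple(rows))


# --- two-level stacking ----------------------------------------------------

def train_level1(
    datasets: Mapping[str, tuple[np.ndarray, np.ndarray]],
    feature_ids: Mapping[str, Sequence[str]] | None = None,
    config: SVMConfig | None = None,
) -> dict[str, TrainedModel]:
    """One calibrated first-level model per task (keys CLF/MF/PF/CF/CRYS)."""
    missing = [t for t in TASKS if t not in datasets]
    if missing:
        raise MLError(f"missing task dataset(s): {', '.join(missing)}")
    models = {}
    for task in TASKS:
        X, y = datasets[task]
        ids = feature_ids[task] if feature_ids is not None else None
        models[task] = train_classifier(X, y, config, ids)
    return models


def stack_meta_features(
    level1: Mapping[str, TrainedModel] | None,
    table: FeatureTable | np.ndarray,
    mode: str = "direct",
    y_by_task: Mapping[str, np.ndarray] | None = None,
    config: SVMConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """The (n, 5) matrix of level-1 probabilities, one column per task.

    ``direct`` mode scores with the trained level-1 models (inference).
    ``oof`` mode (training) refits each task's model per stratified fold so
    every row's meta-features come from models that never saw that row; it
    requires per-task labels and, for a FeatureTable input, per-task
    feature subsets taken from ``level1``.
    """
    if mode == "direct":
        if level1 is None:
            raise MLError("direct mode requires trained level-1 models")
        cols = [level1[task].predict_proba(table) for task in TASKS]
        return np.column_stack(cols)
    if mode != "oof":
        raise MLError(f"unknown stacking mode {mode!r}")
    if y_by_task is None:
        raise MLError("oof mode requires per-task labels (fold assignments)")
    meta_cols = []
    for task in TASKS:
        y = np.asarray(y_by_task[task], dtype=int)
        if isinstance(table, FeatureTable):
            if level1 is None:
                raise MLError("oof mode on a FeatureTable requires level-1 models "
                              "to supply per-task feature subsets")
            X = table.subset(list(level1[task].feature_ids)).values
        else:
            X = np.asarray(table, dtype=float)
        oof = np.empty(X.shape[0])
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(X, y):
            model = train_classifier(X[train_idx], y[train_idx], config)
            oof[test_idx] = model.predict_proba(X[test_idx])
        meta_cols.append(oof)
    return np.column_stack(meta_cols)


META_FEATURE_IDS = tuple(f"level1_prob::{t}" for t in TASKS)


def train_level2(
    meta: np.ndarray,
    y_by_task: Mapping[str, np.ndarray],
    config: SVMConfig | None = None,
) -> dict[str, TrainedModel]:
    """One second-level model per task on the 5-dim meta input."""
    meta = np.asarray(meta, dtype=float)
    if meta.shape[1] != len(TASKS):
        raise MLError(f"meta table must have {len(TASKS)} columns")
    return {
        task: train_classifier(meta, y_by_task[task], config, META_FEATURE_IDS)
        for task in TASKS
    }


@dataclasses.dataclass
class StackedModel:
    """Five level-1 models, five level-2 models, and provenance."""

    level1: dict[str, TrainedModel]
    level2: dict[str, TrainedModel]
    registry_fingerprint: str
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping in (self.level1, self.level2):
            missing = [t for t in TASKS if t not in mapping]
            if missing:
                raise MLError(f"stacked model missing task(s): {', '.join(missing)}")

    def predict_level1(self, table: FeatureTable) -> np.ndarray:
        return stack_meta_features(self.level1, table, mode="direct")

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """(n, 5) level-2 probabilities in task order CLF/MF/PF/CF/CRYS."""
        meta = self.predict_level1(table)
        return np.column_stack(
            [self.level2[task].predict_proba(meta) for task in TASKS]
        )

    def predict_report(self, table: FeatureTable):
        import pandas as pd

        probs = self.predict_proba(table)
        df = pd.DataFrame(probs, index=table.row_ids, columns=TASKS)
        df["tier"] = [classify_difficulty(p).value for p in df["CRYS"]]
        df.index.name = "protein_id"
        return df


#: smooth near-linear combiner for the 5-dim probability meta-input
DEFAULT_LEVEL2_CONFIG = SVMConfig(kernel="POLY", C=1.0, gamma=0.1)


def stacking_experiment(
    spec=None,
    seed: int = 0,
    level1_config: SVMConfig | None = None,
    level2_config: SVMConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Measure whether second-level stacking improves on first-level
    predictors under planted study conditions.

    Emulates the production setting in which each task's first-level model
    is trained on its own corpus: rows are partitioned into five disjoint
    level-1 training sets (one per task), a stacking set, and a test set.
    Level-1 models are fitted per task on their partition; the stacking
    set trains each task's level-2 model on the 5-vector of level-1
    probabilities; both levels are scored on the untouched test set.  No
    model ever scores a row it was trained on.  When the tasks share
    signal (rho > 0) the five level-1 outputs are complementary estimates
    of the shared component and the level-2 combination is expected to
    win; with independent tasks (rho = 0) it should merely match level-1.

    Returns (level-1 AUCs, level-2 AUCs), one entry per task.
    """
    from crysprop.datasets import SyntheticSpec, simulate_planted

    if spec is None:
        spec = SyntheticSpec(n=2000, p=60, k=10, delta=0.5, rho=0.8, seed=seed)
    level1_config = level1_config or SVMConfig(seed=seed)
    level2_config = level2_config or dataclasses.replace(DEFAULT_LEVEL2_CONFIG, seed=seed)
    table, labels, _truth = simulate_planted(spec)
    X = table.values
    rng = np.random.default_rng(seed + 20011)
    perm = rng.permutation(spec.n)
    n_l1 = (spec.n // 2) // len(TASKS)
    parts = [perm[i * n_l1 : (i + 1) * n_l1] for i in range(len(TASKS))]
    rest = perm[len(TASKS) * n_l1 :]
    stack_idx = rest[: len(rest) // 2]
    test_idx = rest[len(rest) // 2 :]
    level1 = {
        task: train_classifier(X[part], labels[task][part], level1_config)
        for task, part in zip(TASKS, parts)
    }
    meta_stack = np.column_stack(
        [level1[t].predict_proba(X[stack_idx]) for t in TASKS]
    )
    meta_test = np.column_stack(
        [level1[t].predict_proba(X[test_idx]) for t in TASKS]
    )
    l1_aucs, l2_aucs = [], []
    for i, task in enumerate(TASKS):
        m2 = train_classifier(meta_stack, labels[task][stack_idx], level2_config)
        l1_aucs.append(_auc(meta_test[:, i], labels[task][test_idx]))
        l2_aucs.append(_auc(m2.predict_proba(meta_test), labels[task][test_idx]))
    return np.array(l1_aucs), np.array(l2_aucs)


# --- difficulty tiers ------------------------------------------------------

class DifficultyTier(enum.Enum):
    OPTIMAL = "Optimal"
    SUBOPTIMAL = "Suboptimal"
    AVERAGE = "Average"
    DIFFICULT = "Difficult"
    VERY_DIFFICULT = "Very difficult"


TIER_CUTOFFS = (0.6, 0.55, 0.45, 0.2)


def classify_difficulty(score: float) -> DifficultyTier:
    """Map a crystallizability probability to its difficulty tier:
    >=0.6 Optimal, [0.55,0.6) Suboptimal, [0.45,0.55) Average,
    [0.2,0.45) Difficult, <0.2 Very difficult."""
    if not (0.0 <= score <= 1.0):
        raise MLError(f"probability score {score} outside [0, 1]")
    if score >= 0.6:
        return DifficultyTier.OPTIMAL
    if score >= 0.55:
        return DifficultyTier.SUBOPTIMAL
    if score >= 0.45:
        return DifficultyTier.AVERAGE
    if score >= 0.2:
        return DifficultyTier.DIFFICULT
    return DifficultyTier.VERY_DIFFICULT
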