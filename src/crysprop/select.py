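"""Feature ranking and selection: mutual information, mRMR (one-step and
two-step), and the IFS/FFS wrapper stages scored by cross-validated AUC.

mRMR uses the difference criterion (relevance minus mean redundancy) with
plug-in mutual information (log base 2) on discretized features.
Discretization is equal-frequency terciles; a feature with three or fewer
distinct values keeps those values as its categories, which makes a binary
feature score as itself and a constant feature carry zero information.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from crysprop.features import AAINDEX_BLOCK_IDS, FeatureRegistry
from crysprop.seqio import FeatureTable


class SelectionError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MRMRConfig:
    k_one_step: int = 300
    k_first_step_per_block: int = 100
    k_second_step: int = 300


@dataclasses.dataclass(frozen=True)
class RankedFeatures:
    feature_ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise SelectionError("ranked feature ids are not unique")


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    trajectory: tuple[tuple[int, float], ...]  # (subset size, CV AUC)
    best_auc: float
    stopping_round: int


# --- discretization and mutual information ---------------------------------

def discretize_terciles(x: np.ndarray) -> np.ndarray:
    """Equal-frequency tercile codes (ties broken by value then index);
    features with <= 3 distinct values keep their values as categories."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= 3:
        return np.searchsorted(uniq, x).astype(np.int8)
    order = np.argsort(x, kind="stable")
    codes = np.empty(x.shape[0], dtype=np.int8)
    for bin_no, idx in enumerate(np.array_split(order, 3)):
        codes[idx] = bin_no
    return codes


def _plugin_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) of two small-cardinality integer code vectors."""
    n = a.shape[0]
    la, lb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.zeros((la, lb))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float((joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI (bits) between a real feature and discrete labels after tercile
    discretization of the feature; always >= 0 (0 for a constant)."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape[0] != y.shape[0] or x.shape[0] < 3:
        raise SelectionError("mutual_information needs matched vectors of length >= 3")
    _, y_codes = np.unique(y, return_inverse=True)
    return max(0.0, _plugin_mi(discretize_terciles(x), y_codes.astype(np.int8)))


class _CodedTable:
    """Tercile codes plus per-level one-hot matrices for fast pairwise MI."""

    def __init__(self, values: np.ndarray):
        n, p = values.shape
        self.n = n
        self.codes = np.empty((n, p), dtype=np.int8)
        for j in range(p):
            self.codes[:, j] = discretize_terciles(values[:, j])
        self.n_levels = int(self.codes.max()) + 1 if p else 1
        # onehot[l] has shape (n, p): column j marks rows where code == l
        self.onehot = [
            (self.codes == l).astype(np.float64) for l in range(self.n_levels)
        ]

    def mi_against(self, codes_a: np.ndarray) -> np.ndarray:
        """MI (bits) of one discrete vector against every column."""
        n = self.n
        la = int(codes_a.max()) + 1
        counts = np.zeros((la, self.n_levels, self.codes.shape[1]))
        for a_level in range(la):
            mask = (codes_a == a_level).astype(np.float64)
            for b_level in range(self.n_levels):
                counts[a_level, b_level] = mask @ self.onehot[b_level]
        joint = counts / n
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log2(joint / (pa * pb))
        return np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(0, 1))


# --- mRMR -------------------------------------------------------------------

def mrmr_rank(table: FeatureTable, y: np.ndarray, k: int) -> RankedFeatures:
    """Greedy mRMR (difference criterion): the first feature maximizes
    relevance I(f;y); each next feature maximizes relevance minus mean MI
    with the already-selected set.  Scores are compared at 1e-12 resolution
    so mathematically tied features break to the earlier (registry) column
    regardless of floating-point summation order."""
    if k <= 0:
        raise SelectionError("k must be positive")
    p = len(table.feature_ids)
    if k > p:
        raise SelectionError(f"k={k} exceeds the {p} available features")
    coded = _CodedTable(table.values)
    _, y_codes = np.unique(np.asarray(y), return_inverse=True)
    relevance = coded.mi_against(y_codes.astype(np.int8))

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for _ in range(k):
        if selected:
            score = relevance - redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        best = int(np.argmax(np.round(score, 12)))  # first maximum wins ties
        selected.append(best)
        scores.append(float(score[best]))
        available[best] = False
        redundancy_sum += coded.mi_against(coded.codes[:, best])
    return RankedFeatures(
        feature_ids=tuple(table.feature_ids[i] for i in selected),
        scores=tuple(scores),
    )


def one_step_select(
    table: FeatureTable,
    y: np.ndarray,
    registry: FeatureRegistry,
    config: MRMRConfig | None = None,
) -> RankedFeatures:
    """Single mRMR pass over the full candidate registry (top 300)."""
    config = config or MRMRConfig()
    if list(table.feature_ids) != registry.feature_ids:
        raise SelectionError("feature table columns do not match the registry")
    return mrmr_rank(table, y, config.k_one_step)


def two_step_select(
    table: FeatureTable,
    y: np.ndarray,
    registry: FeatureRegistry,
    config: MRMRConfig | None = None,
) -> RankedFeatures:
    """Two-step mRMR: 100 features from each of the three AAindex blocks
    (pool of 300), then a second mRMR pass over that pool plus the 1,292
    non-AAindex features (1,592 candidates), keeping the top 300."""
    config = config or MRMRConfig()
    if list(table.feature_ids) != registry.feature_ids:
        raise SelectionError("feature table columns do not match the registry")
    pool: list[str] = []
    for block_id in AAINDEX_BLOCK_IDS:
        block_ids = list(registry.block_feature_ids(block_id))
        ranked = mrmr_rank(table.subset(block_ids), y, config.k_first_step_per_block)
        pool.extend(ranked.feature_ids)
    aaindex_ids = {
        fid for b in AAINDEX_BLOCK_IDS for fid in registry.block_feature_ids(b)
    }
    non_aaindex = [f for f in registry.feature_ids if f not in aaindex_ids]
    candidate_set = set(pool) | set(non_aaindex)
    candidates = [f for f in registry.feature_ids if f in candidate_set]
    return mrmr_rank(table.subset(candidates), y, config.k_second_step)


# --- wrapper stages ---------------------------------------------------------

CVScorer = Callable[[np.ndarray, np.ndarray], float]


def _default_cv_scorer(folds: int = 5, seed: int = 0) -> CVScorer:
    from crysprop.mlcore import cv_auc_score

    return lambda X, y: cv_auc_score(X, y, folds=folds, seed=seed)


def ifs(
    table: FeatureTable,
    y: np.ndarray,
    ranked: RankedFeatures,
    cv_scorer: CVScorer | None = None,
    max_features: int | None = None,
) -> SelectionResult:
    """Incremental feature selection: evaluate ranked prefixes by CV AUC and
    keep the prefix with the maximal AUC (smallest prefix on ties)."""
    if not ranked.feature_ids:
        raise SelectionError("ranking is empty")
    cv_scorer = cv_scorer or _default_cv_scorer()
    sub = table.subset(list(ranked.feature_ids))
    y = np.asarray(y)
    limit = len(ranked.feature_ids) if max_features is None else min(
        max_features, len(ranked.feature_ids)
    )
    trajectory: list[tuple[int, float]] = []
    for m in range(1, limit + 1):
        auc = cv_scorer(sub.values[:, :m], y)
        trajectory.append((m, auc))
    best_m, best_auc = max(trajectory, key=lambda t: (t[1], -t[0]))
    return SelectionResult(
        selected=ranked.feature_ids[:best_m],
        trajectory=tuple(trajectory),
        best_auc=best_auc,
        stopping_round=best_m,
    )


def ffs(
    table: FeatureTable,
    y: np.ndarray,
    candidates: Sequence[str],
    cv_scorer: CVScorer | None = None,
    tolerance: float = 1e-4,
    max_features: int | None = None,
) -> SelectionResult:
    """Forward feature selection: each round adds the single candidate whose
    inclusion maximizes CV AUC; stops when the best addition improves the
    AUC by no more than ``tolerance``."""
    if not candidates:
        raise SelectionError("candidate set is empty")
    cv_scorer = cv_scorer or _default_cv_scorer()
    y = np.asarray(y)
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    remaining = list(candidates)
    chosen: list[str] = []
    chosen_cols: list[int] = []
    best_auc = -np.inf
    trajectory: list[tuple[int, float]] = []
    limit = len(candidates) if max_features is None else max_features
    while remaining and len(chosen) < limit:
        round_best: tuple[float, str] | None = None
        for f in remaining:
            X = table.values[:, chosen_cols + [pos[f]]]
            auc = cv_scorer(X, y)
            if round_best is None or auc > round_best[0]:
                round_best = (auc, f)
        auc, f = round_best
        if chosen and auc <= best_auc + tolerance:
            break
        if not chosen and auc <= tolerance:  # all-noise guard: still accept round 1
            pass
        chosen.append(f)
        chosen_cols.append(pos[f])
        remaining.remove(f)
        best_auc = auc
        trajectory.append((len(chosen), auc))
    return SelectionResult(
        selected=tuple(chosen),
        trajectory=tuple(trajectory),
        best_auc=float(best_auc),
        stopping_round=len(chosen),
    )
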