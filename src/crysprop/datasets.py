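"""Dataset construction from experimental status records, and the
synthetic generators used throughout testing and calibration.

The five-step pipeline classes are CLF (cloning failure), MF (material
production failure), PF (purification failure), CF (crystallization
failure) and CRYS (crystallizable).  A target's class comes from its most
advanced in-window X-ray trial status; per-task positive/negative label
compositions follow the one-versus-rest-with-exclusions scheme documented
in :data:`TASK_COMPOSITION`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from crysprop.seqio import FeatureTable, ProteinRecord, StatusRecord

TASKS = ("CLF", "MF", "PF", "CF", "CRYS")


class DatasetError(ValueError):
    pass


# --- status vocabulary ------------------------------------------------------

#: advancement order of stop statuses; later = more advanced
STATUS_PRECEDENCE = (
    "selected",
    "cloned",
    "expressed",
    "soluble",
    "purified",
    "purification failed",
    "crystallization failed",
    "crystallized",
    "poor diffraction",
    "diffraction",
    "crystal structure",
    "structure successful",
    "in pdb",
)

CLASS_OF_STATUS = {
    "selected": "CLF",
    "cloned": "MF",
    "expressed": "MF",
    "soluble": "PF",
    "purified": "PF",
    "purification failed": "PF",
    "crystallization failed": "CF",
    "poor diffraction": "CF",
    "crystallized": "CF",
    "diffraction": "CF",
    "crystal structure": "CRYS",
    "structure successful": "CRYS",
    "in pdb": "CRYS",
}

#: the nine X-ray statuses used by the record simulator
XRAY_STATUSES = (
    "selected", "cloned", "expressed", "soluble", "purified",
    "crystallized", "diffraction", "crystal structure", "in PDB",
)


def _norm(s: str) -> str:
    return " ".join(s.strip().lower().split())


def status_rank(status: str) -> int:
    try:
        return STATUS_PRECEDENCE.index(_norm(status))
    except ValueError:
        raise DatasetError(
            f"unknown status {status!r}; known: {', '.join(STATUS_PRECEDENCE)}"
        ) from None


def assign_class(status: str) -> str:
    """Map a final stop status to its pipeline class (CLF/MF/PF/CF/CRYS)."""
    cls = CLASS_OF_STATUS.get(_norm(status))
    if cls is None:
        raise DatasetError(
            f"unknown status {status!r}; known: {', '.join(sorted(CLASS_OF_STATUS))}"
        )
    return cls


# --- trial filtering --------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FilterCriteria:
    window_start: _dt.date = _dt.date(2006, 1, 1)
    window_end: _dt.date = _dt.date(2010, 12, 31)
    stop_conditions: frozenset = frozenset({"current status: work stopped", "work stopped"})
    stop_statuses: frozenset = frozenset({"in pdb", "crystal structure"})
    method: str = "x-ray"

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise DatasetError("filter window start must precede end")


def filter_trials(
    records: Iterable[StatusRecord], criteria: FilterCriteria | None = None
) -> list[StatusRecord]:
    """Apply the four inclusion criteria in order: authentic-stop whitelist,
    date window, X-ray method, then collapse each target to its most
    advanced status keeping the latest trial among equal statuses."""
    criteria = criteria or FilterCriteria()
    kept = [
        r
        for r in records
        if (
            _norm(r.stop_condition) in criteria.stop_conditions
            or _norm(r.status) in criteria.stop_statuses
        )
        and criteria.window_start <= r.stop_date <= criteria.window_end
        and _norm(r.method).startswith(criteria.method)
    ]
    by_target: dict[str, list[StatusRecord]] = {}
    for r in kept:
        by_target.setdefault(r.target_id, []).append(r)
    final = []
    for target_id in by_target:
        trials = by_target[target_id]
        top = max(status_rank(r.status) for r in trials)
        best = [r for r in trials if status_rank(r.status) == top]
        final.append(max(best, key=lambda r: r.stop_date))
    return final


# --- task datasets ----------------------------------------------------------

#: per-task (negative classes, positive classes); remaining classes excluded
TASK_COMPOSITION: dict[str, tuple[frozenset, frozenset]] = {
    "CLF": (frozenset({"CLF"}), frozenset({"MF", "PF", "CF", "CRYS"})),
    "MF": (frozenset({"CLF", "MF"}), frozenset({"PF", "CF", "CRYS"})),
    "PF": (frozenset({"PF"}), frozenset({"CF", "CRYS"})),
    "CF": (frozenset({"CF"}), frozenset({"CRYS"})),
    "CRYS": (frozenset({"CLF", "MF", "PF", "CF"}), frozenset({"CRYS"})),
}


@dataclasses.dataclass
class LabeledDataset:
    """Binary-labelled rows of one prediction task."""

    task: str
    row_ids: list[str]
    labels: np.ndarray
    excluded_ids: list[str]
    provenance: dict[str, str]  # row id -> pipeline class
    features: FeatureTable | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.row_ids) != len(self.labels):
            raise DatasetError("labels do not match rows")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise DatasetError("duplicate row ids")
        if set(np.unique(self.labels)) != {0, 1}:
            raise DatasetError(f"{self.task}: both label classes must be present")


def build_task_dataset(
    target_classes: Mapping[str, str],
    task: str,
    features: FeatureTable | None = None,
) -> LabeledDataset:
    """Assemble one task's labelled rows from per-target classes.

    Negative/positive compositions follow :data:`TASK_COMPOSITION`;
    targets in neither set are excluded (e.g. CLF and MF targets never
    enter the purification task, which conditions on reaching that step).
    """
    if task not in TASK_COMPOSITION:
        raise DatasetError(f"unknown task {task!r}")
    neg_classes, pos_classes = TASK_COMPOSITION[task]
    row_ids, labels, excluded = [], [], []
    for target_id, cls in target_classes.items():
        if cls in pos_classes:
            row_ids.append(target_id)
            labels.append(1)
        elif cls in neg_classes:
            row_ids.append(target_id)
            labels.append(0)
        else:
            excluded.append(target_id)
    sub_features = None
    if features is not None:
        sub = {rid for rid in row_ids}
        idx = [i for i, rid in enumerate(features.row_ids) if rid in sub]
        sub_features = FeatureTable(
            row_ids=[features.row_ids[i] for i in idx],
            feature_ids=list(features.feature_ids),
            values=features.values[idx],
        )
    return LabeledDataset(
        task=task,
        row_ids=row_ids,
        labels=np.array(labels),
        excluded_ids=excluded,
        provenance={rid: target_classes[rid] for rid in row_ids},
        features=sub_features,
    )


def classes_from_records(records: Iterable[StatusRecord]) -> dict[str, str]:
    """filter_trials output -> per-target class map."""
    return {r.target_id: assign_class(r.status) for r in records}


# --- sequence redundancy ----------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global pairwise identity: matches / alignment length."""
    aligner = aligner or _aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def reduce_redundancy(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.4
) -> list[ProteinRecord]:
    """Greedy incremental clustering, longest sequence first; a sequence
    joins the first cluster whose representative it matches at or above the
    threshold, otherwise founds its own.  Returns the representatives
    (each cluster's longest member)."""
    if not 0.0 < identity_threshold <= 1.0:
        raise DatasetError("identity threshold must be in (0, 1]")
    aligner = _aligner()
    ordered = sorted(records, key=lambda r: -r.n)
    representatives: list[ProteinRecord] = []
    for rec in ordered:
        if any(
            pairwise_identity(rec.sequence, rep.sequence, aligner) >= identity_threshold
            for rep in representatives
        ):
            continue
        representatives.append(rec)
    return representatives


# --- train/test splitting ---------------------------------------------------

def split_train_test(
    dataset: LabeledDataset,
    seed: int,
    n_subsets: int = 6,
    cross_identity_threshold: float | None = None,
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Stratified random partition into ``n_subsets`` near-equal subsets;
    one subset is the independent test set, the rest the training set.
    With ``cross_identity_threshold`` set (e.g. 0.25) and sequences given,
    test rows too similar to any training row are dropped."""
    if len(dataset.row_ids) < n_subsets:
        raise DatasetError(f"need at least {n_subsets} rows to split")
    rng = np.random.default_rng(seed)
    subsets: list[list[str]] = [[] for _ in range(n_subsets)]
    for label in (0, 1):
        ids = [r for r, l in zip(dataset.row_ids, dataset.labels) if l == label]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for i, rid in enumerate(ids):
            subsets[i % n_subsets].append(rid)
    test_ids = subsets[0]
    train_ids = [rid for s in subsets[1:] for rid in s]
    if cross_identity_threshold is not None:
        if sequences is None:
            raise DatasetError("cross-set identity filter requires sequences")
        aligner = _aligner()
        test_ids = [
            t
            for t in test_ids
            if all(
                pairwise_identity(sequences[t], sequences[tr], aligner)
                < cross_identity_threshold
                for tr in train_ids
            )
        ]
    return train_ids, test_ids


# --- synthetic generators ---------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic benchmark."""

    n: int = 600
    length_range: tuple[int, int] = (50, 300)
    p: int = 200
    k: int = 10
    delta: float = 1.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.p:
            raise DatasetError("k informative features cannot exceed p")
        if self.delta < 0 or not 0.0 <= self.rho <= 1.0:
            raise DatasetError("delta must be >= 0 and rho in [0, 1]")


def simulate_sequences(
    spec: SyntheticSpec, residue_probs: Sequence[float] | None = None
) -> list[ProteinRecord]:
    """i.i.d. random protein sequences with uniform lengths in the spec's
    range and the given residue composition (uniform by default)."""
    from crysprop.data.scales import AA20

    rng = np.random.default_rng(spec.seed)
    probs = np.full(20, 0.05) if residue_probs is None else np.asarray(residue_probs)
    probs = probs / probs.sum()
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA20), size=length, p=probs))
        records.append(ProteinRecord(id=f"syn{i + 1:05d}", sequence=seq))
    return records


def simulate_status_records(
    n_targets: int,
    class_mixture: Mapping[str, float],
    seed: int = 0,
) -> tuple[list[StatusRecord], dict[str, str]]:
    """Status-record tables with planted per-target classes.

    Each target gets one final in-window X-ray trial whose status maps to
    its planted class, up to three less-advanced earlier trials, and decoy
    trials that the filters must remove (pre-window dates, non-X-ray
    methods, work still in progress).  Returns (records, truth)."""
    if abs(sum(class_mixture.values()) - 1.0) > 1e-9:
        raise DatasetError("class mixture must sum to 1")
    rng = np.random.default_rng(seed)
    final_status_of = {
        "CLF": ["selected"],
        "MF": ["cloned", "expressed"],
        "PF": ["soluble", "purified"],
        "CF": ["crystallized", "diffraction"],
        "CRYS": ["crystal structure", "in PDB"],
    }
    classes = list(class_mixture)
    probs = np.array([class_mixture[c] for c in classes])
    records: list[StatusRecord] = []
    truth: dict[str, str] = {}

    def in_window_date() -> _dt.date:
        return _dt.date(2006, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 1826)))

    for i in range(n_targets):
        target_id = f"tgt{i + 1:05d}"
        cls = classes[int(rng.choice(len(classes), p=probs))]
        truth[target_id] = cls
        final_status = final_status_of[cls][int(rng.integers(len(final_status_of[cls])))]
        final_date = in_window_date()
        trial_no = 0

        def add(status, date, method="X-ray", stop="current status: work stopped"):
            nonlocal trial_no
            trial_no += 1
            records.append(
                StatusRecord(
                    target_id=target_id,
                    trial_id=f"{target_id}.t{trial_no}",
                    status=status,
                    stop_date=date,
                    method=method,
                    stop_condition=stop,
                )
            )

        add(final_status, final_date)
        final_rank = status_rank(final_status)
        for _ in range(int(rng.integers(0, 3))):
            earlier = [s for s in XRAY_STATUSES if status_rank(s) < final_rank]
            if not earlier:
                break
            status = earlier[int(rng.integers(len(earlier)))]
            add(status, final_date - _dt.timedelta(days=int(rng.integers(1, 400))))
        # decoys the filters must remove
        if rng.random() < 0.5:
            add(
                XRAY_STATUSES[int(rng.integers(len(XRAY_STATUSES)))],
                _dt.date(2005, 6, 1),
            )
        if rng.random() < 0.5:
            add(
                XRAY_STATUSES[int(rng.integers(len(XRAY_STATUSES)))],
                in_window_date(),
                method="NMR",
            )
        if rng.random() < 0.3:
            # in-progress trials never carry a terminal status, which would
            # pass the authentic-stop whitelist on its own
            open_statuses = XRAY_STATUSES[:7]
            add(
                open_statuses[int(rng.integers(len(open_statuses)))],
                in_window_date(),
                stop="work in progress",
            )
    return records, truth


def simulate_planted(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, dict[str, np.ndarray], dict[str, tuple[str, ...]]]:
    """Feature table with planted informative features for all five tasks.

    p standard-normal features; a shared latent factor per protein realized
    as the normalized sum of a dedicated latent feature subset (so the
    inter-task correlation it induces is predictable from the features, the
    way shared crystallizability signal is); each task draws k informative
    features from the remaining columns.  Labels follow a logistic model
    whose signal mixes the shared and task-private components by variance:

        logit_t = delta * sqrt(k) * (sqrt(rho) * z + sqrt(1 - rho) * s_t)

    with s_t the task's normalized private sum, so rho is exactly the
    fraction of signal variance shared between tasks (and the correlation
    of any two task signals).  At rho = 0 this reduces to independent
    logistic models with per-feature effect delta.  Returns (table, labels
    by task, ground truth with per-task informative ids and the shared
    "latent" ids)."""
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    feature_ids = [f"f{j + 1:04d}" for j in range(spec.p)]
    row_ids = [f"p{i + 1:05d}" for i in range(spec.n)]
    latent_idx = rng.choice(spec.p, size=spec.k, replace=False)
    z = X[:, latent_idx].sum(axis=1) / np.sqrt(spec.k)
    non_latent = np.setdiff1d(np.arange(spec.p), latent_idx)
    labels: dict[str, np.ndarray] = {}
    truth: dict[str, tuple[str, ...]] = {}
    truth["latent"] = tuple(feature_ids[j] for j in sorted(latent_idx))
    for task in TASKS:
        idx = rng.choice(non_latent, size=spec.k, replace=False)
        s = X[:, idx].sum(axis=1) / np.sqrt(spec.k)
        logit = spec.delta * np.sqrt(spec.k) * (
            np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * s
        )
        prob = 1.0 / (1.0 + np.exp(-logit))
        labels[task] = (rng.random(spec.n) < prob).astype(int)
        truth[task] = tuple(feature_ids[j] for j in sorted(idx))
    table = FeatureTable(row_ids=row_ids, feature_ids=feature_ids, values=X)
    return table, labels, truth
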