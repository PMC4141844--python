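"""Per-residue annotation tracks: secondary structure, disorder, exposure.

Tracks can come from external predictor output (PSIPRED-style ``.ss2``
files, per-residue disorder or accessibility tables) through
:func:`parse_external_annotation`, or from the built-in deterministic
baseline annotators in :func:`baseline_annotate`.  The baselines exist so
the feature encoder never depends on external binaries: they are simple
windowed propensity rules over published residue scales, not re-creations
of any particular predictor's output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np

from crysprop.data.scales import (
    CHOU_FASMAN_HELIX,
    CHOU_FASMAN_STRAND,
    DISORDER_PROMOTING,
    KYTE_DOOLITTLE,
    standardize_scale,
)
from crysprop.seqio import ProteinRecord

SS_ALPHABET = frozenset("HEC")
DISORDER_ALPHABET = frozenset("DO")
EXPOSURE_ALPHABET = frozenset("EB")

AnnotationKind = Literal["ss2", "disorder_tab", "acc_tab"]


class AnnotationError(ValueError):
    pass


@dataclasses.dataclass
class ResidueAnnotation:
    """Aligned per-residue tracks for one protein.

    ``ss`` over {H,E,C}; ``disorder`` over {D,O}; ``exposure`` over {E,B}.
    Tracks not yet set are None and must be filled (e.g. by
    :func:`baseline_annotate`) before feature encoding.
    """

    length: int
    ss: str | None = None
    disorder: str | None = None
    exposure: str | None = None
    source: str = "baseline"

    def __post_init__(self) -> None:
        for name, track, alphabet in (
            ("ss", self.ss, SS_ALPHABET),
            ("disorder", self.disorder, DISORDER_ALPHABET),
            ("exposure", self.exposure, EXPOSURE_ALPHABET),
        ):
            if track is None:
                continue
            if len(track) != self.length:
                raise AnnotationError(
                    f"{name} track length {len(track)} != sequence length {self.length}"
                )
            bad = set(track) - alphabet
            if bad:
                raise AnnotationError(f"{name} track has invalid symbols {sorted(bad)}")

    def require_complete(self) -> None:
        for name in ("ss", "disorder", "exposure"):
            if getattr(self, name) is None:
                raise AnnotationError(f"annotation track {name!r} is unset")


@dataclasses.dataclass(frozen=True)
class BaselineParams:
    """Tunables of the built-in annotators (windows in residues)."""

    hydropathy_window: int = 9
    exposure_threshold: float = 0.0  # on the standardized hydropathy scale
    disorder_window: int = 21
    disorder_threshold: float = 0.3
    coil_baseline: float = 1.0  # Chou-Fasman-propensity units

    def __post_init__(self) -> None:
        for w in (self.hydropathy_window, self.disorder_window):
            if w < 3 or w % 2 == 0:
                raise ValueError("windows must be odd and >= 3")


def _windowed_mean_directional(values: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated symmetrically at the ends.

    Averaged over both scan directions so the result is bit-exactly
    mirror-symmetric: reversing the input reverses the output even where
    one-directional cumulative sums would differ in the last ulp (which
    can flip downstream state calls at propensity ties).
    """
    fwd = _windowed_mean_directional(values, window)
    bwd = _windowed_mean_directional(values[::-1], window)[::-1]
    return (fwd + bwd) / 2.0


def baseline_annotate(
    record: ProteinRecord, params: BaselineParams | None = None
) -> ResidueAnnotation:
    """Deterministic three-track annotation from residue propensity scales.

    exposure: exposed iff the windowed mean of standardized Kyte-Doolittle
    hydropathy is below the threshold (hydrophilic stretches exposed);
    ss: argmax of windowed helix/strand propensity vs a fixed coil
    baseline, ties to coil; disorder: disordered iff the windowed fraction
    of disorder-promoting residues (D,E,K,R,S,Q,P,G) reaches the threshold.
    """
    params = params or BaselineParams()
    seq = record.sequence
    n = record.n

    kd_z = standardize_scale(KYTE_DOOLITTLE)
    hyd = np.array([kd_z[aa] for aa in seq])
    exposed = _windowed_mean(hyd, params.hydropathy_window) < params.exposure_threshold
    exposure = "".join("E" if e else "B" for e in exposed)

    helix = _windowed_mean(
        np.array([CHOU_FASMAN_HELIX[aa] for aa in seq]), params.hydropathy_window
    )
    strand = _windowed_mean(
        np.array([CHOU_FASMAN_STRAND[aa] for aa in seq]), params.hydropathy_window
    )
    ss_chars = []
    for h, e in zip(helix, strand):
        best = max(h, e, params.coil_baseline)
        if best == params.coil_baseline or h == e == best:
            ss_chars.append("C")
        elif h == best:
            ss_chars.append("H")
        else:
            ss_chars.append("E")
    ss = "".join(ss_chars)

    promoting = np.array([aa in DISORDER_PROMOTING for aa in seq], dtype=float)
    disordered = _windowed_mean(promoting, params.disorder_window) >= params.disorder_threshold
    disorder = "".join("D" if d else "O" for d in disordered)

    return ResidueAnnotation(
        length=n, ss=ss, disorder=disorder, exposure=exposure, source="baseline"
    )


def fill_missing_tracks(
    record: ProteinRecord,
    annotation: ResidueAnnotation,
    params: BaselineParams | None = None,
) -> ResidueAnnotation:
    """Complete unset tracks of a partial annotation with baseline calls."""
    base = baseline_annotate(record, params)
    return ResidueAnnotation(
        length=annotation.length,
        ss=annotation.ss or base.ss,
        disorder=annotation.disorder or base.disorder,
        exposure=annotation.exposure or base.exposure,
        source=annotation.source if all(
            getattr(annotation, t) for t in ("ss", "disorder", "exposure")
        ) else "mixed",
    )


_SS2_STATE_MAP = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E", "C": "C", "T": "C", "S": "C"}


def parse_external_annotation(
    kind: AnnotationKind, path: str | Path, record: ProteinRecord
) -> ResidueAnnotation:
    """Parse one external predictor output file into a (partial) annotation.

    ``ss2``: PSIPRED-style columns (index, residue, state, 3 probabilities);
    ``disorder_tab``: per-residue rows (index, residue, mark) where the mark
    ``D`` or ``*`` means disordered; ``acc_tab``: per-residue rows with a
    two-state ``e``/``b`` accessibility call.  The file's residue column
    must match the record's sequence.
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    rows = [ln.split() for ln in lines]
    rows = [r for r in rows if len(r) >= 3 and r[0].isdigit()]
    if len(rows) != record.n:
        raise AnnotationError(
            f"{path}: {len(rows)} residue rows for sequence of length {record.n}"
        )
    track_chars = []
    for i, row in enumerate(rows):
        residue = row[1].upper()
        if residue != record.sequence[i]:
            raise AnnotationError(
                f"{path}: residue mismatch at position {i + 1}: "
                f"file has {residue!r}, sequence has {record.sequence[i]!r}"
            )
        mark = row[2]
        if kind == "ss2":
            state = _SS2_STATE_MAP.get(mark.upper())
            if state is None:
                raise AnnotationError(f"{path}: unknown ss state {mark!r} at row {i + 1}")
            track_chars.append(state)
        elif kind == "disorder_tab":
            track_chars.append("D" if mark.upper() in {"D", "*"} else "O")
        elif kind == "acc_tab":
            if mark.lower() not in {"e", "b"}:
                raise AnnotationError(
                    f"{path}: unknown accessibility call {mark!r} at row {i + 1}"
                )
            track_chars.append(mark.upper())
        else:
            raise ValueError(f"unknown annotation kind {kind!r}")
    track = "".join(track_chars)
    if kind == "ss2":
        return ResidueAnnotation(length=record.n, ss=track, source="external")
    if kind == "disorder_tab":
        return ResidueAnnotation(length=record.n, disorder=track, source="external")
    return ResidueAnnotation(length=record.n, exposure=track, source="external")
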