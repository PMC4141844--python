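"""I/O for every external artifact: sequences, AAindex tables, status
records, feature tables and trained model bundles."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crysprop.data.scales import AA20, AAINDEX_ROW_ORDER

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset(AA20)

MODEL_BUNDLE_FORMAT_VERSION = 1


class SeqIOError(ValueError):
    """Raised on malformed external artifacts."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein target: identifier plus validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record id must be non-empty")
        if not self.sequence:
            raise SeqIOError(f"{self.id}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_AA:
                raise SeqIOError(
                    f"{self.id}: non-standard residue {aa!r} at position {pos}"
                )

    @property
    def n(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class AAindexTable:
    """Ordered collection of amino-acid property scales."""

    entries: list[tuple[str, dict[str, float]]]

    def __post_init__(self) -> None:
        ids = [idx for idx, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate AAindex ids in table")
        for idx_id, values in self.entries:
            missing = STANDARD_AA - set(values)
            if missing:
                raise SeqIOError(f"{idx_id}: missing values for {sorted(missing)}")

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def index_ids(self) -> list[str]:
        return [idx for idx, _ in self.entries]

    def matrix(self) -> np.ndarray:
        """(count, 20) value matrix in AA20 column order."""
        return np.array(
            [[values[aa] for aa in AA20] for _, values in self.entries], dtype=float
        )


@dataclasses.dataclass(frozen=True)
class StatusRecord:
    """One experimental trial of one crystallization target."""

    target_id: str
    trial_id: str
    status: str
    stop_date: _dt.date
    method: str
    stop_condition: str

    def __post_init__(self) -> None:
        if not self.status:
            raise SeqIOError(f"{self.target_id}/{self.trial_id}: empty status")


@dataclasses.dataclass
class FeatureTable:
    """Row-major real matrix of per-protein feature values."""

    row_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.feature_ids)):
            raise SeqIOError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise SeqIOError("feature table contains non-finite values")

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[f] for f in feature_ids]
        except KeyError as exc:
            raise SeqIOError(f"unknown feature id {exc.args[0]!r}") from None
        return FeatureTable(
            row_ids=list(self.row_ids),
            feature_ids=list(feature_ids),
            values=self.values[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_ids)


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path, *, skip_nonstandard: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated protein records.

    Lowercase residues are uppercased.  Records containing residues outside
    the 20-letter standard alphabet (B, J, O, U, X, Z, gaps, ...) raise in
    strict mode (default) or are skipped with a log message when
    ``skip_nonstandard`` is true.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SeqIOError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        except SeqIOError:
            if skip_nonstandard:
                logger.warning("skipping %s: non-standard residues", entry.id)
                continue
            raise
    if not records and not seen:
        raise SeqIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    _BioSeqIO.write(bio, str(path), "fasta")


# --- AAindex1 flat file ----------------------------------------------------

def parse_aaindex1(
    path: str | Path, *, allow_any_count: bool = False, expected_count: int = 544
) -> AAindexTable:
    """Parse an AAindex1 flat file (H/I records, two 10-value rows, ``NA``).

    ``NA`` values are imputed with the mean of the index's available values
    (logged).  A snapshot whose entry count differs from ``expected_count``
    is rejected unless ``allow_any_count`` is set: the downstream feature
    registry arithmetic assumes the 544-entry snapshot.
    """
    text = Path(path).read_text()
    entries: list[tuple[str, dict[str, float]]] = []
    for block in text.split("//"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        idx_id = None
        value_rows: list[str] = []
        in_values = False
        for ln in lines:
            if ln.startswith("H "):
                idx_id = ln[2:].strip().split()[0]
                in_values = False
            elif ln.startswith("I "):
                in_values = True
            elif in_values and not ln[:1].isalpha():
                value_rows.append(ln)
        if idx_id is None:
            continue
        tokens = " ".join(value_rows).split()
        if len(tokens) != 20:
            raise SeqIOError(
                f"{idx_id}: malformed I-block, expected 20 values, got {len(tokens)}"
            )
        raw: dict[str, float | None] = {}
        for aa, tok in zip(AAINDEX_ROW_ORDER, tokens):
            raw[aa] = None if tok.upper() == "NA" else float(tok)
        present = [v for v in raw.values() if v is not None]
        if not present:
            raise SeqIOError(f"{idx_id}: all values NA")
        mean = float(np.mean(present))
        values: dict[str, float] = {}
        for aa, v in raw.items():
            if v is None:
                logger.info("%s: imputing NA for %s with mean %.4f", idx_id, aa, mean)
                values[aa] = mean
            else:
                values[aa] = v
        entries.append((idx_id, values))
    table = AAindexTable(entries=entries)
    if table.count != expected_count and not allow_any_count:
        raise SeqIOError(
            f"AAindex snapshot has {table.count} entries, expected {expected_count} "
            "(pass allow_any_count to accept)"
        )
    return table


# --- status records --------------------------------------------------------

STATUS_COLUMNS = ["target_id", "trial_id", "status", "stop_date", "method", "stop_condition"]


def read_status_records(path: str | Path) -> list[StatusRecord]:
    """Read a TSV of experimental-trial status records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"status table missing column(s): {', '.join(missing)}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            stop_date = _dt.date.fromisoformat(row.stop_date)
        except ValueError:
            raise SeqIOError(
                f"row {row_no}: unparseable stop_date {row.stop_date!r}"
            ) from None
        records.append(
            StatusRecord(
                target_id=row.target_id,
                trial_id=row.trial_id,
                status=row.status,
                stop_date=stop_date,
                method=row.method,
                stop_condition=row.stop_condition,
            )
        )
    return records


def write_status_records(records: Iterable[StatusRecord], path: str | Path) -> None:
    rows = [
        {
            "target_id": r.target_id,
            "trial_id": r.trial_id,
            "status": r.status,
            "stop_date": r.stop_date.isoformat(),
            "method": r.method,
            "stop_condition": r.stop_condition,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=STATUS_COLUMNS).to_csv(path, sep="\t", index=False)


# --- feature tables --------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="protein_id", float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="protein_id", float_precision="round_trip")
    return FeatureTable(
        row_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


# --- model bundles ---------------------------------------------------------

class ModelBundleError(SeqIOError):
    """Raised on unreadable or incompatible model bundles."""


def save_model_bundle(bundle, path: str | Path) -> None:
    """Persist a trained stacked model (joblib payload + version stamp)."""
    payload = {
        "format_version": MODEL_BUNDLE_FORMAT_VERSION,
        "bundle": bundle,
    }
    joblib.dump(payload, str(path))


def load_model_bundle(path: str | Path):
    try:
        payload = joblib.load(str(path))
    except Exception as exc:  # corrupted/truncated payloads must not mispredict
        raise ModelBundleError(f"{path}: unreadable model bundle ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelBundleError(f"{path}: not a crysprop model bundle")
    version = payload["format_version"]
    if version != MODEL_BUNDLE_FORMAT_VERSION:
        raise ModelBundleError(
            f"{path}: bundle format version {version} != supported "
            f"{MODEL_BUNDLE_FORMAT_VERSION}"
        )
    return payload["bundle"]
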