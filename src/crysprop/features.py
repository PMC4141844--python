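"""The 2,924-feature candidate encoding.

Layout (registry order):

* three AAindex blocks (whole-sequence / exposed / buried mean property,
  544 scales each) — 1,632 features;
* ten PROFEAT-style blocks: dipeptide composition 400, normalized
  Moreau-Broto / Moran / Geary autocorrelation 90 each, composition /
  transition / distribution over seven 3-class physicochemical partitions
  21 + 21 + 105, quasi-sequence-order 160, amphiphilic pseudo-amino-acid
  composition 80, total amino-acid properties 3 — 1,060 features;
* 232 sequence/structure features: amino-acid and grouped compositions
  (87) and annotation-derived exposure / secondary-structure / disorder /
  cross-track / global blocks (145).

Every encoder is a pure function of (sequence, annotation, parameters).
Compositional sub-blocks sum to 1 (or 0 when undefined); zero-variance
autocorrelations and empty exposure classes follow the documented
conventions rather than raising.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np

from crysprop.annotate import ResidueAnnotation
from crysprop.data.scales import (
    AA20,
    AA_TO_INDEX,
    APAAC_HYDROPHILICITY,
    APAAC_HYDROPHOBICITY,
    CTD_ORDER,
    CTD_PARTITIONS,
    FIVE_CLASS_GROUPS,
    FIVE_CLASS_ORDER,
    FLEXIBILITY,
    KYTE_DOOLITTLE,
    PKA_SIDECHAIN,
    PKA_TERMINI,
    POLARIZABILITY,
    RESIDUE_MASS,
    SS_AA_CLASS_ORDER,
    SS_AA_CLASSES,
    TEN_FUNCTIONAL_GROUPS,
    TEN_GROUP_ORDER,
    THREE_CLASS_GROUPS,
    THREE_CLASS_ORDER,
    grantham_matrix,
    physchem_distance_matrix,
    standardize_scale,
)
from crysprop.seqio import AAindexTable, FeatureTable, ProteinRecord

TOTAL_FEATURES = 2924
AAINDEX_BLOCK_SIZE = 544
NON_AAINDEX_FEATURES = TOTAL_FEATURES - 3 * AAINDEX_BLOCK_SIZE  # 1292


class EncodingError(ValueError):
    pass


# --- parameter objects -----------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AutocorrParams:
    """Three property scales x 30 lags per autocorrelation family."""

    property_ids: tuple[str, str, str] = ("KYTJ820101", "BHAR880101", "CHAM820101")
    scales: tuple[dict, dict, dict] = (KYTE_DOOLITTLE, FLEXIBILITY, POLARIZABILITY)
    maxlag: int = 30


@dataclasses.dataclass(frozen=True)
class QSOParams:
    maxlag: int = 30
    weight: float = 0.1
    matrix_names: tuple[str, str] = ("grantham", "physchem")


@dataclasses.dataclass(frozen=True)
class APAACParams:
    lam: int = 30
    weight: float = 0.05


@dataclasses.dataclass(frozen=True)
class PIParams:
    pka_termini: dict = dataclasses.field(default_factory=lambda: dict(PKA_TERMINI))
    pka_sidechain: dict = dataclasses.field(default_factory=lambda: dict(PKA_SIDECHAIN))
    tolerance: float = 1e-4


_QSO_MATRICES = {"grantham": grantham_matrix, "physchem": physchem_distance_matrix}


# --- small helpers ---------------------------------------------------------

def _codes(seq: str) -> np.ndarray:
    return np.fromiter((AA_TO_INDEX[aa] for aa in seq), dtype=np.int64, count=len(seq))


def _run_lengths(mask: Sequence[bool]) -> list[int]:
    runs, current = [], 0
    for m in mask:
        if m:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def _seq_values(seq: str, scale: dict) -> np.ndarray:
    return np.array([scale[aa] for aa in seq], dtype=float)


# --- compositions (87) -----------------------------------------------------

def encode_compositions(record: ProteinRecord) -> np.ndarray:
    """AA composition 20, five-class 5, ten-group 10, grouped dipeptide 25,
    grouped tripeptide 27 (zeros when the sequence is too short)."""
    seq, n = record.sequence, record.n
    counts = np.bincount(_codes(seq), minlength=20)
    aa_comp = counts / n

    class5 = np.array(
        [sum(counts[AA_TO_INDEX[a]] for a in FIVE_CLASS_GROUPS[c]) for c in FIVE_CLASS_ORDER]
    ) / n
    group10 = np.array(
        [sum(counts[AA_TO_INDEX[a]] for a in TEN_FUNCTIONAL_GROUPS[g]) for g in TEN_GROUP_ORDER]
    ) / n

    cls5_of = {a: i for i, c in enumerate(FIVE_CLASS_ORDER) for a in FIVE_CLASS_GROUPS[c]}
    gdip = np.zeros((5, 5))
    if n >= 2:
        for a, b in zip(seq, seq[1:]):
            gdip[cls5_of[a], cls5_of[b]] += 1
        gdip /= n - 1

    cls3_of = {a: i for i, c in enumerate(THREE_CLASS_ORDER) for a in THREE_CLASS_GROUPS[c]}
    gtri = np.zeros((3, 3, 3))
    if n >= 3:
        for a, b, c in zip(seq, seq[1:], seq[2:]):
            gtri[cls3_of[a], cls3_of[b], cls3_of[c]] += 1
        gtri /= n - 2

    return np.concatenate([aa_comp, class5, group10, gdip.ravel(), gtri.ravel()])


# --- AAindex blocks (3 x 544) ----------------------------------------------

def encode_aaindex_blocks(
    record: ProteinRecord, annot: ResidueAnnotation, table: AAindexTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean property value per scale over all / exposed / buried residues.

    An empty exposure class falls back to the whole-sequence mean so the
    block stays defined for fully exposed or fully buried chains.
    """
    if annot.exposure is None:
        raise EncodingError("AAindex exposure blocks require the exposure track")
    matrix = table.matrix()  # (count, 20)
    codes = _codes(record.sequence)
    per_residue = matrix[:, codes]  # (count, N)
    seq_mean = per_residue.mean(axis=1)
    exposed_mask = np.frombuffer(annot.exposure.encode(), dtype=np.uint8) == ord("E")
    if exposed_mask.any():
        exposed_mean = per_residue[:, exposed_mask].mean(axis=1)
    else:
        exposed_mean = seq_mean.copy()
    if (~exposed_mask).any():
        buried_mean = per_residue[:, ~exposed_mask].mean(axis=1)
    else:
        buried_mean = seq_mean.copy()
    return seq_mean, exposed_mean, buried_mean


# --- PROFEAT-style blocks --------------------------------------------------

def encode_dipeptide(record: ProteinRecord) -> np.ndarray:
    """400 ordered-pair frequencies n_ab/(N-1), row-major over AA20."""
    seq, n = record.sequence, record.n
    out = np.zeros((20, 20))
    if n < 2:
        return out.ravel()
    for a, b in zip(seq, seq[1:]):
        out[AA_TO_INDEX[a], AA_TO_INDEX[b]] += 1
    return (out / (n - 1)).ravel()


def encode_autocorrelation(
    record: ProteinRecord, params: AutocorrParams | None = None
) -> np.ndarray:
    """Normalized Moreau-Broto, Moran and Geary autocorrelation: 3 families
    x 3 properties x 30 lags = 270 values (family-major, property-major)."""
    params = params or AutocorrParams()
    n, d_max = record.n, params.maxlag
    nmb, moran, geary = [], [], []
    for scale in params.scales:
        p = _seq_values(record.sequence, scale)
        z = _seq_values(record.sequence, standardize_scale(scale))
        p_bar = p.mean()
        dev = p - p_bar
        var_n = (dev**2).sum() / n
        var_n1 = (dev**2).sum() / (n - 1) if n > 1 else 0.0
        for d in range(1, d_max + 1):
            if n <= d:
                nmb.append(0.0)
                moran.append(0.0)
                geary.append(0.0)
                continue
            nmb.append(float((z[:-d] * z[d:]).sum() / (n - d)))
            if var_n == 0.0:
                moran.append(0.0)
            else:
                moran.append(float((dev[:-d] * dev[d:]).sum() / (n - d) / var_n))
            if var_n1 == 0.0:
                geary.append(0.0)
            else:
                geary.append(float(((p[:-d] - p[d:]) ** 2).sum() / (2 * (n - d)) / var_n1))
    return np.concatenate([nmb, moran, geary])


def encode_ctd(record: ProteinRecord) -> np.ndarray:
    """Composition (21), transition (21) and distribution (105) over the
    seven 3-class physicochemical partitions."""
    seq, n = record.sequence, record.n
    comp, trans, dist = [], [], []
    for prop in CTD_ORDER:
        groups = CTD_PARTITIONS[prop]
        cls_of = {a: g for g, members in enumerate(groups) for a in members}
        labels = np.array([cls_of[a] for a in seq])
        counts = np.bincount(labels, minlength=3)
        comp.extend(counts / n)
        pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for a, b in zip(labels, labels[1:]):
            if a != b:
                pair_counts[(min(a, b), max(a, b))] += 1
        for pair in ((0, 1), (0, 2), (1, 2)):
            trans.append(pair_counts[pair] / (n - 1) if n > 1 else 0.0)
        for g in range(3):
            positions = np.flatnonzero(labels == g) + 1  # 1-based
            n_c = len(positions)
            if n_c == 0:
                dist.extend([0.0] * 5)
                continue
            ks = [1] + [int(np.ceil(q * n_c)) for q in (0.25, 0.5, 0.75, 1.0)]
            dist.extend(100.0 * positions[k - 1] / n for k in ks)
    return np.concatenate([comp, trans, dist])


def encode_qso(record: ProteinRecord, params: QSOParams | None = None) -> np.ndarray:
    """Quasi-sequence-order: per distance matrix, 30 raw coupling terms
    tau_d plus 50 normalized descriptors (20 residue + 30 order) = 160."""
    params = params or QSOParams()
    seq, n, w = record.sequence, record.n, params.weight
    codes = _codes(seq)
    freqs = np.bincount(codes, minlength=20) / n
    out = []
    for name in params.matrix_names:
        dmat = _QSO_MATRICES[name]()
        taus = np.zeros(params.maxlag)
        for d in range(1, params.maxlag + 1):
            if d < n:
                taus[d - 1] = (dmat[codes[:-d], codes[d:]] ** 2).sum()
        denom = freqs.sum() + w * taus.sum()
        out.append(taus)
        out.append(freqs / denom)
        out.append(w * taus / denom)
    return np.concatenate(out)


def encode_apaac(record: ProteinRecord, params: APAACParams | None = None) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition: 20 residue terms plus
    2*lambda interleaved hydrophobicity/hydrophilicity correlation terms."""
    params = params or APAACParams()
    seq, n, w = record.sequence, record.n, params.weight
    h1 = _seq_values(seq, standardize_scale(APAAC_HYDROPHOBICITY))
    h2 = _seq_values(seq, standardize_scale(APAAC_HYDROPHILICITY))
    taus = np.zeros(2 * params.lam)
    for j in range(1, params.lam + 1):
        if j < n:
            taus[2 * j - 2] = (h1[:-j] * h1[j:]).sum() / (n - j)
            taus[2 * j - 1] = (h2[:-j] * h2[j:]).sum() / (n - j)
    freqs = np.bincount(_codes(seq), minlength=20) / n
    denom = freqs.sum() + w * np.abs(taus).sum()
    return np.concatenate([freqs / denom, w * taus / denom])


def encode_taap(record: ProteinRecord, params: AutocorrParams | None = None) -> np.ndarray:
    """Total amino-acid property: sequence-summed scale / N for the three
    autocorrelation property scales."""
    params = params or AutocorrParams()
    return np.array(
        [_seq_values(record.sequence, scale).sum() / record.n for scale in params.scales]
    )


# --- isoelectric point -----------------------------------------------------

def net_charge(record: ProteinRecord, ph: float, params: PIParams | None = None) -> float:
    """Henderson-Hasselbalch net charge over termini and ionizable side chains."""
    params = params or PIParams()
    positive_pkas = [params.pka_termini["Nterm"]]
    negative_pkas = [params.pka_termini["Cterm"]]
    for aa in record.sequence:
        pka = params.pka_sidechain.get(aa)
        if pka is None:
            continue
        if aa in ("K", "R", "H"):
            positive_pkas.append(pka)
        else:
            negative_pkas.append(pka)
    pos = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in positive_pkas)
    neg = sum(-1.0 / (1.0 + 10 ** (pka - ph)) for pka in negative_pkas)
    return pos + neg


def compute_pi(record: ProteinRecord, params: PIParams | None = None) -> float:
    """Isoelectric point by bisection on [0, 14]; the charge curve is
    monotone decreasing in pH so the root is unique."""
    params = params or PIParams()
    lo, hi = 0.0, 14.0
    if net_charge(record, lo, params) < 0:
        return lo
    if net_charge(record, hi, params) > 0:
        return hi
    while hi - lo > params.tolerance:
        mid = (lo + hi) / 2
        if net_charge(record, mid, params) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# --- annotation-derived blocks (145) ---------------------------------------

def _run_stats(mask: list[bool], n: int, thresholds: tuple[int, ...]) -> list[float]:
    runs = _run_lengths(mask)
    stats = [sum(1 for r in runs if r >= t) / n for t in thresholds]
    stats.append(float(max(runs)) if runs else 0.0)
    stats.append(float(np.mean(runs)) if runs else 0.0)
    return stats


def encode_structure_blocks(
    record: ProteinRecord, annot: ResidueAnnotation, pi_params: PIParams | None = None
) -> np.ndarray:
    """Exposure (65), secondary structure (37), disorder (13), cross-track
    (20) and sequence-global (10) features from the three annotation tracks."""
    annot.require_complete()
    seq, n = record.sequence, record.n
    ss, dis, exp = annot.ss, annot.disorder, annot.exposure
    cls5_of = {a: i for i, c in enumerate(FIVE_CLASS_ORDER) for a in FIVE_CLASS_GROUPS[c]}

    def freq(pred) -> float:
        return sum(1 for i in range(n) if pred(i)) / n

    out: list[float] = []

    # exposure block (65)
    exposed = [c == "E" for c in exp]
    out.append(sum(exposed) / n)
    for aa in AA20:
        out.append(freq(lambda i, aa=aa: seq[i] == aa and exposed[i]))
    for aa in AA20:
        out.append(freq(lambda i, aa=aa: seq[i] == aa and not exposed[i]))
    for ci in range(5):
        out.append(freq(lambda i, ci=ci: cls5_of[seq[i]] == ci and exposed[i]))
    for ci in range(5):
        out.append(freq(lambda i, ci=ci: cls5_of[seq[i]] == ci and not exposed[i]))
    out.extend(_run_stats(exposed, n, (1, 2, 4, 8, 16)))
    out.extend(_run_stats([not e for e in exposed], n, (1, 2, 4, 8, 16)))

    # secondary-structure block (37)
    total_segments = 0
    for state in "HEC":
        out.append(freq(lambda i, s=state: ss[i] == s))
    for state in "HEC":
        runs = _run_lengths([c == state for c in ss])
        total_segments += len(runs)
        out.append(float(np.mean(runs)) if runs else 0.0)
        out.append(float(max(runs)) if runs else 0.0)
        out.append(len(runs) / n)
    for state in "HEC":
        runs = _run_lengths([c == state for c in ss])
        for t in (1, 4, 8):
            out.append(sum(1 for r in runs if r >= t) / n)
    for state in "HEC":
        for cls_name in SS_AA_CLASS_ORDER:
            members = SS_AA_CLASSES[cls_name]
            out.append(freq(lambda i, s=state, m=members: ss[i] == s and seq[i] in m))
    out.append(total_segments / n)

    # disorder block (13)
    disordered = [c == "D" for c in dis]
    runs = _run_lengths(disordered)
    out.append(sum(disordered) / n)
    out.append(len(runs) / n)
    out.append(float(np.mean(runs)) if runs else 0.0)
    out.append(float(max(runs)) if runs else 0.0)
    for t in (4, 8, 16, 32):
        out.append(sum(1 for r in runs if r >= t) / n)
    for state in "HEC":
        out.append(freq(lambda i, s=state: disordered[i] and ss[i] == s))
    head = min(20, n)
    out.append(sum(disordered[:head]) / head)
    out.append(sum(disordered[-head:]) / head)

    # cross-track block (20)
    for ci in range(5):
        out.append(freq(lambda i, ci=ci: cls5_of[seq[i]] == ci and disordered[i]))
    for state in "HEC":
        out.append(freq(lambda i, s=state: exposed[i] and ss[i] == s))
    for state in "HEC":
        out.append(freq(lambda i, s=state: not exposed[i] and ss[i] == s))
    out.append(freq(lambda i: disordered[i] and exposed[i]))
    out.append(freq(lambda i: disordered[i] and not exposed[i]))
    out.append(freq(lambda i: seq[i] == "H" and exposed[i]))
    out.append(freq(lambda i: seq[i] == "E" and not exposed[i]))
    out.append(freq(lambda i: seq[i] == "E" and exposed[i]))
    out.append(freq(lambda i: seq[i] == "H" and not exposed[i]))
    kd = _seq_values(seq, KYTE_DOOLITTLE)
    for state in "HEC":
        sel = [i for i in range(n) if ss[i] == state and exposed[i]]
        out.append(float(kd[sel].mean()) if sel else 0.0)

    # sequence-global block (10)
    out.append(float(n))
    out.append(float(np.log(n)))
    out.append(compute_pi(record, pi_params))
    out.append(float(np.mean([RESIDUE_MASS[a] for a in seq])))
    out.append(float(kd.mean()))
    out.append(net_charge(record, 7.0, pi_params) / n)
    out.append((sum(seq.count(a) for a in "KRH") - sum(seq.count(a) for a in "DE")) / n)
    out.append(sum(seq.count(a) for a in "FWY") / n)
    out.append(sum(seq.count(a) for a in "CM") / n)
    out.append(float(seq.count("C") % 2))

    return np.array(out)


# --- registry ---------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureRegistry:
    """Ordered catalogue of the candidate features, grouped in blocks."""

    blocks: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def feature_ids(self) -> list[str]:
        return [fid for _, ids in self.blocks for fid in ids]

    @property
    def total(self) -> int:
        return sum(len(ids) for _, ids in self.blocks)

    @property
    def block_sizes(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.blocks}

    def block_feature_ids(self, block_id: str) -> tuple[str, ...]:
        for name, ids in self.blocks:
            if name == block_id:
                return ids
        raise KeyError(block_id)

    @property
    def fingerprint(self) -> str:
        digest = hashlib.sha256("\n".join(self.feature_ids).encode())
        return digest.hexdigest()[:16]

    def validate(self) -> None:
        ids = self.feature_ids
        if len(set(ids)) != len(ids):
            raise EncodingError("registry feature ids are not unique")
        if self.total != TOTAL_FEATURES:
            raise EncodingError(f"registry total {self.total} != {TOTAL_FEATURES}")


def build_registry(table: AAindexTable) -> FeatureRegistry:
    """The canonical registry for an AAindex snapshot (544 scales)."""
    if table.count != AAINDEX_BLOCK_SIZE:
        raise EncodingError(
            f"registry requires a {AAINDEX_BLOCK_SIZE}-entry AAindex table, "
            f"got {table.count}"
        )
    ac = AutocorrParams()
    blocks: list[tuple[str, tuple[str, ...]]] = []
    blocks.append(("aaindex_seq", tuple(f"AAseq::{i}" for i in table.index_ids)))
    blocks.append(("aaindex_exposed", tuple(f"AAexp::{i}" for i in table.index_ids)))
    blocks.append(("aaindex_buried", tuple(f"AAbur::{i}" for i in table.index_ids)))
    blocks.append(
        ("dipeptide", tuple(f"dipep::{a}{b}" for a in AA20 for b in AA20))
    )
    for family in ("nmbroto", "moran", "geary"):
        blocks.append(
            (
                family,
                tuple(
                    f"{family}::{pid}::lag{d}"
                    for pid in ac.property_ids
                    for d in range(1, ac.maxlag + 1)
                ),
            )
        )
    blocks.append(
        ("ctd_c", tuple(f"ctd_c::{p}::g{g}" for p in CTD_ORDER for g in (1, 2, 3)))
    )
    blocks.append(
        ("ctd_t", tuple(f"ctd_t::{p}::{pr}" for p in CTD_ORDER for pr in ("g12", "g13", "g23")))
    )
    blocks.append(
        (
            "ctd_d",
            tuple(
                f"ctd_d::{p}::g{g}::p{q}"
                for p in CTD_ORDER
                for g in (1, 2, 3)
                for q in ("first", 25, 50, 75, 100)
            ),
        )
    )
    qso = QSOParams()
    qso_ids: list[str] = []
    for mat in qso.matrix_names:
        qso_ids += [f"qso::{mat}::tau{d}" for d in range(1, qso.maxlag + 1)]
        qso_ids += [f"qso::{mat}::comp::{aa}" for aa in AA20]
        qso_ids += [f"qso::{mat}::order{d}" for d in range(1, qso.maxlag + 1)]
    blocks.append(("qso", tuple(qso_ids)))
    apaac = APAACParams()
    blocks.append(
        (
            "apaac",
            tuple(f"apaac::comp::{aa}" for aa in AA20)
            + tuple(f"apaac::tau{k}" for k in range(1, 2 * apaac.lam + 1)),
        )
    )
    blocks.append(("taap", tuple(f"taap::{pid}" for pid in ac.property_ids)))

    blocks.append(("aa_comp", tuple(f"comp::{aa}" for aa in AA20)))
    blocks.append(("class5_comp", tuple(f"comp5::{c}" for c in FIVE_CLASS_ORDER)))
    blocks.append(("group10_comp", tuple(f"comp10::{g}" for g in TEN_GROUP_ORDER)))
    blocks.append(
        (
            "grouped_dipeptide",
            tuple(f"gdipep::{a}|{b}" for a in FIVE_CLASS_ORDER for b in FIVE_CLASS_ORDER),
        )
    )
    blocks.append(
        (
            "grouped_tripeptide",
            tuple(
                f"gtripep::{a}|{b}|{c}"
                for a in THREE_CLASS_ORDER
                for b in THREE_CLASS_ORDER
                for c in THREE_CLASS_ORDER
            ),
        )
    )

    exp_ids = ["exp::exposed_frac"]
    exp_ids += [f"exp::freqE::{aa}" for aa in AA20]
    exp_ids += [f"exp::freqB::{aa}" for aa in AA20]
    exp_ids += [f"exp::class5E::{c}" for c in FIVE_CLASS_ORDER]
    exp_ids += [f"exp::class5B::{c}" for c in FIVE_CLASS_ORDER]
    for track in ("runE", "runB"):
        exp_ids += [f"exp::{track}::ge{t}" for t in (1, 2, 4, 8, 16)]
        exp_ids += [f"exp::{track}::max", f"exp::{track}::mean"]
    blocks.append(("exposure", tuple(exp_ids)))

    ss_ids = [f"ss::frac::{s}" for s in "HEC"]
    for s in "HEC":
        ss_ids += [f"ss::seg_mean::{s}", f"ss::seg_max::{s}", f"ss::seg_count::{s}"]
    for s in "HEC":
        ss_ids += [f"ss::run::{s}::ge{t}" for t in (1, 4, 8)]
    for s in "HEC":
        ss_ids += [f"ss::aa::{s}::{cls}" for cls in SS_AA_CLASS_ORDER]
    ss_ids.append("ss::seg_total")
    blocks.append(("secstruct", tuple(ss_ids)))

    dis_ids = ["dis::frac", "dis::seg_count", "dis::seg_mean", "dis::seg_max"]
    dis_ids += [f"dis::run::ge{t}" for t in (4, 8, 16, 32)]
    dis_ids += [f"dis::ss::{s}" for s in "HEC"]
    dis_ids += ["dis::nterm20", "dis::cterm20"]
    blocks.append(("disorder", tuple(dis_ids)))

    cross_ids = [f"cross::dis_class5::{c}" for c in FIVE_CLASS_ORDER]
    cross_ids += [f"cross::expE_ss::{s}" for s in "HEC"]
    cross_ids += [f"cross::expB_ss::{s}" for s in "HEC"]
    cross_ids += ["cross::dis_expE", "cross::dis_expB"]
    cross_ids += [
        "cross::exposed_His", "cross::buried_Glu", "cross::exposed_Glu", "cross::buried_His",
    ]
    cross_ids += [f"cross::expE_kd::{s}" for s in "HEC"]
    blocks.append(("cross", tuple(cross_ids)))

    blocks.append(
        (
            "seq_global",
            (
                "glob::length", "glob::log_length", "glob::pi", "glob::mean_mass",
                "glob::mean_kd", "glob::net_charge_ph7", "glob::charge_balance",
                "glob::aromatic_frac", "glob::sulfur_frac", "glob::cys_parity",
            ),
        )
    )

    registry = FeatureRegistry(blocks=tuple(blocks))
    registry.validate()
    return registry


AAINDEX_BLOCK_IDS = ("aaindex_seq", "aaindex_exposed", "aaindex_buried")


# --- full encoding ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureVector:
    protein_id: str
    values: np.ndarray


def encode_all(
    record: ProteinRecord,
    annot: ResidueAnnotation,
    table: AAindexTable,
    registry: FeatureRegistry | None = None,
) -> FeatureVector:
    """Concatenate all blocks in registry order: exactly 2,924 values."""
    registry = registry or build_registry(table)
    try:
        seq_block, exp_block, bur_block = encode_aaindex_blocks(record, annot, table)
        parts = [
            seq_block, exp_block, bur_block,
            encode_dipeptide(record),
            encode_autocorrelation(record),
            encode_ctd(record),
            encode_qso(record),
            encode_apaac(record),
            encode_taap(record),
            encode_compositions(record),
            encode_structure_blocks(record, annot),
        ]
    except Exception as exc:
        raise EncodingError(f"{record.id}: {exc}") from exc
    values = np.concatenate(parts)
    if values.shape[0] != registry.total:
        raise EncodingError(
            f"{record.id}: encoded {values.shape[0]} values, registry expects "
            f"{registry.total}"
        )
    return FeatureVector(protein_id=record.id, values=values)


def encode_table(
    records: Sequence[ProteinRecord],
    annots: Sequence[ResidueAnnotation],
    table: AAindexTable,
    registry: FeatureRegistry | None = None,
) -> FeatureTable:
    registry = registry or build_registry(table)
    vectors = [
        encode_all(rec, ann, table, registry).values for rec, ann in zip(records, annots)
    ]
    return FeatureTable(
        row_ids=[r.id for r in records],
        feature_ids=registry.feature_ids,
        values=np.vstack(vectors) if vectors else np.empty((0, registry.total)),
    )
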