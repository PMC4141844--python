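"""Amino-acid property scales, class partitions and distance matrices.

All scales are keyed by one-letter code over the 20 standard amino acids.
``AA20`` (alphabetical) is the canonical ordering used by every encoder;
``AAINDEX_ROW_ORDER`` is the ordering of the AAindex1 flat-file value rows.

The Grantham distance matrix is computed from Grantham's composition /
polarity / volume formula rather than stored as 400 literals.  The second
sequence-order distance matrix is a synthetic physicochemical distance
(see :func:`physchem_distance_matrix`) standing in for the Schneider-Wrede
matrix, which is not bundled.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.IUPACData import protein_weights

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_TO_INDEX = {aa: i for i, aa in enumerate(AA20)}

#: order of the two 10-value rows in an AAindex1 entry:
#: A R N D C Q E G H I / L K M F P S T W Y V
AAINDEX_ROW_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

# Kyte & Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Hopp & Woods hydrophilicity (also the classic pseudo-composition H2 scale)
APAAC_HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

# classic pseudo-composition hydrophobicity scale (H1)
APAAC_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Bhaskaran & Ponnuswamy average flexibility
FLEXIBILITY = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
    "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
    "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
    "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
}

# Charton & Charton polarizability
POLARIZABILITY = {
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
}

# Grantham polarity
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

# normalized van der Waals volume
VDW_VOLUME = {
    "A": 1.00, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43,
    "Q": 3.95, "E": 3.78, "G": 0.00, "H": 4.66, "I": 4.00,
    "L": 4.00, "K": 4.77, "M": 4.43, "F": 5.89, "P": 2.72,
    "S": 1.60, "T": 2.60, "W": 8.08, "Y": 6.47, "V": 3.00,
}

# Chou-Fasman conformational propensities
CHOU_FASMAN_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
CHOU_FASMAN_STRAND = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

# average residue mass = free amino-acid mass minus one water
_WATER = 18.0153
RESIDUE_MASS = {aa: protein_weights[aa] - _WATER for aa in AA20}

# side-chain and terminal pKa values (EMBOSS-style)
PKA_TERMINI = {"Nterm": 8.6, "Cterm": 3.6}
PKA_SIDECHAIN = {
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
}

# residues enriched in intrinsically disordered regions
DISORDER_PROMOTING = frozenset("DEKRSQPG")

# --- class alphabets -------------------------------------------------------

#: hydrophobic / hydrophilic / neutral / positive / negative partition used
#: for the 5-class composition and the grouped dipeptide alphabet
FIVE_CLASS_GROUPS = {
    "hydrophobic": frozenset("ACFILMVWY"),
    "hydrophilic": frozenset("NQST"),
    "neutral": frozenset("GP"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
}
FIVE_CLASS_ORDER = ("hydrophobic", "hydrophilic", "neutral", "positive", "negative")

#: grouped tripeptide alphabet; W assigned to the hydrophobic group so the
#: three groups partition all 20 residues
THREE_CLASS_GROUPS = {
    "hydrophobic": frozenset("FIMLVYCAW"),
    "hydrophilic": frozenset("RKNDEP"),
    "neutral": frozenset("THGSQ"),
}
THREE_CLASS_ORDER = ("hydrophobic", "hydrophilic", "neutral")

#: side-chain functional-group composition alphabet
TEN_FUNCTIONAL_GROUPS = {
    "sulfhydryl": frozenset("M"),
    "phenyl": frozenset("FWY"),
    "carboxyl": frozenset("DE"),
    "guanidyl": frozenset("R"),
    "imidazole": frozenset("H"),
    "primary_amino": frozenset("K"),
    "thiol": frozenset("C"),
    "amido": frozenset("NQ"),
    "hydroxyl": frozenset("ST"),
    "non_polar": frozenset("AGILPV"),
}
TEN_GROUP_ORDER = (
    "sulfhydryl", "phenyl", "carboxyl", "guanidyl", "imidazole",
    "primary_amino", "thiol", "amido", "hydroxyl", "non_polar",
)

#: the seven 3-class physicochemical partitions used by the
#: composition/transition/distribution descriptors
CTD_PARTITIONS = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}
CTD_ORDER = (
    "hydrophobicity", "vdw_volume", "polarity", "polarizability",
    "charge", "secondary_structure", "solvent_accessibility",
)

# residue classes for per-secondary-structure-state composition features
SS_AA_CLASSES = {
    "sulfur": frozenset("CM"),
    "aromatic": frozenset("FWY"),
    "charged": frozenset("DEHKR"),
    "polar": frozenset("NQST"),
    "small": frozenset("AGS"),
}
SS_AA_CLASS_ORDER = ("sulfur", "aromatic", "charged", "polar", "small")


def scale_vector(scale: dict[str, float]) -> np.ndarray:
    """Scale as a length-20 array in AA20 order."""
    return np.array([scale[aa] for aa in AA20], dtype=float)


def standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    """Zero-mean, unit-sd standardization over the 20 amino acids."""
    v = scale_vector(scale)
    z = (v - v.mean()) / v.std()
    return dict(zip(AA20, z))


# Grantham (1974) physicochemical distance: composition, polarity, volume
_GRANTHAM_COMPOSITION = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75,
    "Q": 0.89, "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0,
    "L": 0.0, "K": 0.33, "M": 0.0, "F": 0.0, "P": 0.39,
    "S": 1.42, "T": 0.71, "W": 0.13, "Y": 0.20, "V": 0.0,
}
_GRANTHAM_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0,
    "Q": 85.0, "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0,
    "L": 111.0, "K": 119.0, "M": 105.0, "F": 132.0, "P": 32.5,
    "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0,
}
_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399
_GRANTHAM_RHO = 50.723  # scales the mean inter-residue distance to ~100


def grantham_matrix() -> np.ndarray:
    """20x20 Grantham distance matrix (AA20 order, zero diagonal).

    Computed from D_ij = rho * sqrt(alpha dc^2 + beta dp^2 + gamma dv^2);
    reproduces the published table (e.g. Leu-Ile 5, Cys-Trp 215) to within
    rounding of the printed integers.
    """
    c = np.array([_GRANTHAM_COMPOSITION[a] for a in AA20])
    p = np.array([GRANTHAM_POLARITY[a] for a in AA20])
    v = np.array([_GRANTHAM_VOLUME[a] for a in AA20])
    d2 = (
        _GRANTHAM_ALPHA * np.subtract.outer(c, c) ** 2
        + _GRANTHAM_BETA * np.subtract.outer(p, p) ** 2
        + _GRANTHAM_GAMMA * np.subtract.outer(v, v) ** 2
    )
    m = _GRANTHAM_RHO * np.sqrt(d2)
    np.fill_diagonal(m, 0.0)
    return m


def physchem_distance_matrix() -> np.ndarray:
    """Synthetic residue-pair distance matrix (AA20 order, zero diagonal).

    A stand-in built from standardized hydropathy, hydrophilicity and side
    chain volume: the Euclidean distance in that 3-space, normalized so the
    largest pair distance is 1.  It plays the role a second sequence-order
    coupling matrix (Schneider-Wrede-like) plays in quasi-sequence-order
    descriptors; it is NOT the published Schneider-Wrede table.
    """
    cols = [
        scale_vector(KYTE_DOOLITTLE),
        scale_vector(APAAC_HYDROPHILICITY),
        scale_vector(VDW_VOLUME),
    ]
    z = np.stack([(c - c.mean()) / c.std() for c in cols], axis=1)
    diff = z[:, None, :] - z[None, :, :]
    m = np.sqrt((diff**2).sum(axis=2))
    m /= m.max()
    np.fill_diagonal(m, 0.0)
    return m
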