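"""Feature-encoder tests.

Each descriptor family is checked against an independent straight-loop
evaluation of its defining formula (written here, separately from the
vectorized implementations) on random sequences, plus hand-derived cases.
"""

import math

import numpy as np
import pytest

from crysprop.annotate import ResidueAnnotation, baseline_annotate
from crysprop.data.scales import (
    AA20,
    APAAC_HYDROPHILICITY,
    APAAC_HYDROPHOBICITY,
    CTD_ORDER,
    CTD_PARTITIONS,
    FLEXIBILITY,
    KYTE_DOOLITTLE,
    POLARIZABILITY,
    grantham_matrix,
    physchem_distance_matrix,
    standardize_scale,
)
from crysprop.features import (
    NON_AAINDEX_FEATURES,
    TOTAL_FEATURES,
    EncodingError,
    compute_pi,
    encode_aaindex_blocks,
    encode_all,
    encode_apaac,
    encode_autocorrelation,
    encode_compositions,
    encode_ctd,
    encode_dipeptide,
    encode_qso,
    encode_structure_blocks,
    encode_taap,
    net_charge,
)
from crysprop.seqio import ProteinRecord

from conftest import random_record

AUTOCORR_SCALES = (KYTE_DOOLITTLE, FLEXIBILITY, POLARIZABILITY)


# --- independent straight-loop oracles -------------------------------------

def naive_autocorrelation(seq):
    n = len(seq)
    nmb, moran, geary = [], [], []
    for scale in AUTOCORR_SCALES:
        zmap = standardize_scale(scale)
        z = [zmap[a] for a in seq]
        p = [scale[a] for a in seq]
        pbar = sum(p) / n
        var_n = sum((v - pbar) ** 2 for v in p) / n
        var_n1 = sum((v - pbar) ** 2 for v in p) / (n - 1) if n > 1 else 0.0
        for d in range(1, 31):
            if n <= d:
                nmb.append(0.0); moran.append(0.0); geary.append(0.0)
                continue
            nmb.append(sum(z[i] * z[i + d] for i in range(n - d)) / (n - d))
            if var_n == 0:
                moran.append(0.0)
            else:
                num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)) / (n - d)
                moran.append(num / var_n)
            if var_n1 == 0:
                geary.append(0.0)
            else:
                num = sum((p[i] - p[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
                geary.append(num / var_n1)
    return np.array(nmb + moran + geary)


def naive_ctd(seq):
    n = len(seq)
    out = {"c": [], "t": [], "d": []}
    for prop in CTD_ORDER:
        groups = CTD_PARTITIONS[prop]
        labels = []
        for a in seq:
            for g, members in enumerate(groups):
                if a in members:
                    labels.append(g)
        for g in range(3):
            out["c"].append(labels.count(g) / n)
        for r, s in ((0, 1), (0, 2), (1, 2)):
            count = sum(
                1
                for i in range(n - 1)
                if {labels[i], labels[i + 1]} == {r, s}
            )
            out["t"].append(count / (n - 1) if n > 1 else 0.0)
        for g in range(3):
            pos = [i + 1 for i, l in enumerate(labels) if l == g]
            if not pos:
                out["d"].extend([0.0] * 5)
                continue
            ks = [1] + [math.ceil(q * len(pos)) for q in (0.25, 0.5, 0.75, 1.0)]
            out["d"].extend(100.0 * pos[k - 1] / n for k in ks)
    return np.concatenate([out["c"], out["t"], out["d"]])


def naive_qso(seq, w=0.1):
    n = len(seq)
    idx = {a: i for i, a in enumerate(AA20)}
    out = []
    for dmat in (grantham_matrix(), physchem_distance_matrix()):
        taus = []
        for d in range(1, 31):
            if d >= n:
                taus.append(0.0)
            else:
                taus.append(
                    sum(dmat[idx[seq[i]], idx[seq[i + d]]] ** 2 for i in range(n - d))
                )
        freqs = [seq.count(a) / n for a in AA20]
        denom = sum(freqs) + w * sum(taus)
        out.extend(taus)
        out.extend(f / denom for f in freqs)
        out.extend(w * t / denom for t in taus)
    return np.array(out)


def naive_apaac(seq, lam=30, w=0.05):
    n = len(seq)
    h1map = standardize_scale(APAAC_HYDROPHOBICITY)
    h2map = standardize_scale(APAAC_HYDROPHILICITY)
    h1 = [h1map[a] for a in seq]
    h2 = [h2map[a] for a in seq]
    taus = []
    for j in range(1, lam + 1):
        if j >= n:
            taus.extend([0.0, 0.0])
        else:
            taus.append(sum(h1[i] * h1[i + j] for i in range(n - j)) / (n - j))
            taus.append(sum(h2[i] * h2[i + j] for i in range(n - j)) / (n - j))
    freqs = [seq.count(a) / n for a in AA20]
    denom = sum(freqs) + w * sum(abs(t) for t in taus)
    return np.array([f / denom for f in freqs] + [w * t / denom for t in taus])


def naive_dipeptide(seq):
    n = len(seq)
    out = np.zeros(400)
    if n < 2:
        return out
    for i in range(n - 1):
        out[AA20.index(seq[i]) * 20 + AA20.index(seq[i + 1])] += 1
    return out / (n - 1)


# --- oracle equivalence -----------------------------------------------------

@pytest.mark.parametrize(
    "encoder,oracle",
    [
        (encode_dipeptide, naive_dipeptide),
        (encode_autocorrelation, naive_autocorrelation),
        (encode_ctd, naive_ctd),
        (encode_qso, naive_qso),
        (encode_apaac, naive_apaac),
    ],
    ids=["dipeptide", "autocorrelation", "ctd", "qso", "apaac"],
)
def test_encoder_matches_straight_loop_oracle(encoder, oracle, rng):
    for i in range(20):
        rec = random_record(rng, int(rng.integers(31, 120)), f"r{i}")
        got = encoder(rec) if encoder is not encode_qso else encode_qso(rec)
        want = oracle(rec.sequence)
        np.testing.assert_allclose(got, want, atol=1e-10)


# --- hand-derived and structural cases --------------------------------------

class TestCompositions:
    def test_amino_acid_fractions(self):
        v = encode_compositions(ProteinRecord("x", "ACDC"))
        aa = dict(zip(AA20, v[:20]))
        assert aa["A"] == 0.25 and aa["C"] == 0.5 and aa["D"] == 0.25
        assert sum(aa.values()) == pytest.approx(1.0)

    def test_homogeneous_hydrophobic_tripeptides(self):
        v = encode_compositions(ProteinRecord("x", "AAAA"))
        tri = v[60:87]
        assert tri[0] == pytest.approx(1.0)  # (hyd,hyd,hyd) is the first cell
        assert tri[1:].sum() == pytest.approx(0.0)

    def test_charged_dipeptide_class_pair(self):
        v = encode_compositions(ProteinRecord("x", "KD"))
        gdip = v[35:60].reshape(5, 5)
        # five-class order: hydrophobic, hydrophilic, neutral, positive, negative
        assert gdip[3, 4] == pytest.approx(1.0)
        assert gdip.sum() == pytest.approx(1.0)

    def test_sub_blocks_sum_to_one_or_zero(self, rng):
        for i in range(10):
            rec = random_record(rng, int(rng.integers(3, 60)), f"c{i}")
            v = encode_compositions(rec)
            for block in (v[:20], v[20:25], v[25:35], v[35:60], v[60:87]):
                assert block.sum() == pytest.approx(1.0) or block.sum() == 0.0

    def test_aa_composition_shuffle_invariant_dipeptide_not(self, rng):
        rec = ProteinRecord("x", "ACDEFGHIKLAC")
        shuffled = "".join(rng.permutation(list(rec.sequence)))
        rec2 = ProteinRecord("y", shuffled)
        np.testing.assert_allclose(
            encode_compositions(rec)[:20], encode_compositions(rec2)[:20]
        )
        assert not np.allclose(
            encode_dipeptide(ProteinRecord("a", "ACAC")),
            encode_dipeptide(ProteinRecord("b", "AACC")),
        )


class TestAAindexBlocks:
    def test_constant_sequence_returns_scale_values(self, aaindex_table):
        rec = ProteinRecord("x", "AAAA")
        ann = ResidueAnnotation(length=4, ss="CCCC", disorder="OOOO", exposure="EEBB")
        seq_b, exp_b, bur_b = encode_aaindex_blocks(rec, ann, aaindex_table)
        expected = np.array([values["A"] for _, values in aaindex_table.entries])
        np.testing.assert_allclose(seq_b, expected)
        np.testing.assert_allclose(exp_b, expected)

    def test_exposed_and_buried_means_split(self, aaindex_table):
        rec = ProteinRecord("x", "AC")
        ann = ResidueAnnotation(length=2, ss="CC", disorder="OO", exposure="EB")
        _, exp_b, bur_b = encode_aaindex_blocks(rec, ann, aaindex_table)
        np.testing.assert_allclose(
            exp_b, [v["A"] for _, v in aaindex_table.entries]
        )
        np.testing.assert_allclose(
            bur_b, [v["C"] for _, v in aaindex_table.entries]
        )

    def test_empty_class_falls_back_to_sequence_mean(self, aaindex_table):
        rec = ProteinRecord("x", "ACDE")
        ann = ResidueAnnotation(length=4, ss="CCCC", disorder="OOOO", exposure="EEEE")
        seq_b, _, bur_b = encode_aaindex_blocks(rec, ann, aaindex_table)
        np.testing.assert_allclose(bur_b, seq_b)

    def test_missing_exposure_track_rejected(self, aaindex_table):
        rec = ProteinRecord("x", "ACDE")
        ann = ResidueAnnotation(length=4, ss="CCCC")
        with pytest.raises(EncodingError, match="exposure"):
            encode_aaindex_blocks(rec, ann, aaindex_table)


class TestAutocorrelationConventions:
    def test_homopolymer_nmb_constant_over_lags(self):
        v = encode_autocorrelation(ProteinRecord("x", "A" * 40))
        z = standardize_scale(KYTE_DOOLITTLE)["A"]
        np.testing.assert_allclose(v[:30], z * z, atol=1e-12)

    def test_homopolymer_moran_geary_zero(self):
        v = encode_autocorrelation(ProteinRecord("x", "A" * 40))
        np.testing.assert_allclose(v[90:270], 0.0)

    def test_alternating_sequence_moran_lag2_is_one(self):
        v = encode_autocorrelation(ProteinRecord("x", "AR" * 20))
        moran = v[90:180].reshape(3, 30)
        np.testing.assert_allclose(moran[:, 1], 1.0, atol=1e-12)


class TestCTDConventions:
    def test_homogeneous_distribution_quantiles(self):
        v = encode_ctd(ProteinRecord("x", "AAAA"))
        dist = v[42:147].reshape(7, 3, 5)
        # 'A' is class 2 (neutral) of the hydrophobicity partition
        np.testing.assert_allclose(dist[0, 1], [25, 25, 50, 75, 100])

    def test_single_class_sequence_has_no_transitions(self):
        v = encode_ctd(ProteinRecord("x", "AAAA"))
        assert v[21:42].sum() == 0.0

    def test_composition_triples_sum_to_one(self, rng):
        rec = random_record(rng, 50, "ctd")
        v = encode_ctd(rec)
        comp = v[:21].reshape(7, 3)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)


class TestQSOAndAPAAC:
    def test_homopolymer_qso_degenerates(self):
        v = encode_qso(ProteinRecord("x", "A" * 40))
        per_matrix = v.reshape(2, 80)
        for block in per_matrix:
            np.testing.assert_allclose(block[:30], 0.0)  # zero-diagonal couplings
            comp = dict(zip(AA20, block[30:50]))
            assert comp["A"] == pytest.approx(1.0)
            assert block[50:].sum() == pytest.approx(0.0)

    def test_qso_block_length_and_normalization(self, rng):
        rec = random_record(rng, 80, "q")
        v = encode_qso(rec)
        assert v.shape == (160,)
        for block in v.reshape(2, 80):
            assert block[30:].sum() == pytest.approx(1.0)

    def test_apaac_homopolymer_taus_are_squared_scales(self):
        v = encode_apaac(ProteinRecord("x", "A" * 50))
        h1 = standardize_scale(APAAC_HYDROPHOBICITY)["A"]
        h2 = standardize_scale(APAAC_HYDROPHILICITY)["A"]
        taus = v[20:] / v[20] if v[20] != 0 else v[20:]
        # tau pattern alternates h1^2, h2^2 before normalization
        ratio = (v[21] / v[20])
        assert ratio == pytest.approx((h2 * h2) / (h1 * h1))

    def test_apaac_sums_to_one_when_taus_nonnegative(self):
        v = encode_apaac(ProteinRecord("x", "A" * 50))
        assert v.shape == (80,)
        assert v.sum() == pytest.approx(1.0)


class TestTAAP:
    def test_homopolymer_returns_property_values(self):
        v = encode_taap(ProteinRecord("x", "AAAA"))
        expected = [KYTE_DOOLITTLE["A"], FLEXIBILITY["A"], POLARIZABILITY["A"]]
        np.testing.assert_allclose(v, expected)

    def test_concatenation_invariance(self):
        np.testing.assert_allclose(
            encode_taap(ProteinRecord("x", "ARAR")), encode_taap(ProteinRecord("y", "AR"))
        )


class TestIsoelectricPoint:
    def test_charge_at_pi_is_near_zero(self, rng):
        for i in range(5):
            rec = random_record(rng, 40, f"pi{i}")
            pi = compute_pi(rec)
            assert abs(net_charge(rec, pi)) < 1e-3

    def test_acidic_low_basic_high(self):
        assert compute_pi(ProteinRecord("d", "DDDD")) < 7
        assert compute_pi(ProteinRecord("k", "KKKK")) > 7

    def test_matches_grid_search_oracle(self):
        rec = ProteinRecord("x", "ACDEFGHIK")
        grid = np.arange(0.0, 14.0, 0.001)
        charges = np.array([net_charge(rec, ph) for ph in grid])
        oracle = grid[np.argmin(np.abs(charges))]
        assert compute_pi(rec) == pytest.approx(oracle, abs=1e-3)


class TestStructureBlocks:
    def test_exposure_run_statistics(self, manual_annotation):
        rec = ProteinRecord("x", "MKLVA")
        v = encode_structure_blocks(rec, manual_annotation)
        assert v[0] == pytest.approx(3 / 5)  # exposed fraction of EEBBE
        run_e = v[51:58]  # runs>= {1,2,4,8,16}/N, max, mean for the E track
        np.testing.assert_allclose(run_e, [2 / 5, 1 / 5, 0, 0, 0, 2.0, 1.5])

    def test_ss_segment_statistics(self, manual_annotation):
        rec = ProteinRecord("x", "MKLVA")
        v = encode_structure_blocks(rec, manual_annotation)
        ss = v[65:102]
        assert ss[36] == pytest.approx(2 / 5)  # total segments / N for CCHHH
        # per-state (mean, max, count/N) for H then E then C
        np.testing.assert_allclose(ss[3:6], [3.0, 3.0, 1 / 5])
        np.testing.assert_allclose(ss[9:12], [2.0, 2.0, 1 / 5])

    def test_sulfur_in_coil_frequency(self):
        rec = ProteinRecord("x", "MMMMM")
        ann = ResidueAnnotation(length=5, ss="CCCCC", disorder="OOOOO", exposure="BBBBB")
        v = encode_structure_blocks(rec, ann)
        ss = v[65:102]
        sulfur_in_coil = ss[21 + 10]  # third state's first residue-class slot
        assert sulfur_in_coil == pytest.approx(1.0)

    def test_unset_track_rejected(self):
        rec = ProteinRecord("x", "MKLVA")
        with pytest.raises(Exception, match="unset"):
            encode_structure_blocks(rec, ResidueAnnotation(length=5, ss="CCCCC"))


class TestFullEncoding:
    def test_vector_length_and_purity(self, aaindex_table, registry, sample_record, sample_annotation):
        v1 = encode_all(sample_record, sample_annotation, aaindex_table, registry)
        v2 = encode_all(sample_record, sample_annotation, aaindex_table, registry)
        assert v1.values.shape == (TOTAL_FEATURES,) == (2924,)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert np.all(np.isfinite(v1.values))

    def test_non_aaindex_remainder(self, registry):
        aaindex_total = sum(
            size for name, size in registry.block_sizes.items() if name.startswith("aaindex")
        )
        assert registry.total - aaindex_total == NON_AAINDEX_FEATURES == 1292

    def test_registry_block_arithmetic(self, registry):
        sizes = registry.block_sizes
        assert sizes["dipeptide"] == 400
        profeat = (
            sizes["dipeptide"] + sizes["nmbroto"] + sizes["moran"] + sizes["geary"]
            + sizes["ctd_c"] + sizes["ctd_t"] + sizes["ctd_d"]
            + sizes["qso"] + sizes["apaac"] + sizes["taap"]
        )
        assert profeat == 1060
        assert registry.total == 3 * 544 + 1060 + 232
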