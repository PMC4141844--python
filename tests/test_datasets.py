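import datetime as dt

import numpy as np
import pytest

from crysprop.datasets import (
    DatasetError,
    SyntheticSpec,
    TASKS,
    assign_class,
    build_task_dataset,
    classes_from_records,
    filter_trials,
    pairwise_identity,
    reduce_redundancy,
    simulate_planted,
    simulate_sequences,
    simulate_status_records,
    split_train_test,
)
from crysprop.seqio import ProteinRecord, StatusRecord


def _trial(target, status, date, trial="t1", method="X-ray", stop="current status: work stopped"):
    return StatusRecord(
        target_id=target, trial_id=trial, status=status,
        stop_date=dt.date.fromisoformat(date), method=method, stop_condition=stop,
    )


class TestFilterTrials:
    def test_pre_window_trial_removed(self):
        assert filter_trials([_trial("a", "soluble", "2005-06-01")]) == []

    def test_post_window_trial_removed(self):
        assert filter_trials([_trial("a", "soluble", "2011-02-01")]) == []

    def test_non_xray_removed(self):
        assert filter_trials([_trial("a", "soluble", "2008-01-01", method="NMR")]) == []

    def test_open_ended_trial_removed(self):
        assert filter_trials([_trial("a", "soluble", "2008-01-01", stop="in progress")]) == []

    def test_terminal_status_passes_without_stop_condition(self):
        kept = filter_trials([_trial("a", "in PDB", "2008-01-01", stop="")])
        assert len(kept) == 1

    def test_most_advanced_status_wins_regardless_of_date(self):
        kept = filter_trials([
            _trial("a", "expressed", "2008-01-01", trial="t1"),
            _trial("a", "soluble", "2007-01-01", trial="t2"),
        ])
        assert len(kept) == 1 and kept[0].status == "soluble"

    def test_latest_trial_kept_among_equal_statuses(self):
        kept = filter_trials([
            _trial("a", "purified", "2007-03-01", trial="t1"),
            _trial("a", "purified", "2009-03-01", trial="t2"),
        ])
        assert kept[0].trial_id == "t2"


class TestAssignClass:
    @pytest.mark.parametrize(
        "status,expected",
        [
            ("selected", "CLF"),
            ("cloned", "MF"),
            ("expressed", "MF"),
            ("soluble", "PF"),
            ("purified", "PF"),
            ("purification failed", "PF"),
            ("crystallization failed", "CF"),
            ("poor diffraction", "CF"),
            ("crystallized", "CF"),
            ("diffraction", "CF"),
            ("crystal structure", "CRYS"),
            ("structure successful", "CRYS"),
            ("in PDB", "CRYS"),
        ],
    )
    def test_five_class_mapping(self, status, expected):
        assert assign_class(status) == expected

    def test_matching_is_case_and_whitespace_insensitive(self):
        assert assign_class("  In PDB ") == "CRYS"

    def test_unknown_status_lists_vocabulary(self):
        with pytest.raises(DatasetError, match="selected"):
            assign_class("vitrified")


class TestTaskComposition:
    CLASSES = (
        {f"clf{i}": "CLF" for i in range(10)}
        | {f"mf{i}": "MF" for i in range(10)}
        | {f"pf{i}": "PF" for i in range(5)}
        | {f"cf{i}": "CF" for i in range(3)}
        | {f"crys{i}": "CRYS" for i in range(2)}
    )

    def test_purification_task_excludes_upstream_failures(self):
        ds = build_task_dataset(self.CLASSES, "PF")
        assert (ds.labels == 0).sum() == 5
        assert (ds.labels == 1).sum() == 5
        assert len(ds.excluded_ids) == 20

    def test_material_task_counts(self):
        ds = build_task_dataset(self.CLASSES, "MF")
        assert (ds.labels == 0).sum() == 20
        assert (ds.labels == 1).sum() == 10
        assert not ds.excluded_ids

    def test_crystallizable_task_counts(self):
        ds = build_task_dataset(self.CLASSES, "CRYS")
        assert (ds.labels == 0).sum() == 28
        assert (ds.labels == 1).sum() == 2

    def test_rows_plus_excluded_cover_all_targets(self):
        for task in TASKS:
            ds = build_task_dataset(self.CLASSES, task)
            assert len(ds.row_ids) + len(ds.excluded_ids) == len(self.CLASSES)

    def test_empty_side_rejected(self):
        with pytest.raises(DatasetError):
            build_task_dataset({"a": "CLF", "b": "MF"}, "CF")


class TestRedundancyReduction:
    def test_identical_sequences_collapse(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        records = [ProteinRecord("a", seq), ProteinRecord("b", seq)]
        assert len(reduce_redundancy(records, 0.4)) == 1

    def test_unrelated_sequences_both_kept(self):
        a = ProteinRecord("a", "MKKKKKKEEEEEEDDDDDDRRRRRR")
        b = ProteinRecord("b", "GAVLIFWPGAVLIFWPGAVLIFWPG")
        assert len(reduce_redundancy([a, b], 0.4)) == 2

    def test_representative_is_longest_member(self):
        long = ProteinRecord("long", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 2)
        short = ProteinRecord("short", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        reps = reduce_redundancy([short, long], 0.4)
        assert [r.id for r in reps] == ["long"]

    def test_identity_is_symmetric_and_bounded(self):
        a, b = "MKTAYIAKQRQ", "MKTAYIWKQRQ"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
        assert 0.0 <= pairwise_identity(a, b) <= 1.0


class TestSplit:
    @staticmethod
    def _dataset(n=600):
        from crysprop.datasets import LabeledDataset

        return LabeledDataset(
            task="CRYS",
            row_ids=[f"r{i}" for i in range(n)],
            labels=np.array([0, 1] * (n // 2)),
            excluded_ids=[],
            provenance={},
        )

    def test_five_sixths_one_sixth_partition(self):
        train, test = split_train_test(self._dataset(600), seed=0)
        assert len(train) == 500 and len(test) == 100
        assert not set(train) & set(test)
        assert set(train) | set(test) == {f"r{i}" for i in range(600)}

    def test_split_is_stratified(self):
        ds = self._dataset(600)
        label_of = dict(zip(ds.row_ids, ds.labels))
        train, test = split_train_test(ds, seed=1)
        assert sum(label_of[r] for r in test) == 50

    def test_same_seed_same_split(self):
        a = split_train_test(self._dataset(), seed=7)
        b = split_train_test(self._dataset(), seed=7)
        assert a == b

    def test_cross_set_identity_filter_drops_near_duplicates(self):
        from crysprop.datasets import LabeledDataset

        seqs = {f"r{i}": "".join(
            np.random.default_rng(i).choice(list("ACDEFGHIKLMNPQRSTVWY"), 30)
        ) for i in range(12)}
        ds = LabeledDataset(
            task="CRYS", row_ids=list(seqs), labels=np.array([0, 1] * 6),
            excluded_ids=[], provenance={},
        )
        train, test = split_train_test(ds, seed=0)
        seqs[test[0]] = seqs[train[0]]  # make one test row identical to a training row
        _, filtered = split_train_test(
            ds, seed=0, cross_identity_threshold=0.25, sequences=seqs
        )
        assert test[0] not in filtered

    def test_too_few_rows_rejected(self):
        with pytest.raises(DatasetError):
            split_train_test(_tiny(), seed=0)


def _tiny():
    from crysprop.datasets import LabeledDataset

    return LabeledDataset(
        task="CRYS", row_ids=["a", "b", "c", "d"], labels=np.array([0, 1, 0, 1]),
        excluded_ids=[], provenance={},
    )


class TestSimulators:
    def test_sequences_respect_spec(self):
        records = simulate_sequences(SyntheticSpec(n=100, length_range=(50, 300), seed=3))
        assert len(records) == 100
        assert all(50 <= r.n <= 300 for r in records)

    def test_sequences_deterministic(self):
        a = simulate_sequences(SyntheticSpec(n=20, seed=5))
        b = simulate_sequences(SyntheticSpec(n=20, seed=5))
        assert a == b

    def test_uniform_composition_within_binomial_bounds(self):
        records = simulate_sequences(SyntheticSpec(n=500, length_range=(200, 200), seed=9))
        residues = "".join(r.sequence for r in records)
        n = len(residues)
        sigma = np.sqrt(0.05 * 0.95 / n)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(residues.count(aa) / n - 0.05) < 3 * sigma

    def test_status_simulation_recovers_planted_classes(self):
        records, truth = simulate_status_records(
            300, {c: 0.2 for c in TASKS}, seed=4
        )
        classes = classes_from_records(filter_trials(records))
        recovered = np.mean([classes.get(t) == c for t, c in truth.items()])
        assert recovered >= 0.99

    def test_status_decoys_are_removed_by_filters(self):
        records, _ = simulate_status_records(200, {c: 0.2 for c in TASKS}, seed=8)
        kept_ids = {r.trial_id for r in filter_trials(records)}
        decoys = [
            r for r in records
            if r.stop_date.year == 2005 or r.method != "X-ray"
            or r.stop_condition == "work in progress"
        ]
        assert decoys  # generator actually plants decoys
        assert not kept_ids & {r.trial_id for r in decoys}

    def test_pure_class_mixture(self):
        records, truth = simulate_status_records(50, {"CLF": 1.0}, seed=2)
        classes = classes_from_records(filter_trials(records))
        assert set(classes.values()) == {"CLF"}

    def test_planted_table_shapes_and_truth(self):
        spec = SyntheticSpec(n=50, p=20, k=4, delta=1.0, rho=0.5, seed=6)
        table, labels, truth = simulate_planted(spec)
        assert table.values.shape == (50, 20)
        assert set(labels) == set(TASKS)
        for task in TASKS:
            assert len(truth[task]) == 4
            assert set(truth[task]) <= set(table.feature_ids)
        assert len(truth["latent"]) == 4

    def test_planted_null_is_chance_level(self):
        from crysprop.mlcore import cv_auc_score

        aucs = []
        for seed in range(10):
            table, labels, _ = simulate_planted(
                SyntheticSpec(n=100, p=10, k=3, delta=0.0, rho=0.0, seed=seed)
            )
            aucs.append(cv_auc_score(table.values, labels["CRYS"], folds=4, seed=seed))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_latent_correlation_raises_inter_task_label_agreement(self):
        def mean_offdiag_corr(rho):
            vals = []
            for seed in range(10):
                _, labels, _ = simulate_planted(
                    SyntheticSpec(n=400, p=30, k=5, delta=1.0, rho=rho, seed=seed)
                )
                mat = np.column_stack([labels[t] for t in TASKS]).astype(float)
                corr = np.corrcoef(mat, rowvar=False)
                vals.append(corr[np.triu_indices(5, 1)].mean())
            return np.mean(vals)

        assert mean_offdiag_corr(0.8) > mean_offdiag_corr(0.0)
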