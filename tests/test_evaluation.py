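import numpy as np
import pytest

from eegid.errors import DataShapeError, ScenarioError, SplitError
from eegid.evaluation import (
    FUSION_REGION_PAIRS,
    REGION_PAIRS,
    ConfusionMatrix,
    CVResult,
    MetricsReport,
    StudyCase,
    build_scenario,
    compute_metrics,
    confusion,
    enumerate_cases,
    finalize,
    kfold_partition,
    run_cv_case,
    shuffle_labels,
    split_dataset,
    split_dataset_by_record,
)
from eegid.model import TrainConfig
from eegid.preprocess import ALL_REGIONS, RegionSelection, SegmentSet

from .conftest import make_segment_set


def brute_force_metrics(counts):
    """Independent loop implementation of the one-vs-rest metric family."""
    counts = np.asarray(counts)
    K = counts.shape[0]
    total = counts.sum()
    accs, precs, recs = [], [], []
    for k in range(K):
        tp = counts[k][k]
        fp = sum(counts[i][k] for i in range(K)) - tp
        fn = sum(counts[k][j] for j in range(K)) - tp
        tn = total - tp - fp - fn
        accs.append((tp + tn) / total)
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
    mp = 100 * sum(precs) / K
    mr = 100 * sum(recs) / K
    f1 = 2 * mp * mr / (mp + mr) if mp + mr else 0.0
    return (
        100 * sum(accs) / K,
        mp,
        mr,
        f1,
        100 * np.trace(counts) / total,
    )


class TestConfusion:
    def test_identity(self):
        cm = confusion([0, 1, 2], [0, 1, 2], 3)
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_off_diagonal(self):
        cm = confusion([0, 0], [1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[0, 2], [0, 0]])

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 7, 200)
        y_pred = rng.integers(0, 7, 200)
        cm = confusion(y_true, y_pred, 7)
        tally = np.zeros((7, 7), dtype=int)
        for t, p in zip(y_true, y_pred):
            tally[t][p] += 1
        np.testing.assert_array_equal(cm.counts, tally)

    def test_length_mismatch(self):
        with pytest.raises(DataShapeError):
            confusion([0, 1], [0], 2)

    def test_out_of_range(self):
        with pytest.raises(DataShapeError):
            confusion([0, 5], [0, 1], 3)

    def test_one_vs_rest_sums(self):
        rng = np.random.default_rng(1)
        cm = ConfusionMatrix(rng.integers(0, 10, (4, 4)))
        for k in range(4):
            tp, fp, fn, tn = cm.one_vs_rest(k)
            assert tp + fp + fn + tn == cm.total


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionMatrix(np.diag([5, 5, 5])))
        for m in rep.as_dict().values():
            assert m == pytest.approx(100.0)

    def test_worked_three_class_example(self):
        # hand-evaluated one-vs-rest values for this 3x3 table
        cm = ConfusionMatrix([[4, 1, 0], [0, 5, 0], [1, 0, 4]])
        rep = compute_metrics(cm)
        assert rep.average_accuracy == pytest.approx(100 * 41 / 45, abs=0.01)
        assert rep.macro_precision == pytest.approx(87.78, abs=0.01)
        assert rep.macro_recall == pytest.approx(86.67, abs=0.01)
        assert rep.macro_f1 == pytest.approx(87.22, abs=0.01)
        assert rep.plain_accuracy == pytest.approx(86.67, abs=0.01)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            K = int(rng.integers(2, 11))
            counts = rng.integers(0, 30, (K, K))
            if counts.sum() == 0:
                counts[0, 0] = 1
            with np.errstate(all="ignore"):
                rep = compute_metrics(ConfusionMatrix(counts))
            expect = brute_force_metrics(counts)
            for got, want in zip(rep.as_dict().values(), expect):
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_transpose_swaps_precision_recall(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, (5, 5))
        a = compute_metrics(ConfusionMatrix(counts))
        b = compute_metrics(ConfusionMatrix(counts.T))
        assert a.macro_precision == pytest.approx(b.macro_recall, rel=1e-12)
        assert a.macro_recall == pytest.approx(b.macro_precision, rel=1e-12)

    def test_zero_denominator_warns_and_contributes_zero(self):
        # class 2 never predicted and never true -> precision and recall terms 0
        counts = np.array([[3, 0, 0], [0, 3, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-denominator"):
            rep = compute_metrics(ConfusionMatrix(counts))
        assert rep.macro_precision == pytest.approx(100 * 2 / 3, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DataShapeError):
            compute_metrics(ConfusionMatrix(np.zeros((3, 3), dtype=int)))

    def test_f1_is_harmonic_mean_of_macros(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 20, (6, 6))
        rep = compute_metrics(ConfusionMatrix(counts))
        expect = 2 * rep.macro_precision * rep.macro_recall / (rep.macro_precision + rep.macro_recall)
        assert rep.macro_f1 == pytest.approx(expect, rel=1e-12)


@pytest.fixture(scope="module")
def thousand_segments():
    return make_segment_set(n_per_class=50, n_classes=20, n_channels=2, window=16, seed=0)


class TestSplitDataset:
    def test_sizes(self, thousand_segments):
        tr, te = split_dataset(thousand_segments, 0.8, seed=0)
        assert len(tr) == 800 and len(te) == 200

    def test_partition_property(self, thousand_segments):
        tr, te = split_dataset(thousand_segments, 0.8, seed=0)
        all_prov = set(thousand_segments.provenance())
        tr_prov, te_prov = set(tr.provenance()), set(te.provenance())
        assert tr_prov | te_prov == all_prov
        assert not (tr_prov & te_prov)

    def test_stratification(self, thousand_segments):
        tr, _ = split_dataset(thousand_segments, 0.8, seed=0)
        for label in range(20):
            n = int((tr.subject_labels == label).sum())
            assert abs(n - 40) <= 1

    def test_deterministic(self, thousand_segments):
        a, _ = split_dataset(thousand_segments, 0.8, seed=5)
        b, _ = split_dataset(thousand_segments, 0.8, seed=5)
        np.testing.assert_array_equal(a.start_samples, b.start_samples)

    def test_invalid_fraction(self, thousand_segments):
        with pytest.raises(SplitError):
            split_dataset(thousand_segments, 1.2, seed=0)

    def test_small_class_warning(self):
        s = make_segment_set(3, 2, n_channels=2, window=8, seed=1)
        with pytest.warns(UserWarning, match="fewer than"):
            split_dataset(s, 0.5, seed=0)

    def test_by_record_blocks_contiguous(self):
        s = make_segment_set(10, 3, n_channels=2, window=8, seed=1)
        tr, te = split_dataset_by_record(s, 0.8, seed=0)
        assert len(tr) + len(te) == len(s)
        # within each record, every test start sample follows every train one
        for rid in np.unique(s.record_ids):
            tr_starts = tr.start_samples[tr.record_ids == rid]
            te_starts = te.start_samples[te.record_ids == rid]
            if len(tr_starts) and len(te_starts):
                assert tr_starts.max() < te_starts.min()


class TestKFold:
    def test_five_folds_of_160(self, thousand_segments):
        tr, _ = split_dataset(thousand_segments, 0.8, seed=0)
        folds = kfold_partition(tr, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(va) == 160 for _, va in folds)

    def test_each_segment_validated_once(self, thousand_segments):
        tr, _ = split_dataset(thousand_segments, 0.8, seed=0)
        folds = kfold_partition(tr, k=5, seed=0)
        seen = []
        for _, va in folds:
            seen.extend(va.provenance())
        assert len(seen) == len(tr)
        assert set(seen) == set(tr.provenance())

    def test_train_val_disjoint_per_fold(self, thousand_segments):
        tr, _ = split_dataset(thousand_segments, 0.8, seed=0)
        for ftr, fva in kfold_partition(tr, k=5, seed=0):
            assert not (set(ftr.provenance()) & set(fva.provenance()))

    def test_k_too_large(self):
        s = make_segment_set(2, 2, n_channels=2, window=8, seed=0)
        with pytest.raises(SplitError):
            kfold_partition(s, k=10, seed=0)

    def test_k_too_small(self, thousand_segments):
        with pytest.raises(SplitError):
            kfold_partition(thousand_segments, k=1, seed=0)


@pytest.fixture(scope="module")
def multi_task():
    parts = [
        make_segment_set(5, 3, n_channels=2, window=8, seed=i, task_id=t)
        for i, t in enumerate(["rest", "level1", "level2", "level3"])
    ]
    return SegmentSet.concatenate(parts)


class TestScenarios:
    def test_individual(self, multi_task):
        out = build_scenario(multi_task, "rest")
        assert set(out.task_ids) == {"rest"}
        assert len(out) == 15

    def test_game_fusion(self, multi_task):
        out = build_scenario(multi_task, "game_fusion")
        assert set(out.task_ids) == {"level1", "level2", "level3"}
        assert len(out) == 45

    def test_all_fusion(self, multi_task):
        rest = build_scenario(multi_task, "rest")
        game = build_scenario(multi_task, "game_fusion")
        out = build_scenario(multi_task, "all_fusion")
        assert len(out) == len(rest) + len(game)

    def test_missing_task(self, multi_task):
        only_rest = build_scenario(multi_task, "rest")
        with pytest.raises(ScenarioError):
            build_scenario(only_rest, "game_fusion")

    def test_unknown_scenario(self, multi_task):
        with pytest.raises(ScenarioError):
            build_scenario(multi_task, "nap")


class TestEnumerateCases:
    def test_total_104(self):
        assert len(enumerate_cases(("A", "B"))) == 104

    def test_decomposition(self):
        cases = enumerate_cases(("A",))
        assert len(cases) == 4 * (1 + 6 + 4) + 2 * (1 + 3)

    def test_six_pairs_four_singles(self):
        cases = enumerate_cases(("A",))
        rest = [c for c in cases if c.scenario == "rest"]
        assert sum(len(c.regions.regions) == 2 for c in rest) == 6
        assert sum(len(c.regions.regions) == 1 for c in rest) == 4

    def test_fusion_pairs_restricted(self):
        cases = enumerate_cases(("B",))
        fusion = [c for c in cases if c.scenario == "game_fusion"]
        assert len(fusion) == 4
        pairs = {frozenset(c.regions.regions) for c in fusion if len(c.regions.regions) == 2}
        assert pairs == {frozenset(p) for p in FUSION_REGION_PAIRS}

    def test_deterministic_order(self):
        assert [c.label() for c in enumerate_cases()] == [c.label() for c in enumerate_cases()]

    def test_invalid_fusion_pair_rejected(self):
        with pytest.raises(ScenarioError):
            StudyCase("A", "game_fusion", RegionSelection(("F", "C")))

    def test_invalid_triple_rejected(self):
        with pytest.raises(ScenarioError):
            StudyCase("A", "rest", RegionSelection(("F", "C", "P")))


@pytest.fixture(scope="module")
def toy_cohort():
    # perfectly separable 4-class toy with enough segments for CV
    return make_segment_set(n_per_class=40, n_classes=4, n_channels=8, window=250, seed=0)


class TestCVDriver:
    def test_perfect_separability(self, toy_cohort):
        case = StudyCase("A", "rest", ALL_REGIONS)
        res = run_cv_case(case, toy_cohort, tc=TrainConfig(max_epochs=20, seed=0), k=3)
        assert res.mean["average_accuracy"] >= 99.0
        assert res.mean["plain_accuracy"] >= 95.0

    def test_sd_zero_for_identical_folds(self):
        rep = MetricsReport(90.0, 80.0, 80.0, 80.0, 75.0)
        res = CVResult(StudyCase("A", "rest", ALL_REGIONS), [rep, rep, rep])
        assert all(v == 0.0 for v in res.sd.values())

    def test_finalize_provenance_and_accuracy(self, toy_cohort):
        case = StudyCase("A", "rest", ALL_REGIONS)
        report, model = finalize(
            case, toy_cohort, tc=TrainConfig(max_epochs=20, seed=0), internal_val_fraction=0.15
        )
        assert report.average_accuracy >= 99.0

    def test_finalize_degenerate_test_rejected(self):
        # subject 1 has so few segments that the by-record split leaves it
        # out of the test partition entirely
        a = make_segment_set(20, 1, n_channels=2, window=8, seed=0)
        b = make_segment_set(2, 1, n_channels=2, window=8, seed=1)
        b.subject_labels[:] = 1
        b.record_ids[:] = 99
        s = SegmentSet.concatenate([a, b])
        case = StudyCase("A", "rest", RegionSelection(("F",)))
        with pytest.raises(SplitError):
            finalize(case, s, tc=TrainConfig(max_epochs=1), split_by_record=True)


def test_shuffle_labels_permutes(thousand_segments):
    out = shuffle_labels(thousand_segments, seed=0)
    assert not np.array_equal(out.subject_labels, thousand_segments.subject_labels)
    assert sorted(out.subject_labels) == sorted(thousand_segments.subject_labels)
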