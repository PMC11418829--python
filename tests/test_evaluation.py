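"""Leave-one-patient-out protocol, aggregation, and metrics."""

import numpy as np
import pytest

import cardiokin as ck
from cardiokin.cine import CineSequence
from cardiokin.evaluation import (PipelineConfig, aggregate_patient,
                                  all_class_pairs, compute_metrics,
                                  lopo_split, render_report, run_lopo,
                                  write_report)


def _cohort(n_patients, slices_per_patient=1):
    rng = np.random.default_rng(0)
    return [CineSequence(frames=rng.random((4, 8, 8)),
                         patient_id=f"p{i:02d}", slice_index=s)
            for i in range(n_patients) for s in range(slices_per_patient)]


class TestSplit:
    @pytest.mark.parametrize("n", [2, 40])
    def test_one_fold_per_patient(self, n):
        folds = lopo_split(_cohort(n))
        assert len(folds) == n
        for train_ids, held in folds:
            assert held not in train_ids
            assert len(train_ids) == n - 1

    def test_folds_partition_the_cohort(self):
        folds = lopo_split(_cohort(7, slices_per_patient=3))
        held = [h for _, h in folds]
        assert sorted(held) == [f"p{i:02d}" for i in range(7)]
        assert len(set(held)) == 7

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            lopo_split(_cohort(1, slices_per_patient=5))

    def test_split_ignores_cohort_order(self):
        cohort = _cohort(5)
        shuffled = list(reversed(cohort))
        assert lopo_split(cohort) == lopo_split(shuffled)


class TestAggregation:
    @pytest.mark.parametrize("votes,expected", [
        (["N", "N", "DCM"], "N"),
        (["DCM", "N"], "DCM"),              # tie -> lexicographic
        (["HCM"] * 13, "HCM"),
    ])
    def test_majority_vote(self, votes, expected):
        assert aggregate_patient(votes) == expected

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])


class TestMetrics:
    def test_perfect_predictions(self):
        pairs = [("N", "N")] * 6 + [("DCM", "DCM")] * 4
        r = compute_metrics(pairs)
        assert r.as_percent() == {"accuracy": 100.0, "precision": 100.0,
                                  "recall": 100.0, "f1": 100.0}

    def test_hand_computed_binary_case(self):
        truths = ["P", "P", "P", "P", "N", "N", "N", "N"]
        preds = ["P", "P", "P", "N", "N", "N", "N", "P"]
        r = compute_metrics(list(zip(preds, truths)))
        assert r.as_percent() == {"accuracy": 75.0, "precision": 75.0,
                                  "recall": 75.0, "f1": 75.0}
        # confusion matrix rows (true class) sum to per-class counts
        assert r.confusion_matrix.sum(axis=1).tolist() == [4, 4]

    def test_degenerate_single_class_predictions(self):
        truths = ["A", "A", "B", "B"]
        preds = ["A", "A", "A", "A"]
        r = compute_metrics(list(zip(preds, truths)))
        assert r.accuracy == pytest.approx(0.5)

    def test_metrics_recomputable_from_confusion_matrix(self):
        pairs = [("N", "N"), ("N", "DCM"), ("DCM", "DCM"), ("DCM", "DCM")]
        r = compute_metrics(pairs)
        cm = r.confusion_matrix
        assert r.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            compute_metrics([("X", "N")], classes=("N", "DCM"))


@pytest.fixture(scope="module")
def pairwise_lopo():
    """Small end-to-end LOPO on an easy class pair (shared, ~20 s)."""
    cohort = [s for s in ck.generate_cohort(4, seed=21)
              if s.label in ("DCM", "N")]
    config = PipelineConfig.reduced()
    return run_lopo(cohort, "DCM:N", config=config, seed=0), cohort, config


class TestLopoRun:
    def test_fold_count_and_no_leakage(self, pairwise_lopo):
        (folds, report), cohort, _ = pairwise_lopo
        assert len(folds) == 8
        for fold in folds:
            assert fold.held_out_patient not in fold.train_patient_ids
            assert len(fold.train_patient_ids) == 7

    def test_easy_pair_classified_above_chance(self, pairwise_lopo):
        (_, report), _, _ = pairwise_lopo
        assert report.accuracy > 0.5
        assert report.n == 8

    def test_softmax_mode_runs_end_to_end(self):
        cohort = [s for s in ck.generate_cohort(2, seed=21)
                  if s.label in ("DCM", "N")]
        config = PipelineConfig.reduced(mode="softmax", channels=("div",))
        folds, report = run_lopo(cohort, "DCM:N", config=config, seed=0)
        assert len(folds) == 4
        assert 0.0 <= report.accuracy <= 1.0

    def test_cohort_order_does_not_change_report(self, pairwise_lopo):
        (_, report), cohort, config = pairwise_lopo
        _, again = run_lopo(list(reversed(cohort)), "DCM:N",
                            config=config, seed=0)
        assert render_report(again) == render_report(report)

    def test_report_files_written(self, pairwise_lopo, tmp_path):
        (_, report), _, _ = pairwise_lopo
        out = write_report(report, tmp_path / "rep")
        assert (out / "report.csv").exists()
        md = (out / "report.md").read_text()
        assert "DCM:N" in md and "ACC" in md

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            run_lopo(_cohort(4), "everything")


def test_ten_pairwise_tasks_enumerated():
    pairs = all_class_pairs()
    assert len(pairs) == 10
    assert "MINF:DCM" in pairs and "RV:N" in pairs
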