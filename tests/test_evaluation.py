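"""Confusion matrices, binomial CIs, ROC/AUC, ratings, threshold tables."""

import numpy as np
import pandas as pd
import pytest

from cellspm import (
    SpmConfig,
    auc_rating,
    confusion_matrix,
    loo_evaluate,
    overall_accuracy,
    roc_curve,
    run_report,
    sensitivity_error_table,
    write_report,
)
from cellspm.evaluation import ConfusionMatrix


def mann_whitney_auc(scores, correct):
    """Independent oracle: pairwise comparison probability with ties = 1/2."""
    pos = [s for s, c in zip(scores, correct) if c]
    neg = [s for s, c in zip(scores, correct) if not c]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def outcomes_from(pairs):
    """Build minimal leave-one-out outcomes from (true, predicted) labels."""
    from cellspm import PeakList, SpectrumRecord
    from cellspm.search import Hit, MatchResult, QueryOutcome

    out = []
    for k, (true, pred) in enumerate(pairs):
        rec = SpectrumRecord(
            id=f"q{k}", peaks=PeakList([100.0], [1.0]), genus=true,
            species=f"{true} sp", polarity="positive",
        )
        hit = Hit(reference_id=f"r{k}", score=0.9, genus=pred, species=f"{pred} sp")
        out.append(
            QueryOutcome(rec, MatchResult(f"q{k}", (hit,)), true, true == pred)
        )
    return out


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        cm = confusion_matrix(outcomes_from([("A", "A"), ("B", "B"), ("A", "A")]), "genus")
        assert np.trace(cm.counts) == 3 == cm.n_total

    def test_direct_tally(self):
        cm = confusion_matrix(outcomes_from([("A", "A"), ("A", "B"), ("B", "B")]), "genus")
        assert cm.labels == ("A", "B")
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_prediction_only_labels_get_zero_rows(self):
        cm = confusion_matrix(outcomes_from([("A", "C")]), "genus")
        assert cm.labels == ("A", "C")
        assert cm.counts[cm.labels.index("C"), :].sum() == 0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], "genus")


class TestOverallAccuracy:
    def test_perfect_ten_clopper_pearson(self):
        # exact interval for 10/10: lower bound (alpha/2)^(1/n) = 0.6915
        cm = ConfusionMatrix(("A",), np.array([[10]]))
        acc, lo, hi = overall_accuracy(cm)
        assert acc == 1.0
        assert lo == pytest.approx(0.6915, abs=2e-4)
        assert hi == 1.0

    def test_zero_of_ten(self):
        cm = ConfusionMatrix(("A", "B"), np.array([[0, 10], [0, 0]]))
        acc, lo, hi = overall_accuracy(cm)
        assert acc == 0.0 and lo == 0.0
        assert hi == pytest.approx(1 - 0.6915, abs=2e-4)

    def test_interval_brackets_accuracy(self):
        cm = ConfusionMatrix(("A", "B"), np.array([[7, 1], [2, 5]]))
        acc, lo, hi = overall_accuracy(cm)
        assert 0 <= lo <= acc <= hi <= 1


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.3, 0.2], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)
        # endpoints in FPR coordinates
        assert roc.fpr[0] == 0.0 and roc.fpr[-1] == 1.0
        assert roc.sensitivity[0] == 0.0 and roc.sensitivity[-1] == 1.0

    def test_interleaved_scores_give_half(self):
        roc = roc_curve([0.8, 0.8, 0.2, 0.2], [True, False, True, False])
        assert roc.auc == pytest.approx(0.5)

    def test_tied_scores_match_pairwise_oracle(self):
        scores = [0.9, 0.7, 0.7, 0.6, 0.5, 0.4]
        correct = [True, True, False, True, False, False]
        roc = roc_curve(scores, correct)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, correct))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_curve([0.9, 0.8], [True, True])

    def test_random_inputs_match_pairwise_oracle(self, rng):
        for _ in range(40):
            n = rng.integers(4, 50)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
            correct = rng.random(n) < 0.5
            if correct.all() or not correct.any():
                continue
            roc = roc_curve(scores, correct)
            assert roc.auc == pytest.approx(mann_whitney_auc(scores, correct))


class TestAucRating:
    @pytest.mark.parametrize(
        "auc,label",
        [
            (0.970, "excellent"),
            (0.850, "good"),
            (0.753, "fair"),
            (0.791, "fair"),
            (0.680, "poor"),
            (0.55, "fail"),
            (0.3, "worse-than-chance"),
            (0.9, "excellent"),
            (0.8, "good"),
        ],
    )
    def test_bands(self, auc, label):
        assert auc_rating(auc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_rating(1.2)


class TestSensitivityErrorTable:
    def test_all_correct(self):
        t = sensitivity_error_table([0.9, 0.5, 0.2], [True, True, True], [0.05])
        row = t.iloc[0]
        assert row.achievable and row.sensitivity == 1.0 and row.error_rate == 0.0

    def test_brute_force_example(self):
        # {0.9 correct, 0.8 correct, 0.7 incorrect}: smallest qualifying
        # threshold is the 0.75 midpoint; sensitivity 2/3
        t = sensitivity_error_table([0.9, 0.8, 0.7], [True, True, False], [0.05])
        row = t.iloc[0]
        assert row.threshold == pytest.approx(0.75)
        assert row.sensitivity == pytest.approx(2 / 3)

    def test_cap_one_gives_min_score_and_overall_accuracy(self):
        scores = [0.9, 0.8, 0.7, 0.4]
        correct = [True, False, True, False]
        t = sensitivity_error_table(scores, correct, [1.0])
        row = t.iloc[0]
        assert row.threshold == min(scores)
        assert row.sensitivity == pytest.approx(0.5)  # overall accuracy

    def test_unachievable_cap(self):
        t = sensitivity_error_table([0.9, 0.5], [False, False], [0.05])
        row = t.iloc[0]
        assert not row.achievable and row.sensitivity == 0.0

    def test_sensitivity_non_increasing_as_cap_tightens(self, rng):
        scores = rng.random(60)
        correct = scores + rng.normal(0, 0.3, 60) > 0.5
        caps = [0.5, 0.3, 0.2, 0.1, 0.05, 0.02]
        t = sensitivity_error_table(scores, correct, caps)
        sens = t.sensitivity.to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)


def test_genus_accuracy_bounds_species_accuracy(small_dataset):
    """On one species-level result set, scoring the same top hits at genus
    level can only help: within-genus species confusions become hits."""
    _, db, _, _, _ = small_dataset
    for pol in ("positive", "negative"):
        out = loo_evaluate(db, SpmConfig(level="species", polarity=pol, measure="Eu"))
        evaluable = [o for o in out if o.evaluable]
        species_acc = np.mean([o.correct for o in evaluable])
        genus_acc = np.mean(
            [o.result.top_hit.genus == o.record.genus for o in evaluable]
        )
        assert genus_acc >= species_acc


class TestRunReport:
    def test_report_structure_and_determinism(self, small_dataset, tmp_path):
        _, db, _, _, _ = small_dataset
        kwargs = dict(
            levels=("genus", "species"), polarities=("positive", "negative"),
            measures=("Cos", "Eu", "iEu"), seed=4,
        )
        report = run_report(db, **kwargs)
        assert len(report.entries) == 2 * 2 * 3
        for entry in report.entries:
            assert entry.n_queries > 0
            assert entry.confusion is not None
            assert entry.accuracy == pytest.approx(entry.confusion.accuracy)
        # determinism: an identical run yields identical result tables
        report2 = run_report(db, **kwargs)
        for e1, e2 in zip(report.entries, report2.entries):
            pd.testing.assert_frame_equal(e1.results, e2.results)

    def test_write_report_emits_tables_and_manifest(self, small_dataset, tmp_path):
        _, db, _, _, _ = small_dataset
        report = run_report(
            db, levels=("genus",), polarities=("positive",), measures=("Eu",), seed=4
        )
        out = write_report(report, tmp_path / "report", plots=False)
        assert (out / "summary.csv").exists()
        assert (out / "results.csv").exists()
        assert (out / "manifest.yaml").exists()
        summary = pd.read_csv(out / "summary.csv")
        assert set(summary.columns) >= {"accuracy", "auc", "auc_rating"}

    def test_all_correct_cell_noted_not_fatal(self):
        """A configuration where every query is correct cannot define a ROC;
        the entry carries a note instead of failing the whole report."""
        from cellspm import PeakList, SpectralDatabase, SpectrumRecord

        def rec(rid, mz, genus):
            return SpectrumRecord(
                id=rid, peaks=PeakList(mz, [1.0] * len(mz)), genus=genus,
                polarity="positive",
            )

        db = SpectralDatabase(
            [
                rec("A1", [100.0, 200.0], "Alpha"),
                rec("A2", [100.0, 200.0], "Alpha"),
                rec("B1", [400.0, 500.0], "Beta"),
                rec("B2", [400.0, 500.0], "Beta"),
            ]
        )
        report = run_report(
            db, levels=("genus",), polarities=("positive",), measures=("Cos",)
        )
        entry = report.entries[0]
        assert entry.accuracy == 1.0
        assert entry.roc_similarity is None
        assert any("single class" in n for n in entry.notes)
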