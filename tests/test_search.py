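"""Top-hit search, leave-one-out protocol, and bootstrap confidence."""

import numpy as np
import pytest

from cellspm import (
    PeakList,
    SpectralDatabase,
    SpectrumRecord,
    SpmConfig,
    bootstrap_spectrum,
    confidence_score,
    loo_evaluate,
    loo_evaluate_multi,
    search,
)


def record(rid, mz, inten, genus, species=None, polarity="positive"):
    return SpectrumRecord(
        id=rid, peaks=PeakList(mz, inten), genus=genus, species=species, polarity=polarity
    )


class TestSearch:
    def test_exact_copy_is_top_hit_with_score_one(self, tiny_db):
        query = record("Q", [100.0, 200.0, 300.0], [1.0, 0.5, 0.2], "Alpha", "Alpha one")
        result = search(query, tiny_db, SpmConfig(measure="Eu", level="species"))
        assert result.top_hit.reference_id in ("A1", "A2")
        assert result.top_hit.score == pytest.approx(1.0)
        assert len(result.hits) == 3

    def test_no_overlap_gives_zero_scores_tie_ordered_by_id(self, tiny_db):
        query = record("Q", [710.0, 820.0], [1.0, 0.5], "Gamma")
        result = search(query, tiny_db, SpmConfig())
        assert [h.score for h in result.hits] == [0.0, 0.0, 0.0]
        assert [h.reference_id for h in result.hits] == ["A1", "A2", "B1"]

    def test_ranking_matches_hand_computed_scores(self, tiny_db):
        # shares 2 of 3 peaks with the Alpha spectra, 1 of 3 with Beta
        query = record("Q", [100.0, 200.0, 650.0], [1.0, 0.5, 0.4], "Alpha")
        result = search(query, tiny_db, SpmConfig(measure="Cos"))
        from cellspm import score_pair

        expected = {
            rid: score_pair(query.peaks, tiny_db.get(rid).peaks, "Cos")
            for rid in ("A1", "A2", "B1")
        }
        got = {h.reference_id: h.score for h in result.hits}
        assert got == pytest.approx(expected)
        assert result.top_hit.reference_id == "A1"  # A1/A2 tie -> id ascending

    def test_no_eligible_references_is_an_error(self, tiny_db):
        query = record("Q", [100.0], [1.0], "Alpha", polarity="negative")
        with pytest.raises(ValueError, match="polarity"):
            search(query, tiny_db, SpmConfig(polarity="negative"))

    def test_species_level_requires_species_labels(self):
        db = SpectralDatabase(
            [
                record("G1", [100.0], [1.0], "Alpha"),  # genus-only
                record("S1", [100.0, 200.0], [1.0, 1.0], "Alpha", "Alpha one"),
                record("S2", [100.0, 200.0], [1.0, 1.0], "Alpha", "Alpha two"),
            ]
        )
        query = db.get("S1")
        result = search(query, db, SpmConfig(level="species"))
        assert {h.reference_id for h in result.hits} == {"S2"}


class TestLeaveOneOut:
    def test_identical_pair_both_correct(self):
        db = SpectralDatabase(
            [
                record("X1", [100.0, 200.0], [1.0, 0.5], "Alpha"),
                record("X2", [100.0, 200.0], [1.0, 0.5], "Alpha"),
            ]
        )
        out = loo_evaluate(db, SpmConfig())
        assert all(o.correct for o in out)
        assert all(o.result.top_hit.score == pytest.approx(1.0) for o in out)

    def test_same_spectra_different_labels_both_wrong(self):
        # adversarial sanity case forced by the definitions: the only
        # reference is an identical spectrum with another genus label
        db = SpectralDatabase(
            [
                record("X1", [100.0, 200.0], [1.0, 0.5], "Alpha"),
                record("X2", [100.0, 200.0], [1.0, 0.5], "Beta"),
            ]
        )
        out = loo_evaluate(db, SpmConfig())
        assert all(o.correct is False for o in out)
        assert all(o.result.top_hit.score == pytest.approx(1.0) for o in out)

    def test_query_never_matches_itself_and_polarity_respected(self, small_dataset):
        _, db, _, _, _ = small_dataset
        for pol in ("positive", "negative"):
            out = loo_evaluate(db, SpmConfig(polarity=pol, measure="Eu"))
            assert out, "expected evaluable queries"
            for o in out:
                assert o.result is not None
                assert all(h.reference_id != o.record.id for h in o.result.hits)
                assert all(db.get(h.reference_id).polarity == pol for h in o.result.hits)

    def test_single_record_polarity_is_unevaluable_not_dropped(self):
        db = SpectralDatabase(
            [
                record("P1", [100.0], [1.0], "Alpha"),
                record("N1", [100.0], [1.0], "Alpha", polarity="negative"),
                record("N2", [100.0], [1.0], "Alpha", polarity="negative"),
            ]
        )
        out = loo_evaluate(db, SpmConfig(polarity="positive"))
        assert len(out) == 1 and not out[0].evaluable and out[0].correct is None

    def test_multi_measure_matches_single_measure(self, tiny_db):
        multi = loo_evaluate_multi(tiny_db, SpmConfig(measure="Cos"), ["Cos", "iEu"])
        single = loo_evaluate(tiny_db, SpmConfig(measure="iEu"))
        for a, b in zip(multi["iEu"], single):
            assert a.result.top_hit == b.result.top_hit


class TestBootstrapSpectrum:
    def test_single_peak_spectrum_is_fixed_point(self, rng):
        p = PeakList([300.0], [0.7])
        rep = bootstrap_spectrum(p, rng)
        assert rep.mz.tolist() == [300.0] and rep.intensity.tolist() == [1.0]

    def test_support_is_subset_and_normalized(self, rng):
        p = PeakList(np.linspace(100, 900, 30), np.linspace(0.1, 1.0, 30))
        for _ in range(20):
            rep = bootstrap_spectrum(p, rng)
            assert set(rep.mz) <= set(p.mz)
            assert rep.intensity.max() == 1.0

    def test_two_peak_outcome_distribution_matches_enumeration(self):
        """n = 2 has four equally likely draws: both peaks survive with
        probability 1/2, each single peak with probability 1/4."""
        p = PeakList([100.0, 200.0], [1.0, 1.0])
        rng = np.random.default_rng(99)
        counts = {"both": 0, "first": 0, "second": 0}
        n = 4000
        for _ in range(n):
            rep = bootstrap_spectrum(p, rng)
            if rep.n_peaks == 2:
                counts["both"] += 1
            elif rep.mz[0] == 100.0:
                counts["first"] += 1
            else:
                counts["second"] += 1
        assert counts["both"] / n == pytest.approx(0.5, abs=0.03)
        assert counts["first"] / n == pytest.approx(0.25, abs=0.03)
        assert counts["second"] / n == pytest.approx(0.25, abs=0.03)

    def test_expected_survival_fraction(self, rng):
        # a peak is missed with probability (1 - 1/n)^n -> 1/e
        p = PeakList(np.linspace(100, 900, 50), np.ones(50))
        fracs = [bootstrap_spectrum(p, rng).n_peaks / 50 for _ in range(200)]
        assert np.mean(fracs) == pytest.approx(1 - np.exp(-1), abs=0.02)


class TestConfidence:
    def test_unambiguous_query_has_confidence_one(self, tiny_db):
        query = record("Q", [100.0, 200.0, 300.0], [1.0, 0.5, 0.2], "Alpha")
        res = confidence_score(query, tiny_db, SpmConfig(n_bootstrap=50, seed=3))
        assert res.confidence == 1.0
        assert res.top_hit_label == "Alpha"

    def test_single_bootstrap_is_zero_or_one(self, tiny_db):
        query = record("Q", [100.0, 650.0], [1.0, 0.9], "Alpha")
        res = confidence_score(query, tiny_db, SpmConfig(n_bootstrap=1, seed=3))
        assert res.confidence in (0.0, 1.0)

    def test_tie_competing_references_match_replay_oracle(self):
        """Two references each own one of the query's two peaks; the winner
        of each replicate is decided by which peaks survive. Replaying the
        same generator draws reproduces the confidence exactly."""
        db = SpectralDatabase(
            [
                record("RA", [100.0], [1.0], "Alpha"),
                record("RB", [200.0], [1.0], "Beta"),
            ]
        )
        query = record("Q", [100.0, 200.0], [1.0, 1.0], "Alpha")
        cfg = SpmConfig(n_bootstrap=200, seed=17)
        res = confidence_score(query, db, cfg)
        # replay: original top hit is RA (score tie, id ascending); a
        # replicate agrees unless it drew peak 2 twice (only RB matches)
        rng = np.random.default_rng(17)
        agree = 0
        for _ in range(cfg.n_bootstrap):
            draws = rng.integers(0, 2, 2)
            survives_first = 0 in draws
            agree += 1 if survives_first else 0
        assert res.confidence == agree / cfg.n_bootstrap
        assert res.confidence == pytest.approx(0.75, abs=0.08)

    def test_reproducible_given_seed(self, small_dataset):
        _, db, _, _, _ = small_dataset
        query = next(iter(db))
        cfg = SpmConfig(level="species", n_bootstrap=25, seed=5)
        r1 = confidence_score(query, db, cfg)
        r2 = confidence_score(query, db, cfg)
        assert r1 == r2

    def test_monte_carlo_error_shrinks_with_replicates(self):
        """The spread of the confidence estimate across independent runs
        scales as 1/sqrt(n_bootstrap)."""
        db = SpectralDatabase(
            [
                record("RA", [100.0], [1.0], "Alpha"),
                record("RB", [200.0], [1.0], "Beta"),
            ]
        )
        query = record("Q", [100.0, 200.0], [1.0, 1.0], "Alpha")
        sds = []
        for n_boot in (16, 256):
            vals = []
            for s in range(40):
                cfg = SpmConfig(n_bootstrap=n_boot, seed=1000 + s)
                vals.append(confidence_score(query, db, cfg).confidence)
            sds.append(np.std(vals))
        ratio = sds[0] / sds[1]  # expect ~ sqrt(256/16) = 4
        assert 2.0 < ratio < 8.0
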