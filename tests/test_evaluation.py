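import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adscan import (
    ORIGINAL,
    AnnotationEntry,
    EvaluationReport,
    PermutationConfig,
    ProteinRecord,
    composition_ttest,
    evaluate,
    motif_shuffle_enrichment,
    permutation_test,
    predict_proteome,
    variant_scan,
)
from adscan.predictor import BoundaryModel, from_anchors
from adscan.synthetic import build_segment
from adscan.tiling import Tile


class TestEvaluationReport:
    @pytest.mark.parametrize(
        "tp,fp,fn,ppv,tpr,f",
        [
            # published confusion counts for the improved trapezoid model:
            # full benchmark and the restricted no-long-domain benchmark
            (110, 436, 409, 0.201, 0.212, 0.207),
            (101, 38, 159, 0.727, 0.388, 0.506),
        ],
    )
    def test_rates_from_confusion_counts(self, tp, fp, fn, ppv, tpr, f):
        report = EvaluationReport(tp=tp, fp=fp, fn=fn)
        assert report.ppv == pytest.approx(ppv, abs=5e-4)
        assert report.tpr == pytest.approx(tpr, abs=5e-4)
        assert report.f_score == pytest.approx(f, abs=5e-4)

    def test_degenerate_zero_counts(self):
        report = EvaluationReport(tp=0, fp=0, fn=0)
        assert report.ppv == report.tpr == report.f_score == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_invariants_on_fuzzed_counts(self, tp, fp, fn):
        report = EvaluationReport(tp=tp, fp=fp, fn=fn)
        assert report.tp + report.fp == report.n_predictions
        assert report.tp_truth + report.fn == report.n_truth
        for rate in (report.ppv, report.tpr, report.f_score):
            assert 0.0 <= rate <= 1.0


class TestEvaluate:
    def test_perfect_predictions(self, planted):
        proteome, truth = planted
        report = evaluate(truth, truth, proteome)
        assert report.ppv == report.tpr == report.f_score == 1.0

    def test_counts_and_protein_level_tn(self):
        proteome = [ProteinRecord(f"P{i}", "A" * 50) for i in range(5)]
        preds = [AnnotationEntry("P0", 1, 10), AnnotationEntry("P1", 1, 10)]
        truth = [AnnotationEntry("P0", 5, 20), AnnotationEntry("P2", 1, 10)]
        report = evaluate(preds, truth, proteome)
        assert (report.tp, report.fp) == (1, 1)
        assert (report.tp_truth, report.fn) == (1, 1)
        assert report.tn == 2  # P3, P4 carry neither predictions nor truth

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate([AnnotationEntry("P1", 1, 9)], [], [])


class TestPermutationTest:
    def test_reproducible_under_fixed_seed(self, planted):
        proteome, truth = planted
        preds = predict_proteome(proteome, ORIGINAL)
        config = PermutationConfig(n_permutations=99, seed=5)
        r1 = permutation_test(preds, truth, proteome, config)
        r2 = permutation_test(preds, truth, proteome, config)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_counts, r2.null_counts)

    def test_p_in_unit_interval_never_zero(self, planted):
        proteome, truth = planted
        preds = predict_proteome(proteome, ORIGINAL)
        res = permutation_test(preds, truth, proteome, PermutationConfig(49, seed=1))
        assert 0.0 < res.p_value <= 1.0

    def test_perfect_overlap_attains_minimum_p(self, planted):
        """Truth used as its own predictions: the observed count is maximal
        and sparse truth means no null draw ties it, so p = 1/(N+1)."""
        proteome, truth = planted
        res = permutation_test(truth, truth, proteome, PermutationConfig(199, seed=2))
        assert res.observed == len(truth)
        assert res.p_value == pytest.approx(1 / 200)

    def test_profile_preservation(self, planted):
        """Null layouts preserve the per-accession count and length
        distribution of the predictions."""
        from adscan.evaluation import _profiles, sample_null_layout

        proteome, truth = planted
        profiles = _profiles(truth)
        rng = np.random.default_rng(0)
        layout = sample_null_layout(rng, proteome, profiles)
        null_lengths = sorted(e - s + 1 for _, s, e in layout)
        assert null_lengths == sorted(t.length for t in truth)

    def test_region_longer_than_every_protein_errors(self):
        proteome = [ProteinRecord("P1", "A" * 40)]
        preds = [AnnotationEntry("P1", 1, 40)]
        truth = [AnnotationEntry("P1", 1, 10)]
        short = [ProteinRecord("P1", "A" * 20)]
        with pytest.raises(RuntimeError):
            permutation_test(preds, truth, short, PermutationConfig(9, seed=0))


class TestCompositionTTest:
    @staticmethod
    def tiles_from(seqs):
        return [Tile("T", 1, len(s), s) for s in seqs]

    def test_identical_groups_not_significant(self):
        seqs = ["DEWL" + "G" * 35, "KKLL" + "G" * 35, "WFYL" + "G" * 35]
        table = composition_ttest(self.tiles_from(seqs), self.tiles_from(seqs),
                                  features=["net_charge", "L", "W"])
        assert (table["statistic"].abs() < 1e-12).all()
        assert (table["p_bonferroni"] == 1.0).all()

    def test_zero_variance_in_both_groups_flagged(self):
        a = self.tiles_from(["G" * 39, "G" * 39])
        b = self.tiles_from(["L" + "G" * 38, "L" + "G" * 38])
        table = composition_ttest(a, b, features=["L"])
        assert not table.loc[0, "defined"]

    def test_planted_mean_shift_detected(self, rng):
        """Group A tiles carry ~2 extra leucines on average; the L feature
        must be flagged at Bonferroni-corrected p < 0.01 and with the right
        sign, while an unshifted feature stays quiet."""
        def random_tiles(n, extra_l):
            tiles = []
            for _ in range(n):
                n_l = rng.binomial(6, 0.5) + extra_l
                rest = rng.choice(list("GSTANQPDEK"), size=39 - n_l)
                seq = "".join(rest) + "L" * n_l
                tiles.append(Tile("T", 1, 39, seq))
            return tiles

        a, b = random_tiles(500, 2), random_tiles(500, 0)
        table = composition_ttest(a, b, features=["L", "K"]).set_index("feature")
        assert table.loc["L", "p_bonferroni"] < 0.01
        assert table.loc["L", "statistic"] > 0  # enrichment in group A
        assert table.loc["K", "p_bonferroni"] > 0.01  # unshifted feature quiet
        assert len(a[0].sequence) == 39

    def test_too_few_tiles_rejected(self):
        t = self.tiles_from(["G" * 39])
        with pytest.raises(ValueError):
            composition_ttest(t, t)


class TestMotifShuffle:
    def test_alternating_sp_has_small_p(self):
        """Observed SP count of SPSPSPSP is 4; only 1 of the 70 equally
        likely S/P arrangements achieves 4, so the exact null tail is
        1/70 ~ 0.014 and the sampled p must sit near it."""
        arrangements = set(itertools.permutations("SSSSPPPP"))
        exact = sum(
            1 for arr in arrangements
            if sum(1 for i in range(7) if arr[i] == "S" and arr[i + 1] == "P") >= 4
        ) / len(arrangements)
        assert exact == pytest.approx(1 / 70)
        table = motif_shuffle_enrichment(["SPSPSPSP"], motifs=["SP"],
                                         n_shuffles=999, seed=3)
        row = table.set_index("motif").loc["SP"]
        assert row["observed"] == 4
        assert row["null_mean"] < 4
        assert row["p_value"] < 0.05

    def test_absent_motif_gives_p_one(self):
        table = motif_shuffle_enrichment(["AAAAAAAA"], motifs=["SP"],
                                         n_shuffles=99, seed=0)
        row = table.set_index("motif").loc["SP"]
        assert row["observed"] == 0 and row["p_value"] == 1.0

    def test_overlapping_occurrences_counted(self):
        from adscan.evaluation import _count_motif

        assert _count_motif("SSS", "SS") == 2
        assert _count_motif("SPSP", "SP") == 2

    def test_reproducible_under_seed(self):
        kwargs = dict(motifs=["SP", "SQ"], n_shuffles=200, seed=11)
        t1 = motif_shuffle_enrichment(["SPQSPQSS"], **kwargs)
        t2 = motif_shuffle_enrichment(["SPQSPQSS"], **kwargs)
        assert t1.equals(t2)


class TestVariantScan:
    def test_leucine_variant_recovers_leucine_plants(self, rng):
        """On a proteome whose plants pair acidity with leucines only, the
        {L}-axis variant (thresholds re-derived from anchors) attains
        sensitivity 1 while a {W}-axis variant finds nothing."""
        background = lambda n: "".join(rng.choice(list("GSTANQP"), size=n))
        plant = "L" * 8 + "D" * 10 + "G" * 21  # charge -10, L count 8, no W/F/Y
        proteome, truth = [], []
        for i in range(8):
            pad = background(120)
            seq = pad[:40] + plant + pad[79:]
            proteome.append(ProteinRecord(f"P{i}", seq))
            truth.append(AnnotationEntry(f"P{i}", 41, 79))
        anchor1 = build_segment(-9, 0, 39) [:29] + "L" * 10  # charge -9, 10 L
        anchor2 = "L" * 7 + "D" * 13 + "G" * 19  # charge -13, 7 L
        variants = [
            ("L-axis", from_anchors(anchor1, anchor2, "L", mode="corner")),
            ("W-axis", BoundaryModel(residue_set="W", charge_max=-9, hydro_min=7)),
        ]
        table = variant_scan(proteome, truth, variants).set_index("variant")
        assert table.loc["L-axis", "sensitivity"] == 1.0
        assert table.loc["W-axis", "n_predictions"] == 0

    def test_duplicate_variants_identical_rows(self, planted):
        proteome, truth = planted
        table = variant_scan(proteome, truth, [("a", ORIGINAL), ("b", ORIGINAL)])
        a = table.drop(columns="variant").iloc[0]
        b = table.drop(columns="variant").iloc[1]
        assert a.equals(b)

    def test_empty_proteome_all_zero(self):
        table = variant_scan([], [AnnotationEntry("P1", 1, 10)], [("a", ORIGINAL)])
        assert (table[["n_predictions", "overlap_count"]] == 0).all().all()

    def test_empty_variant_list_rejected(self, planted):
        proteome, truth = planted
        with pytest.raises(ValueError):
            variant_scan(proteome, truth, [])
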