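"""Evaluation-statistics unit and property tests.

Independent oracles: naive per-epoch tallies for confusion matrices and
one-vs-rest metrics, direct p_o/p_e computation (and sklearn) for
Cohen's kappa.
"""

import math

import numpy as np
import pytest

from somnoseq.metrics import (
    ConfusionMatrix,
    PairwiseAgreement,
    accuracy,
    agreement_table,
    cohens_kappa,
    collapse_stages,
    collapsed_confusion,
    confusion,
    consensus_analysis,
    evaluate,
    groupwise_evaluate,
    hypnogram_summary,
    is_undefined,
    kappa_band,
    sleep_wake_metrics,
    stage_metrics,
    stage_specific_agreement,
)
from somnoseq.stages import Hypnogram, Stage

from conftest import SEED, random_hypnogram_pair


def toy_2class_matrix() -> ConfusionMatrix:
    """[[40,10],[20,30]] embedded in 5x5 on stages (W, N1)."""
    m = np.zeros((5, 5), dtype=int)
    m[0, 0], m[0, 1], m[1, 0], m[1, 1] = 40, 10, 20, 30
    return ConfusionMatrix(m)


class TestConfusion:
    def test_identical_hypnograms_are_diagonal(self):
        h = Hypnogram([0, 1, 2, 3, 4, 2, 3])
        cm = confusion(h, h)
        assert np.trace(cm.counts) == 7
        assert cm.counts.sum() == 7

    def test_constant_disagreement_fills_single_cell(self):
        a = Hypnogram([0] * 9)
        b = Hypnogram([4] * 9)
        cm = confusion(a, b)
        assert cm.counts[0, 4] == 9 and cm.total == 9

    def test_matches_double_loop_tally(self):
        rng = np.random.default_rng(SEED)
        a, b = random_hypnogram_pair(rng, 500)
        cm = confusion(a, b)
        expected = np.zeros((5, 5), dtype=int)
        for i, j in zip(a.codes, b.codes):
            expected[i, j] += 1
        assert np.array_equal(cm.counts, expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths differ"):
            confusion(Hypnogram([0, 1]), Hypnogram([0]))


class TestAccuracyKappa:
    def test_diagonal_matrix_scores_one(self):
        cm = confusion(Hypnogram([0, 1, 2]), Hypnogram([0, 1, 2]))
        assert accuracy(cm) == 1.0
        assert cohens_kappa(cm) == pytest.approx(1.0)

    def test_toy_matrix_hand_arithmetic(self):
        cm = toy_2class_matrix()
        assert accuracy(cm) == pytest.approx(0.70)
        # p_o = 0.7, p_e = 0.6*0.5 + 0.4*0.5 = 0.5 -> kappa = 0.4
        assert cohens_kappa(cm) == pytest.approx(0.40)

    def test_zero_diagonal_scores_zero(self):
        m = np.zeros((5, 5), dtype=int)
        m[0, 1] = 10
        assert accuracy(ConfusionMatrix(m)) == 0.0

    def test_constant_compared_scoring_gives_kappa_zero(self):
        ref = Hypnogram([0, 0, 1, 2, 3, 4])
        pred = Hypnogram([2] * 6)
        assert cohens_kappa(confusion(ref, pred)) == pytest.approx(0.0)

    def test_identical_constant_scorings_undefined(self):
        cm = confusion(Hypnogram([2] * 5), Hypnogram([2] * 5))
        with pytest.raises(ValueError, match="constant"):
            cohens_kappa(cm)

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((5, 5), dtype=int))
        with pytest.raises(ValueError):
            accuracy(cm)

    def test_kappa_equals_raw_pair_oracle_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(SEED)
        for _ in range(50):
            n = int(rng.integers(10, 2000))
            a, b = random_hypnogram_pair(rng, n)
            cm = confusion(a, b)
            p_o = np.mean(a.codes == b.codes)
            p_e = sum(np.mean(a.codes == s) * np.mean(b.codes == s)
                      for s in range(5))
            if p_e >= 1:
                continue
            expected = (p_o - p_e) / (1 - p_e)
            assert cohens_kappa(cm) == pytest.approx(expected, abs=1e-12)
            assert cohens_kappa(cm) == pytest.approx(
                cohen_kappa_score(a.codes, b.codes), abs=1e-10)


class TestKappaBand:
    @pytest.mark.parametrize("kappa,remark", [
        (0.78, "Substantial"),
        (0.82, "Almost Perfect"),
        (0.80, "Substantial"),       # upper bound is inclusive
        (0.60, "Moderate"),
        (0.0, "Poor"),
        (-0.5, "Poor"),
        (0.05, "Slight"),
        (0.30, "Fair"),
        (1.0, "Almost Perfect"),
    ])
    def test_landis_koch_bands(self, kappa, remark):
        assert kappa_band(kappa) == remark

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.2)


class TestStageMetrics:
    def test_diagonal_matrix_all_ones(self):
        cm = confusion(Hypnogram([0, 1, 2, 3, 4]), Hypnogram([0, 1, 2, 3, 4]))
        for s in Stage:
            m = stage_metrics(cm, s)
            assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_absent_stage_yields_undefined_markers(self):
        cm = confusion(Hypnogram([0, 0, 2]), Hypnogram([0, 2, 2]))
        m = stage_metrics(cm, Stage.R)
        assert is_undefined(m.sensitivity) and is_undefined(m.ppv)
        assert m.specificity == 1.0

    def test_matches_binarized_tally_oracle(self):
        rng = np.random.default_rng(SEED)
        a, b = random_hypnogram_pair(rng, 400)
        cm = confusion(a, b)
        for s in range(5):
            ref = a.codes == s
            pred = b.codes == s
            tp = np.sum(ref & pred)
            fn = np.sum(ref & ~pred)
            fp = np.sum(~ref & pred)
            tn = np.sum(~ref & ~pred)
            m = stage_metrics(cm, s)
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.ppv == pytest.approx(tp / (tp + fp))
            assert m.npv == pytest.approx(tn / (tn + fn))

    def test_counts_reconstruct_total_for_every_stage(self):
        rng = np.random.default_rng(SEED + 1)
        cm = ConfusionMatrix(rng.integers(0, 50, (5, 5)))
        for s in range(5):
            tp = cm.counts[s, s]
            fn = cm.counts[s].sum() - tp
            fp = cm.counts[:, s].sum() - tp
            tn = cm.total - tp - fn - fp
            assert tp + fn + fp + tn == cm.total


class TestSleepWake:
    def test_duality_identity_holds_exactly(self):
        rng = np.random.default_rng(SEED)
        for _ in range(200):
            cm = ConfusionMatrix(rng.integers(0, 100, (5, 5)))
            sens, spec = sleep_wake_metrics(cm)
            w = stage_metrics(cm, Stage.W)
            assert sens == w.specificity
            assert spec == w.sensitivity

    def test_diagonal_matrix_is_perfect(self):
        cm = confusion(Hypnogram([0, 1, 2, 3, 4]), Hypnogram([0, 1, 2, 3, 4]))
        assert sleep_wake_metrics(cm) == (1.0, 1.0)

    def test_matches_collapse_then_tally_oracle(self):
        rng = np.random.default_rng(SEED + 2)
        for _ in range(20):
            a, b = random_hypnogram_pair(rng, 300)
            sens, spec = sleep_wake_metrics(confusion(a, b))
            ref_sleep = a.codes != 0
            pred_sleep = b.codes != 0
            tp = np.sum(ref_sleep & pred_sleep)
            fn = np.sum(ref_sleep & ~pred_sleep)
            tn = np.sum(~ref_sleep & ~pred_sleep)
            fp = np.sum(~ref_sleep & pred_sleep)
            assert sens == pytest.approx(tp / (tp + fn))
            assert spec == pytest.approx(tn / (tn + fp))


class TestCollapse:
    def test_scheme_definitions(self):
        h = Hypnogram([0, 1, 2, 3, 4])
        four = collapse_stages(h, "4-stage")
        three = collapse_stages(h, "3-stage")
        assert list(four.codes) == [0, 1, 1, 2, 3]   # W, N1+N2, N1+N2, N3, R
        assert list(three.codes) == [0, 1, 1, 1, 2]  # W, NREM, NREM, NREM, R

    def test_accuracy_nondecreasing_under_collapse(self):
        rng = np.random.default_rng(SEED)
        for _ in range(100):
            a, b = random_hypnogram_pair(rng, 200)
            acc5 = accuracy(confusion(a, b))
            acc4 = accuracy(collapsed_confusion(a, b, "4-stage"))
            acc3 = accuracy(collapsed_confusion(a, b, "3-stage"))
            assert acc5 <= acc4 <= acc3

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            collapse_stages(Hypnogram([0]), "2-stage")


class TestStageSpecificAgreement:
    def test_identical_hypnograms_agree_fully(self):
        h = Hypnogram([0, 1, 2, 3, 4])
        agr = stage_specific_agreement(h, h)
        assert all(v == 1.0 for v in agr.values())

    def test_fixed_reference_hand_count(self):
        a = Hypnogram([0, 0, 2, 2])
        b = Hypnogram([0, 2, 2, 0])
        agr = stage_specific_agreement(a, b, "fixed-reference")
        assert agr["W"] == pytest.approx(0.5)
        assert agr["N2"] == pytest.approx(0.5)

    def test_symmetric_average_order_invariant_but_fixed_is_not(self):
        # counterexample: asymmetric confusion pattern
        a = Hypnogram([0, 0, 0, 2])
        b = Hypnogram([0, 2, 2, 2])
        sym_ab = stage_specific_agreement(a, b, "symmetric-average")
        sym_ba = stage_specific_agreement(b, a, "symmetric-average")
        assert sym_ab == pytest.approx(sym_ba, nan_ok=True)
        fix_ab = stage_specific_agreement(a, b, "fixed-reference")
        fix_ba = stage_specific_agreement(b, a, "fixed-reference")
        assert fix_ab["W"] != fix_ba["W"]


class TestConsensus:
    def test_full_agreement_all_ones(self):
        h = Hypnogram([0, 1, 2, 3, 4, 2])
        rep = consensus_analysis(h, h, h)
        assert rep.consensus_fraction == 1.0
        assert rep.consensus_accuracy == 1.0
        assert rep.match_at_least_one == 1.0

    def test_disjoint_scorers_give_empty_consensus(self):
        s1 = Hypnogram([0, 1, 2])
        s2 = Hypnogram([1, 2, 3])
        rep = consensus_analysis(s1, s2, s1)
        assert rep.consensus_fraction == 0.0
        assert is_undefined(rep.consensus_accuracy)

    def test_matches_per_epoch_scan_oracle(self):
        rng = np.random.default_rng(SEED)
        s1, s2 = random_hypnogram_pair(rng, 10_000)
        auto = Hypnogram(rng.integers(0, 5, 10_000), "auto")
        rep = consensus_analysis(s1, s2, auto)
        cons = match_any = in_cons_match = n_cons = 0
        for x, y, z in zip(s1.codes, s2.codes, auto.codes):
            if x == y:
                n_cons += 1
                in_cons_match += (z == x)
            if z == x or z == y:
                match_any += 1
        assert rep.consensus_fraction == pytest.approx(n_cons / 10_000)
        assert rep.consensus_accuracy == pytest.approx(in_cons_match / n_cons)
        assert rep.match_at_least_one == pytest.approx(match_any / 10_000)


class TestHypnogramSummary:
    def test_all_wake(self):
        s = hypnogram_summary(Hypnogram([0] * 10))
        assert s.tst_min == 0.0 and s.sleep_efficiency_pct == 0.0

    def test_full_night_no_wake(self):
        s = hypnogram_summary(Hypnogram([2] * 960))
        assert s.tst_min == 480.0 and s.sleep_efficiency_pct == 100.0

    def test_rounded_percentages_sum_to_100(self):
        rng = np.random.default_rng(SEED)
        for _ in range(50):
            h = Hypnogram(rng.integers(0, 5, int(rng.integers(50, 2000))))
            s = hypnogram_summary(h)
            rounded = sum(round(v, 1) for v in s.stage_percentages.values())
            assert rounded == pytest.approx(100.0, abs=0.3)


class TestGroupwise:
    def _cms(self, rng, ids):
        return {i: ConfusionMatrix(rng.integers(1, 20, (5, 5))) for i in ids}

    def test_single_group_equals_pool(self):
        rng = np.random.default_rng(SEED)
        cms = self._cms(rng, ["a", "b"])
        meta = {i: {"group": "SDB", "ahi": 2.0} for i in cms}
        reports = groupwise_evaluate(cms, meta)
        assert reports["SDB"].accuracy == reports["all"].accuracy
        assert "control" not in reports

    def test_group_matrices_sum_to_pool(self):
        rng = np.random.default_rng(SEED)
        cms = self._cms(rng, ["a", "b", "c", "d"])
        meta = {
            "a": {"group": "SDB", "ahi": 0.5},
            "b": {"group": "control", "ahi": 1.0},   # boundary: goes to >= 1
            "c": {"group": "SDB", "ahi": 3.0},
            "d": {"group": "control", "ahi": 0.0},
        }
        reports = groupwise_evaluate(cms, meta)
        total = reports["all"].confusion.counts
        assert np.array_equal(
            reports["SDB"].confusion.counts + reports["control"].confusion.counts,
            total)
        assert np.array_equal(
            reports["ahi>=1"].confusion.counts + reports["ahi<1"].confusion.counts,
            total)
        # AHI exactly 1.0 counted in the >= 1 group
        assert reports["ahi>=1"].n_epochs == (
            cms["b"].total + cms["c"].total)

    def test_missing_metadata_names_recording(self):
        rng = np.random.default_rng(SEED)
        cms = self._cms(rng, ["x"])
        with pytest.raises(KeyError, match="x"):
            groupwise_evaluate(cms, {})


class TestAgreementTable:
    def test_symmetric_overall_agreement(self):
        rng = np.random.default_rng(SEED)
        a, b = random_hypnogram_pair(rng, 500)
        t1 = agreement_table({"A": a, "B": b})["A vs B"]
        t2 = agreement_table({"B": b, "A": a})["B vs A"]
        assert t1.percent_agreement == pytest.approx(t2.percent_agreement)
        assert t1.kappa == pytest.approx(t2.kappa)

    def test_report_serialization_replaces_nan(self):
        cm = confusion(Hypnogram([0, 0, 2]), Hypnogram([0, 2, 2]))
        d = evaluate(cm).to_dict()
        assert d["per_stage"]["R"]["sensitivity"] is None
        assert isinstance(d["accuracy"], float)
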