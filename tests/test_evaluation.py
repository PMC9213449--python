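"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from mtppi.evaluation import (
    DegenerateMetricError,
    accuracy,
    auc_pr,
    auc_roc,
    compare_auc_one_sided,
    f1_score,
    hanley_mcneil_se,
    mcc,
    pcc,
    per_protein_analysis,
    precision,
    recall,
    specificity,
)


def pairwise_auc_oracle(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(tie) by explicit enumeration."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def rank_ap_oracle(scores, labels):
    """Average precision by an explicit walk over unique thresholds:
    AP = sum_k (R_k - R_{k-1}) P_k, tied scores sharing one threshold."""
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        sel = scores >= t
        tp = labels[sel].sum()
        prec = tp / sel.sum()
        rec = tp / n_pos
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


class TestAucRoc:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.3, 0.2])
        y = np.array([1, 1, 0, 0])
        assert auc_roc(s, y, np.ones(4, bool)) == 1.0

    def test_all_tied_scores_give_half(self):
        s = np.full(6, 0.4)
        y = np.array([1, 0, 1, 0, 1, 0])
        assert auc_roc(s, y, np.ones(6, bool)) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        s = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        got = auc_roc(s, y, np.ones(n, bool))
        assert got == pytest.approx(pairwise_auc_oracle(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.random(40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        m = np.ones(40, bool)
        base = auc_roc(s, y, m)
        assert auc_roc(np.exp(3 * s), y, m) == pytest.approx(base)
        assert auc_roc(np.log(s + 1e-9), y, m) == pytest.approx(base)

    def test_masked_residues_excluded(self):
        s = np.array([0.9, 0.1, 0.0, 1.0])
        y = np.array([1, 0, 1, 0])
        m = np.array([True, True, False, False])
        assert auc_roc(s, y, m) == 1.0

    def test_degenerate_composition_raises(self):
        with pytest.raises(DegenerateMetricError):
            auc_roc(np.array([0.5, 0.6]), np.array([1, 1]), np.ones(2, bool))


class TestAucPr:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_rank_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 50))
        s = rng.random(n)
        y = rng.integers(0, 2, size=n)
        if y.sum() == 0:
            y[0] = 1
        got = auc_pr(s, y, np.ones(n, bool))
        assert got == pytest.approx(rank_ap_oracle(s, y), abs=1e-12)


class TestThresholdMetrics:
    def test_hand_confusion_table(self):
        """TP=3 FP=1 FN=1 TN=5: precision 0.75, recall 0.75, spec 5/6,
        F1 0.75, ACC 0.8 and the closed-form MCC."""
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.3, 0.2, 0.1, 0.05, 0.04, 0.03])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = np.ones(10, bool)
        assert precision(s, y, m) == pytest.approx(0.75)
        assert recall(s, y, m) == pytest.approx(0.75)
        assert specificity(s, y, m) == pytest.approx(5.0 / 6.0)
        assert f1_score(s, y, m) == pytest.approx(0.75)
        assert accuracy(s, y, m) == pytest.approx(0.8)
        tp, fp, fn, tn = 3, 1, 1, 5
        expected_mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc(s, y, m) == pytest.approx(expected_mcc)

    def test_identities_against_recomputed_tables(self):
        rng = np.random.default_rng(8)
        s = rng.random(200)
        y = rng.integers(0, 2, size=200)
        m = rng.random(200) < 0.8
        tp = int(((s >= 0.5) & (y == 1) & m).sum())
        fp = int(((s >= 0.5) & (y == 0) & m).sum())
        fn = int(((s < 0.5) & (y == 1) & m).sum())
        tn = int(((s < 0.5) & (y == 0) & m).sum())
        assert accuracy(s, y, m) == pytest.approx((tp + tn) / m.sum())
        p, r = precision(s, y, m), recall(s, y, m)
        assert f1_score(s, y, m) == pytest.approx(2 * p * r / (p + r))


class TestPcc:
    def test_exact_prediction_gives_one(self):
        t = np.array([0.1, 0.4, 0.9, 0.3])
        assert pcc(t.copy(), t, np.ones(4, bool)) == pytest.approx(1.0)

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(12)
        p = rng.random(30)
        t = p + rng.normal(scale=0.1, size=30)
        m = np.ones(30, bool)
        assert pcc(3.0 * p + 7.0, t, m) == pytest.approx(pcc(p, t, m))

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateMetricError):
            pcc(np.full(5, 0.3), np.arange(5.0), np.ones(5, bool))


class TestCompareAuc:
    def test_equal_aucs_give_exactly_half(self):
        assert compare_auc_one_sided(0.75, 50, 300, 0.75, 40, 200) == 0.5

    def test_large_samples_large_gap_p_near_zero(self):
        p = compare_auc_one_sided(0.9, 5000, 30000, 0.6, 5000, 30000)
        assert p < 1e-12

    def test_worked_instance_matches_hand_formula(self):
        """Fixed instance recomputed through the published SE formula."""
        auc1, n1p, n1n = 0.80, 60, 300
        auc2, n2p, n2n = 0.72, 55, 280

        def se(a, npos, nneg):
            q1 = a / (2 - a)
            q2 = 2 * a * a / (1 + a)
            return np.sqrt(
                (a * (1 - a) + (npos - 1) * (q1 - a * a)
                 + (nneg - 1) * (q2 - a * a)) / (npos * nneg)
            )

        z = (auc1 - auc2) / np.hypot(se(auc1, n1p, n1n), se(auc2, n2p, n2n))
        expected = stats.norm.sf(z)
        got = compare_auc_one_sided(auc1, n1p, n1n, auc2, n2p, n2n)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_se_positive_and_shrinks_with_n(self):
        small = hanley_mcneil_se(0.75, 20, 100)
        large = hanley_mcneil_se(0.75, 200, 1000)
        assert 0 < large < small

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_one_sided(1.2, 10, 10, 0.5, 10, 10)
        with pytest.raises(ValueError):
            compare_auc_one_sided(0.8, 0, 10, 0.5, 10, 10)


class TestPerProteinAnalysis:
    def test_rows_and_regressions(self, small_dataset):
        records = [r for r in small_dataset if r.is_ppi_annotated][:10]
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(3):
            rep = {}
            for r in records:
                rep[r.protein_id] = {
                    "IF": rng.random(r.length),
                    "BU": rng.random(r.length),
                    "S3": rng.dirichlet(np.ones(3), size=r.length),
                    "SA": rng.random(r.length),
                }
            reps.append(rep)
        rows, regs = per_protein_analysis(reps, records)
        assert len(rows) == len(records)
        for row in rows:
            if row.mean_if_auc is not None:
                assert 0.0 <= row.mean_if_auc <= 1.0
            assert row.n_interface_residues == int(
                (np.asarray(
                    next(r for r in records
                         if r.protein_id == row.protein_id).labels["IF"]) == 1
                 ).sum()
            )
        for task, fit in regs.items():
            assert 0.0 <= fit["r_squared"] <= 1.0

    def test_regression_of_y_on_itself_gives_r2_one(self):
        xs = np.linspace(0.2, 0.9, 10)
        fit = stats.linregress(xs, xs)
        assert fit.rvalue ** 2 == pytest.approx(1.0)

    def test_ols_oracle_on_fixed_table(self):
        """Hand OLS on a fixed 10-point table matches linregress-based R^2."""
        x = np.array([0.2, 0.3, 0.35, 0.4, 0.5, 0.55, 0.6, 0.7, 0.8, 0.9])
        y = np.array([0.5, 0.45, 0.6, 0.55, 0.65, 0.6, 0.7, 0.75, 0.7, 0.85])
        xb, yb = x.mean(), y.mean()
        beta = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
        alpha = yb - beta * xb
        ss_res = ((y - (alpha + beta * x)) ** 2).sum()
        ss_tot = ((y - yb) ** 2).sum()
        r2_hand = 1 - ss_res / ss_tot
        fit = stats.linregress(x, y)
        assert fit.rvalue ** 2 == pytest.approx(r2_hand, abs=1e-12)

    def test_zero_interface_protein_flagged_undefined(self, small_dataset):
        rec = next(r for r in small_dataset if r.is_ppi_annotated).copy()
        rec.labels["IF"] = np.zeros(rec.length, dtype=np.int8)
        rng = np.random.default_rng(1)
        reps = [
            {rec.protein_id: {"IF": rng.random(rec.length)}} for _ in range(2)
        ]
        rows, regs = per_protein_analysis(reps, [rec])
        assert rows[0].mean_if_auc is None
        assert regs == {}

    def test_single_repeat_rejected(self, small_dataset):
        rec = small_dataset[0]
        with pytest.raises(ValueError, match="repeats"):
            per_protein_analysis([{}], [rec])
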