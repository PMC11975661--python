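"""Agreement statistics against independent brute-force implementations."""

import json
import math

import numpy as np
import pytest

from dsca.agreement import (ConfusionCounts, bland_altman,
                            classification_metrics, mae, pearson,
                            pool_confusion, render_reports)
from dsca.quant import AreaRecord


def make_records(true, pred):
    return [AreaRecord(slice_id=f"s{i}", patient_id=f"p{i}",
                       area_true_mm2=t, area_pred_mm2=p, pixel_spacing_mm=1.0)
            for i, (t, p) in enumerate(zip(true, pred))]


# -- brute-force reference implementations (explicit loops, no shared code) --

def brute_confusion(pred_masks, truth_masks):
    tp = fp = tn = fn = 0
    for pred, truth in zip(pred_masks, truth_masks):
        for i in range(pred.shape[0]):
            for j in range(pred.shape[1]):
                p, t = pred[i, j] > 0, truth[i, j] > 0
                if p and t:
                    tp += 1
                elif p and not t:
                    fp += 1
                elif not p and t:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, tn, fn


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def brute_sd(values):
    n = len(values)
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


class TestConfusion:
    def test_perfect_prediction(self):
        masks = [(np.random.default_rng(0).random((6, 6)) > 0.5).astype(float)]
        c = pool_confusion(masks, masks)
        assert c.fp == c.fn == 0
        assert c.tp + c.tn == 36

    def test_inverted_prediction(self):
        truth = (np.random.default_rng(1).random((6, 6)) > 0.5).astype(float)
        c = pool_confusion([1 - truth], [truth])
        assert c.tp == c.tn == 0

    def test_two_by_two_enumeration(self):
        truth = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[1.0, 1.0], [0.0, 0.0]])
        c = pool_confusion([pred], [truth])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 2, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pool_confusion([np.zeros((2, 2))], [np.zeros((3, 3))])

    def test_slice_order_invariance(self, random_mask_pairs):
        preds = [p for p, _ in random_mask_pairs]
        truths = [t for _, t in random_mask_pairs]
        a = classification_metrics(pool_confusion(preds, truths))
        b = classification_metrics(pool_confusion(preds[::-1], truths[::-1]))
        assert (a.accuracy, a.precision, a.recall, a.f1) == \
               (b.accuracy, b.precision, b.recall, b.f1)


class TestClassificationMetrics:
    @pytest.mark.parametrize("precision,recall,f1", [
        (0.7673, 0.9943, 0.8662),   # plain encoder-decoder, main data
        (0.8966, 0.9996, 0.9453),   # multi-resolution variant, main data
        (0.7966, 0.9903, 0.8829),   # attention variant, main data
        (0.7867, 0.9871, 0.8756),   # attention variant, external validation
    ])
    def test_f1_is_harmonic_mean_of_published_rows(self, precision, recall, f1):
        assert 2 * precision * recall / (precision + recall) == pytest.approx(f1, abs=1e-4)

    def test_perfect_metrics(self):
        m = classification_metrics(ConfusionCounts(tp=10, tn=90))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_fallbacks(self):
        m = classification_metrics(ConfusionCounts(tn=100))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts())


class TestMae:
    def test_exact_prediction(self):
        assert mae(make_records([100, 200], [100, 200])) == 0.0

    def test_sign_blindness(self):
        assert mae(make_records([100, 200], [110, 190])) == 10.0

    def test_hand_arithmetic(self):
        recs = make_records([100, 200, 300], [110, 190, 330])
        assert mae(recs) == pytest.approx(50 / 3, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        true = [100.0, 150.0, 210.0]
        assert pearson(make_records(true, true)) == pytest.approx(1.0)
        neg = [300.0 - t for t in true]
        assert pearson(make_records(true, neg)) == pytest.approx(-1.0)

    def test_hand_example(self):
        r = pearson(make_records([1, 2, 3], [2, 4, 7]))
        assert r == pytest.approx(0.9934, abs=5e-5)
        assert r == pytest.approx(brute_pearson([2, 4, 7], [1, 2, 3]), abs=1e-12)

    def test_constant_series_warns_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(pearson(make_records([1, 2, 3], [5, 5, 5])))

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            pearson(make_records([1, 2], [1, 2]))


class TestBlandAltman:
    def test_published_limits_imply_mean(self):
        # limits (4.2782, 63.9832) -> mean difference at their midpoint
        assert (4.2782 + 63.9832) / 2 == pytest.approx(34.1307, abs=5e-5)

    def test_constant_differences_collapse_limits(self):
        rep = bland_altman(make_records([100, 200, 300], [107, 207, 307]))
        assert rep.mean_diff_mm2 == pytest.approx(7.0)
        assert rep.sd_diff_mm2 == 0.0
        assert rep.loa_low == rep.loa_high == pytest.approx(7.0)

    def test_two_point_hand_arithmetic(self):
        rep = bland_altman(make_records([10.0, 10.0], [11.0, 13.0]))
        assert rep.mean_diff_mm2 == pytest.approx(2.0)
        assert rep.sd_diff_mm2 == pytest.approx(math.sqrt(2))
        assert rep.loa_low == pytest.approx(2 - 1.96 * math.sqrt(2))
        assert rep.loa_high == pytest.approx(2 + 1.96 * math.sqrt(2))

    def test_difference_sign_is_pred_minus_true(self):
        rep = bland_altman(make_records([100.0, 100.0], [120.0, 140.0]))
        assert rep.mean_diff_mm2 == pytest.approx(30.0)  # overestimation positive

    def test_invariant_ordering(self):
        rng = np.random.default_rng(8)
        recs = make_records(rng.uniform(50, 300, 30), rng.uniform(50, 300, 30))
        rep = bland_altman(recs)
        assert rep.loa_low <= rep.mean_diff_mm2 <= rep.loa_high
        assert rep.n == 30


def test_statistics_match_bruteforce_on_random_instances():
    """All reported statistics agree with explicit-loop references to 1e-10."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(3, 51))
        true = rng.uniform(50, 300, n)
        pred = true + rng.normal(0, 20, n)
        recs = make_records(true, pred)

        diffs = [p - t for t, p in zip(true, pred)]
        assert mae(recs) == pytest.approx(sum(abs(d) for d in diffs) / n, abs=1e-10)
        assert pearson(recs) == pytest.approx(brute_pearson(pred, true), abs=1e-10)
        rep = bland_altman(recs)
        assert rep.mean_diff_mm2 == pytest.approx(sum(diffs) / n, abs=1e-10)
        sd = brute_sd(diffs)
        assert rep.sd_diff_mm2 == pytest.approx(sd, abs=1e-10)
        assert rep.loa_low == pytest.approx(sum(diffs) / n - 1.96 * sd, abs=1e-10)
        assert rep.loa_high == pytest.approx(sum(diffs) / n + 1.96 * sd, abs=1e-10)


def test_pixel_metrics_match_bruteforce(random_mask_pairs):
    preds = [p for p, _ in random_mask_pairs]
    truths = [t for _, t in random_mask_pairs]
    c = pool_confusion(preds, truths)
    tp, fp, tn, fn = brute_confusion(preds, truths)
    assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
    m = classification_metrics(c)
    assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn), abs=1e-10)
    assert m.precision == pytest.approx(tp / (tp + fp), abs=1e-10)
    assert m.recall == pytest.approx(tp / (tp + fn), abs=1e-10)
    p, r = tp / (tp + fp), tp / (tp + fn)
    assert m.f1 == pytest.approx(2 * p * r / (p + r), abs=1e-10)


def test_limits_cover_95_percent_of_normal_differences():
    """~95% of i.i.d. normal differences fall inside the computed limits."""
    rng = np.random.default_rng(2024)
    n = 10_000
    true = rng.uniform(50, 300, n)
    pred = true + rng.normal(5.0, 12.0, n)
    rep = bland_altman(make_records(true, pred))
    inside = np.mean((rep.diffs >= rep.loa_low) & (rep.diffs <= rep.loa_high))
    assert 0.93 <= inside <= 0.97


class TestRenderReports:
    def test_writes_all_artifacts(self, tmp_path):
        rng = np.random.default_rng(5)
        true = rng.uniform(50, 300, 12)
        recs = make_records(true, true + rng.normal(0, 10, 12))
        rep = bland_altman(recs)
        rows = [{"model": "unet", "dataset": "phantom", "accuracy": 0.99,
                 "precision": 0.9, "recall": 0.95, "f1": 0.924, "mae_mm2": 8.0}]
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.8).astype(float)
        written = render_reports(rows, rep, recs, tmp_path / "out",
                                 examples=[(img, mask, mask, recs[0])])
        for key in ("metrics_csv", "agreement_json", "scatter_png",
                    "bland_altman_png", "triptych_00"):
            assert written[key].exists()
        summary = json.loads(written["agreement_json"].read_text())
        assert summary["mean_diff_mm2"] == pytest.approx(rep.mean_diff_mm2)
        assert summary["n"] == 12

    def test_metrics_csv_row_count(self, tmp_path):
        recs = make_records([100, 150, 200], [101, 149, 202])
        rep = bland_altman(recs)
        rows = [{"model": m, "dataset": d, "accuracy": 1, "precision": 1,
                 "recall": 1, "f1": 1, "mae_mm2": 0}
                for m in ("a", "b") for d in ("main", "external")]
        written = render_reports(rows, rep, recs, tmp_path)
        import pandas as pd

        assert len(pd.read_csv(written["metrics_csv"])) == 4
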