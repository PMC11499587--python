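import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from plotpheno.detect import DetectionInstance, DetectionSet
from plotpheno.errors import UndefinedMetricError
from plotpheno.metrics import (
    average_precision,
    average_recall,
    box_iou,
    classification_metrics,
    euclidean_distance,
    grid_agreement,
    iou,
    match_detections,
    pr_curve,
    precision_recall,
    regression_metrics,
    relative_improvement,
    sampling_stability,
)


def ds(boxes, scores=None):
    scores = scores or [1.0] * len(boxes)
    return DetectionSet(
        [DetectionInstance(box=tuple(b), score=s) for b, s in zip(boxes, scores)]
    )


def random_sets(rng, n_pred, n_gt, span=60):
    def rand_boxes(n):
        out = []
        for _ in range(n):
            x0, y0 = rng.uniform(0, span, 2)
            w, h = rng.uniform(5, 20, 2)
            out.append((x0, y0, x0 + w, y0 + h))
        return out

    return (
        ds(rand_boxes(n_pred), list(rng.uniform(0.1, 1.0, n_pred))),
        ds(rand_boxes(n_gt)),
    )


def matching_oracle_sets(rng, n_pred, n_gt, cell=40.0):
    """Prediction/ground-truth pairs with mutually disjoint ground truths.

    With disjoint ground truths and an IoU threshold of 0.5, a prediction
    can clear the threshold against at most one ground truth, so greedy and
    optimal matching provably agree — the ensemble the greedy-vs-optimal
    oracle is defined over.
    """
    gts = []
    for k in range(n_gt):
        gx = (k % 3) * cell + rng.uniform(0, 5)
        gy = (k // 3) * cell + rng.uniform(0, 5)
        w, h = rng.uniform(15, 30, 2)
        gts.append((gx, gy, gx + w, gy + h))
    preds = []
    for _ in range(n_pred):
        base = gts[int(rng.integers(0, n_gt))]
        dx, dy = rng.uniform(-10, 10, 2)
        preds.append((base[0] + dx, base[1] + dy, base[2] + dx, base[3] + dy))
    return ds(preds, list(rng.uniform(0.1, 1.0, n_pred))), ds(gts)


class TestEuclideanDistance:
    def test_coincident(self):
        assert euclidean_distance((3, 4), (3, 4)) == 0.0

    def test_pythagorean(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_generic(self):
        assert euclidean_distance((1, 1), (4, 5)) == 5.0


class TestIou:
    def test_identical(self):
        assert iou(DetectionInstance(box=(0, 0, 10, 10)), DetectionInstance(box=(0, 0, 10, 10))) == 1.0

    def test_disjoint(self):
        assert box_iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_shift(self):
        assert box_iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(50 / 150)

    def test_masks_used_when_present(self):
        full = np.ones((10, 10), dtype=bool)
        half = np.zeros((10, 10), dtype=bool)
        half[:5] = True
        a = DetectionInstance(box=(0, 0, 10, 10), mask=full)
        b = DetectionInstance(box=(0, 0, 10, 10), mask=half)
        assert iou(a, b) == pytest.approx(0.5)

    def test_zero_area_rejected(self):
        inst = DetectionInstance(box=(0, 0, 10, 10))
        bad = DetectionInstance.__new__(DetectionInstance)
        bad.box = (0, 0, 0, 10)
        bad.mask = None
        with pytest.raises(ValueError):
            iou(inst, bad)


class TestMatchDetections:
    def test_single_match(self):
        m = match_detections(ds([(0, 0, 10, 10)]), ds([(0, 2, 10, 12)]), 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_higher_score_claims_gt(self):
        preds = ds([(0, 0, 10, 10), (1, 0, 11, 10)], [0.9, 0.8])
        m = match_detections(preds, ds([(0, 0, 10, 10)]), 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.matches[0][0] == 0  # the 0.9-score prediction

    def test_threshold_excludes_weak_overlap(self):
        m = match_detections(ds([(0, 0, 10, 10)]), ds([(8, 8, 18, 18)]), 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_invariant_tp_plus_fn_is_gt_count(self, rng):
        for _ in range(50):
            preds, gts = random_sets(rng, int(rng.integers(0, 6)), int(rng.integers(1, 6)))
            m = match_detections(preds, gts, 0.5)
            assert m.tp + m.fn == len(gts.instances)
            assert m.tp == len(m.matches)

    def test_greedy_equals_optimal_on_small_cases(self, rng):
        """Brute-force oracle: maximum bipartite matching via assignment."""
        for _ in range(200):
            preds, gts = matching_oracle_sets(
                rng, int(rng.integers(1, 6)), int(rng.integers(1, 6))
            )
            thr = 0.5
            w = np.zeros((len(preds.instances), len(gts.instances)))
            for i, p in enumerate(preds.instances):
                for j, g in enumerate(gts.instances):
                    w[i, j] = 1.0 if iou(p, g) >= thr else 0.0
            ri, ci = linear_sum_assignment(-w)
            optimal_tp = int(w[ri, ci].sum())
            greedy_tp = match_detections(preds, gts, thr).tp
            assert greedy_tp == optimal_tp


class TestPrecisionRecall:
    def test_perfect(self):
        from plotpheno.metrics import MatchResult

        assert precision_recall(MatchResult(5, 0, 0)) == (1.0, 1.0)

    def test_worked(self):
        from plotpheno.metrics import MatchResult

        assert precision_recall(MatchResult(3, 1, 2)) == (0.75, 0.6)

    def test_degenerate_warns(self):
        from plotpheno.metrics import MatchResult

        with pytest.warns(UserWarning):
            assert precision_recall(MatchResult(0, 0, 4)) == (0.0, 0.0)


def envelope_integral(recalls, precisions, resolution=1_000_000):
    """Independent numeric oracle: Riemann sum over the precision envelope."""
    r = np.asarray(recalls)
    p = np.asarray(precisions)
    grid = (np.arange(resolution) + 0.5) / resolution
    vals = np.zeros_like(grid)
    for i, g in enumerate(grid):
        cover = p[r >= g]
        vals[i] = cover.max() if len(cover) else 0.0
    return float(vals.mean())


class TestAveragePrecision:
    def test_single_true_positive(self):
        assert average_precision(ds([(0, 0, 10, 10)]), ds([(0, 0, 10, 10)])) == 1.0

    def test_fp_then_tp(self):
        preds = ds([(50, 50, 60, 60), (0, 0, 10, 10)], [0.9, 0.8])
        gts = ds([(0, 0, 10, 10)])
        assert average_precision(preds, gts, 0.5) == pytest.approx(0.5)

    def test_no_ground_truth_error(self):
        with pytest.raises(UndefinedMetricError):
            average_precision(ds([(0, 0, 1, 1)]), ds([]))

    @pytest.mark.parametrize("case", range(12))
    def test_matches_numeric_envelope_integration(self, case):
        rng = np.random.default_rng(1000 + case)
        preds, gts = random_sets(rng, int(rng.integers(1, 7)), int(rng.integers(1, 7)), span=40)
        ap = average_precision(preds, gts, 0.5)
        curve = pr_curve(preds, gts, 0.5)
        oracle = envelope_integral(curve.recall, curve.precision, resolution=100_000)
        assert ap == pytest.approx(oracle, abs=1e-4)

    def test_exact_envelope_small_resolution_free_case(self):
        # hand-enumerable: 3 preds, 2 gts, scores force order
        preds = ds([(0, 0, 10, 10), (100, 100, 110, 110), (20, 0, 30, 10)], [0.9, 0.8, 0.7])
        gts = ds([(0, 0, 10, 10), (20, 0, 30, 10)])
        # rank1 TP (p=1, r=.5), rank2 FP (p=.5), rank3 TP (p=2/3, r=1)
        # envelope: [0,.5]->1, (.5,1]->2/3
        assert average_precision(preds, gts, 0.5) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_monotone_in_threshold(self, rng):
        for _ in range(20):
            preds, gts = random_sets(rng, 6, 6, span=40)
            ap50 = average_precision(preds, gts, 0.5)
            ap75 = average_precision(preds, gts, 0.75)
            assert 0.0 <= ap75 <= ap50 <= 1.0


class TestAverageRecall:
    def test_all_matched(self):
        assert average_recall(ds([(0, 0, 10, 10)]), ds([(0, 0, 10, 10)])) == 1.0

    def test_count_ratio(self):
        gts = ds([(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10), (60, 0, 70, 10)])
        preds = ds([(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10)])
        assert average_recall(preds, gts, 0.5) == 0.75

    def test_threshold_list_mean(self):
        # one pred, one gt with IoU between the two thresholds
        preds = ds([(0, 0, 10, 10)])
        gts = ds([(0, 3, 10, 13)])  # IoU = 7/13 ~ 0.538
        assert average_recall(preds, gts, [0.5, 0.75]) == pytest.approx(0.5)

    def test_max_detections_cap(self):
        preds = ds([(0, 0, 10, 10), (20, 0, 30, 10)], [0.9, 0.8])
        gts = ds([(20, 0, 30, 10)])
        # only the top-1 prediction is kept and it misses the gt
        assert average_recall(preds, gts, 0.5, max_detections=1) == 0.0


class TestRegressionMetrics:
    def test_perfect(self):
        rep = regression_metrics([1, 2, 3], [1, 2, 3])
        assert (rep.r2, rep.rmse, rep.rrmse_percent) == (1.0, 0.0, 0.0)

    def test_worked_example(self):
        rep = regression_metrics([100, 200, 300], [110, 190, 310])
        assert rep.rmse == pytest.approx(10.0)
        assert rep.r2 == pytest.approx(0.985)
        assert rep.rrmse_percent == pytest.approx(5.0)

    def test_scale_law(self):
        y, yh = [10.0, 20.0, 35.0], [12.0, 18.0, 33.0]
        a = regression_metrics(y, yh)
        b = regression_metrics([3 * v for v in y], [3 * v for v in yh])
        assert b.r2 == pytest.approx(a.r2)
        assert b.rrmse_percent == pytest.approx(a.rrmse_percent)
        assert b.rmse == pytest.approx(3 * a.rmse)

    def test_r2_never_exceeds_one(self, rng):
        for _ in range(50):
            y = rng.normal(50, 10, 12)
            yh = y + rng.normal(0, 5, 12)
            assert regression_metrics(y, yh).r2 <= 1.0

    def test_constant_y_with_residuals_undefined(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([5, 5, 5], [4, 5, 6])


class TestClassificationMetrics:
    def test_diagonal_is_perfect(self):
        rep = classification_metrics(np.diag([5, 3, 2]))
        assert rep.accuracy == 1.0
        assert all(v["f1"] == 1.0 for v in rep.per_class.values())

    def test_worked_2x2(self):
        rep = classification_metrics(np.array([[8, 2], [1, 9]]), labels=["a", "b"])
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.per_class["a"]["precision"] == pytest.approx(8 / 9)
        assert rep.per_class["a"]["recall"] == pytest.approx(0.8)
        assert rep.per_class["a"]["f1"] == pytest.approx(0.8421, abs=1e-4)

    def test_permutation_symmetry(self, rng):
        cm = rng.integers(0, 20, (4, 4))
        rep = classification_metrics(cm, labels=list("abcd"))
        perm = [2, 0, 3, 1]
        rep_p = classification_metrics(cm[np.ix_(perm, perm)],
                                       labels=[list("abcd")[i] for i in perm])
        assert rep_p.macro_f1 == pytest.approx(rep.macro_f1)
        for lab in "abcd":
            assert rep_p.per_class[lab] == pytest.approx(rep.per_class[lab])

    def test_accuracy_is_weighted_recall_mean(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, (3, 3)).astype(float)
            cm[0, 0] += 1  # guarantee nonzero total
            rep = classification_metrics(cm)
            weights = cm.sum(axis=1) / cm.sum()
            recalls = [rep.per_class[str(i)]["recall"] for i in range(3)]
            assert rep.accuracy == pytest.approx(float(np.dot(weights, recalls)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros((2, 2)))


class TestRelativeImprovement:
    def test_equal_is_zero(self):
        assert relative_improvement(0.5, 0.5) == 0.0

    def test_table2_ap50_second_third(self):
        assert round(relative_improvement(0.652, 0.541), 1) == 20.5

    def test_table2_ap75_final_third(self):
        assert round(relative_improvement(0.282, 0.161), 1) == 75.2

    def test_zero_base(self):
        with pytest.raises(ValueError):
            relative_improvement(1.0, 0.0)


class TestSamplingStability:
    def test_identical_samples(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = sampling_stability(s, s)
        assert rep.mean1 == rep.mean2
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.p_value > 0.9

    def test_shifted_sample(self):
        s1 = [1.0, 2.0, 3.0, 4.0]
        rep = sampling_stability(s1, [v + 10 for v in s1])
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mean2 - rep.mean1 == pytest.approx(10.0)

    def test_sample_sd_uses_n_minus_1(self):
        rep = sampling_stability([1.0, 2.0, 3.0], [2.0, 4.0, 9.0])
        assert rep.sd1 == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sampling_stability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_acceptance_rate(self):
        rng = np.random.default_rng(99)
        accepted = sum(
            sampling_stability(rng.normal(0, 1, 200), rng.normal(0, 1, 200)).p_value > 0.05
            for _ in range(100)
        )
        assert accepted >= 90


class TestGridAgreement:
    def test_identity(self):
        boxes = np.array([[0, 0, 10, 10], [20, 0, 30, 10]], dtype=float)
        agree = grid_agreement(boxes, boxes)
        assert agree.mean_distance == 0.0
        assert agree.mean_iou == 1.0
        assert agree.n_missing == 0

    def test_uniform_shift_3_4(self):
        truth = np.array([[0, 0, 10, 10], [20, 0, 30, 10], [0, 20, 10, 30]], dtype=float)
        shifted = truth + np.array([3, 4, 3, 4])
        agree = grid_agreement(shifted, truth)
        assert agree.mean_distance == pytest.approx(5.0)
        assert agree.sd_distance == pytest.approx(0.0, abs=1e-12)

    def test_missing_reported(self):
        truth = np.array([[0, 0, 10, 10], [100, 100, 110, 110]], dtype=float)
        agree = grid_agreement(truth[:1], truth)
        assert agree.n_paired == 1 and agree.n_missing == 1
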