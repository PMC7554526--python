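"""Pixel metrics, lesion-wise rates, agreement statistics, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmlseg.errors import AlignmentError
from wmlseg.evaluation import (
    lesion_metrics,
    pixel_metrics,
    score_agreement,
    stratify,
)
from wmlseg.synthetic import severity_stratum


def brute_force_pixel_metrics(gt, pred):
    """Independent voxel-by-voxel counting oracle."""
    ng = np_ = inter = 0
    for g, p in zip(gt.ravel(), pred.ravel()):
        ng += bool(g)
        np_ += bool(p)
        inter += bool(g) and bool(p)
    dsc = 2 * inter / (ng + np_) if ng + np_ else float("nan")
    recall = inter / ng if ng else float("nan")
    precision = inter / np_ if np_ else float("nan")
    return dsc, precision, recall


class TestPixelMetrics:
    def test_worked_counts(self):
        # |G| = 80, |P| = 100, overlap 60
        gt = np.zeros((1, 16, 16), dtype=bool)
        pred = np.zeros_like(gt)
        gt.flat[0:80] = True
        pred.flat[20:120] = True
        m = pixel_metrics(gt, pred)
        assert m.dsc == pytest.approx(2 * 60 / 180)
        assert m.recall == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.60)

    def test_identical_masks(self, rng):
        m = rng.random((2, 8, 8)) > 0.5
        out = pixel_metrics(m, m)
        assert out.dsc == out.recall == out.precision == 1.0

    def test_disjoint_masks(self):
        gt = np.zeros((1, 4, 4), dtype=bool)
        pred = np.zeros_like(gt)
        gt[0, 0, 0] = True
        pred[0, 3, 3] = True
        out = pixel_metrics(gt, pred)
        assert out.dsc == out.recall == out.precision == 0.0

    def test_empty_masks_are_missing_not_zero(self):
        empty = np.zeros((1, 4, 4), dtype=bool)
        some = ~empty
        assert np.isnan(pixel_metrics(empty, some).recall)
        assert np.isnan(pixel_metrics(some, empty).precision)
        assert np.isnan(pixel_metrics(empty, empty).dsc)

    def test_alignment_checked(self):
        with pytest.raises(AlignmentError):
            pixel_metrics(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)))

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            gt = rng.random((4, 16, 16)) > 0.7
            pred = rng.random((4, 16, 16)) > 0.7
            m = pixel_metrics(gt, pred)
            d, p, r = brute_force_pixel_metrics(gt, pred)
            assert m.dsc == pytest.approx(d, abs=1e-12)
            assert m.precision == pytest.approx(p, abs=1e-12)
            assert m.recall == pytest.approx(r, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_symmetry_properties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((2, 8, 8)) > 0.6
        b = rng.random((2, 8, 8)) > 0.6
        if not (a.any() and b.any()):
            return
        assert pixel_metrics(a, b).dsc == pytest.approx(pixel_metrics(b, a).dsc)
        assert pixel_metrics(a, b).recall == pytest.approx(pixel_metrics(b, a).precision)

    def test_monotone_in_correct_voxels(self, rng):
        gt = rng.random((1, 16, 16)) > 0.6
        pred = gt & (rng.random((1, 16, 16)) > 0.5)
        missing = gt & ~pred
        r, c = np.nonzero(missing[0])
        before = pixel_metrics(gt, pred)
        pred2 = pred.copy()
        pred2[0, r[0], c[0]] = True
        after = pixel_metrics(gt, pred2)
        assert after.dsc >= before.dsc and after.recall >= before.recall


class TestLesionMetrics:
    def test_two_of_three_detected(self):
        gt = np.zeros((1, 32, 32), dtype=bool)
        gt[0, 2:5, 2:5] = gt[0, 10:13, 10:13] = gt[0, 20:23, 20:23] = True
        pred = np.zeros_like(gt)
        pred[0, 3, 3] = pred[0, 11, 11] = True
        m = lesion_metrics(gt, pred)
        assert (m.tp, m.fn) == (2, 1)
        assert m.tpr == pytest.approx(2 / 3)

    def test_perfect_prediction(self, rng):
        gt = np.zeros((2, 16, 16), dtype=bool)
        gt[0, 2:5, 2:5] = gt[1, 8:11, 8:11] = True
        m = lesion_metrics(gt, gt.copy(), candidates=gt.copy())
        assert m.tpr == 1.0 and m.fp == 0

    def test_rejected_candidates_count_as_tn(self):
        """4 spurious surviving predictions, 4 rejected candidates -> FPR 0.5."""
        side = 48
        gt = np.zeros((1, side, side), dtype=bool)
        gt[0, 2:5, 2:5] = True
        pred = gt.copy()
        cand = gt.copy()
        for i in range(4):  # spurious components that survive
            pred[0, 10, 6 * i + 2 : 6 * i + 4] = True
            cand[0, 10, 6 * i + 2 : 6 * i + 4] = True
        for i in range(4):  # candidates rejected by post-processing
            cand[0, 20, 6 * i + 2 : 6 * i + 4] = True
        m = lesion_metrics(gt, pred, candidates=cand)
        assert (m.fp, m.tn) == (4, 4)
        assert m.fpr == pytest.approx(0.5)
        assert m.fdp == pytest.approx(4 / 5)

    def test_counts_match_exhaustive_enumeration(self, rng):
        from wmlseg.postprocess import label_components

        for _ in range(20):
            gt = rng.random((3, 12, 12)) > 0.82
            pred = rng.random((3, 12, 12)) > 0.82
            m = lesion_metrics(gt, pred)
            g_lab, n_g = label_components(gt)
            tp = sum(1 for lab in range(1, n_g + 1) if pred[g_lab == lab].any())
            p_lab, n_p = label_components(pred)
            fp = sum(1 for lab in range(1, n_p + 1) if not gt[p_lab == lab].any())
            assert (m.tp, m.fn, m.fp) == (tp, n_g - tp, fp)

    def test_empty_denominators_missing(self):
        empty = np.zeros((1, 8, 8), dtype=bool)
        m = lesion_metrics(empty, empty)
        assert np.isnan(m.tpr) and np.isnan(m.fpr)


def anova_icc2(scores: np.ndarray) -> float:
    """Closed-form two-way ANOVA ICC(2,1) oracle (n subjects x k raters)."""
    n, k = scores.shape
    grand = scores.mean()
    subj_means = scores.mean(axis=1)
    rater_means = scores.mean(axis=0)
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    sse = np.sum((scores - subj_means[:, None] - rater_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAgreement:
    def test_perfect_agreement(self):
        t = [0, 2, 4, 5, 7, 9]
        a = score_agreement(t, t)
        assert a.spearman_r == pytest.approx(1.0)
        assert a.icc == pytest.approx(1.0)

    def test_reversed_ranks(self):
        t = [0, 1, 2, 3, 4, 5]
        a = score_agreement(t, t[::-1])
        assert a.spearman_r == pytest.approx(-1.0)

    def test_icc_matches_anova_oracle(self):
        scores = np.array(
            [[9.0, 2.0], [7.5, 1.0], [6.0, 4.0], [5.0, 5.5], [4.0, 6.0], [2.0, 8.0]]
        )
        a = score_agreement(scores[:, 0], scores[:, 1])
        assert a.icc == pytest.approx(anova_icc2(scores), abs=1e-6)

    def test_constant_vector_is_missing(self):
        a = score_agreement([3, 3, 3, 3], [1, 2, 3, 4])
        assert np.isnan(a.spearman_r) and np.isnan(a.icc)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 9, 30)
        p = t + rng.normal(0, 1, 30)
        a = score_agreement(t, p)
        lo, hi = a.icc_ci95
        assert lo <= a.icc <= hi


class TestStratify:
    @pytest.mark.parametrize(
        "wmlv,expected",
        [(5.0, "mild"), (5.01, "moderate"), (20.0, "moderate"), (20.01, "severe"), (0.0, "mild")],
    )
    def test_boundaries(self, wmlv, expected):
        assert severity_stratum(wmlv) == expected

    def test_partition_property(self, rng):
        df = pd.DataFrame(
            {
                "true_wmlv_ml": rng.uniform(0, 40, 30),
                "has_ail": rng.random(30) > 0.5,
                "dsc": rng.uniform(0, 1, 30),
            }
        )
        summary = stratify(df)
        by_group = summary.set_index("group")["n"]
        assert by_group[["mild", "moderate", "severe"]].sum() == 30
        assert by_group[["AILg", "non-AILg"]].sum() == 30
        assert by_group["all"] == 30

    def test_missing_values_excluded_from_means(self):
        df = pd.DataFrame(
            {
                "true_wmlv_ml": [1.0, 2.0, 30.0],
                "has_ail": [False, True, False],
                "dsc": [0.5, np.nan, 0.7],
            }
        )
        summary = stratify(df).set_index("group")
        assert summary.loc["mild", "dsc_mean"] == pytest.approx(0.5)
        assert summary.loc["mild", "dsc_n"] == 1
        assert summary.loc["all", "dsc_n"] == 2
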