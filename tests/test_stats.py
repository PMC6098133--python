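import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ftirsurv.stats import (
    HIGHER,
    LOWER,
    CutoffSpec,
    dichotomize,
    dichotomize_values,
    mann_whitney,
    rank_auc,
    roc_curve,
    select_cutoff,
    spearman,
)
from ftirsurv.features import SpectralFeatures


def brute_force_cost_minimum(scores, labels, orientation, cost_ratio, prevalence):
    """Independent oracle: enumerate every candidate threshold's cost."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    w_pos = n_pos if prevalence else 1.0
    w_neg = n_neg if prevalence else 1.0
    best = math.inf
    for t in np.concatenate(([-np.inf], np.unique(scores), [np.inf])):
        pred = scores >= t if orientation == HIGHER else scores < t
        se = np.sum(pred & (labels == 1)) / n_pos
        sp = np.sum(~pred & (labels == 0)) / n_neg
        cost = cost_ratio * w_pos * (1 - se) + w_neg * (1 - sp)
        best = min(best, cost)
    return best


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([3, 4, 1, 2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        roc = roc_curve([3, 4, 1, 2], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.0)

    def test_pairwise_comparison_oracle(self):
        # positives {3, 1}, negatives {2, 0}: 3 of 4 pairs concordant
        roc = roc_curve([3, 1, 2, 0], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_endpoints_present(self):
        roc = roc_curve([1, 2, 3, 4], [0, 1, 0, 1])
        pts = set(zip(1 - roc.specificity, roc.sensitivity))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            roc_curve([1.0, np.nan], [0, 1])

    @given(
        hst.lists(hst.integers(min_value=0, max_value=8), min_size=4, max_size=25),
        hst.randoms(use_true_random=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_trapezoid_equals_rank_formulation(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        for orientation in (HIGHER, LOWER):
            roc = roc_curve(scores, labels, orientation)
            assert roc.auc == pytest.approx(
                rank_auc(scores, labels, orientation), abs=1e-10
            )


class TestSelectCutoff:
    def test_cost_ratio_one_reduces_to_youden(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = rng.integers(6, 25)
            scores = rng.normal(size=n).round(1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            roc = roc_curve(scores, labels)
            spec = select_cutoff(roc, cost_ratio=1.0, prevalence_weighting=False)
            j_star = max(roc.sensitivity + roc.specificity - 1.0)
            assert spec.sensitivity + spec.specificity - 1.0 == pytest.approx(j_star)

    def test_spec_example_matches_enumeration(self):
        scores = [5, 6, 7, 1, 2, 6]
        labels = [1, 1, 1, 0, 0, 0]
        roc = roc_curve(scores, labels)
        spec = select_cutoff(roc, cost_ratio=2.0)
        assert spec.expected_cost == pytest.approx(
            brute_force_cost_minimum(scores, labels, HIGHER, 2.0, True)
        )
        # the chosen rule must reproduce its printed Se/Sp when re-applied
        pred = [spec.classify(v) for v in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        tn = sum((not p) and (not l) for p, l in zip(pred, labels))
        assert tp / 3 == pytest.approx(spec.sensitivity)
        assert tn / 3 == pytest.approx(spec.specificity)

    def test_global_optimality_random_sets(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            n = rng.integers(6, 30)
            scores = rng.normal(size=n).round(1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            for orientation in (HIGHER, LOWER):
                for prevalence in (True, False):
                    roc = roc_curve(scores, labels, orientation)
                    spec = select_cutoff(roc, 2.0, prevalence)
                    assert spec.expected_cost == pytest.approx(
                        brute_force_cost_minimum(scores, labels, orientation, 2.0, prevalence)
                    )

    def test_threshold_is_attainable(self):
        roc = roc_curve([1.0, 2.5, 3.5, 4.0], [0, 0, 1, 1])
        spec = select_cutoff(roc)
        assert spec.threshold in (1.0, 2.5, 3.5, 4.0, math.inf, -math.inf)


class TestDichotomize:
    def test_ge_boundary_included(self):
        spec = CutoffSpec(feature="t_b", threshold=1027.0, direction="ge")
        assert spec.classify(1027.0) == 1
        assert spec.classify(1026.9) == 0

    def test_lt_boundary_excluded(self):
        spec = CutoffSpec(feature="shift_tt_tb", threshold=1.0, direction="lt")
        assert spec.classify(1.0) == 0
        assert spec.classify(0.9) == 1

    def test_missing_feature_excluded_with_none(self):
        spec = CutoffSpec(feature="shift_tb_tn", threshold=-1.0, direction="ge")
        feats = [
            SpectralFeatures("P1", t_b=1030.0, t_n=1025.0),
            SpectralFeatures("P2", t_b=1030.0, t_n=None),
        ]
        out = dichotomize(feats, spec)
        assert out["P1"] == 1  # shift 5 >= -1
        assert out["P2"] is None

    def test_unknown_feature_rejected(self):
        spec = CutoffSpec(feature="nope", threshold=0.0, direction="ge")
        with pytest.raises(KeyError):
            dichotomize([SpectralFeatures("P1", t_b=1.0)], spec)


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 5.0, 9.0]
        u, p = mann_whitney(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_exact_enumeration_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        # 2 of the 6 label arrangements are as extreme
        assert p == pytest.approx(2 / 6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=12)
        y = rng.normal(loc=0.7, size=9)
        _, p1 = mann_whitney(x, y)
        _, p2 = mann_whitney(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 9.0, 11.0]
        assert spearman(x, y)[0] == pytest.approx(1.0)
        assert spearman(x, y[::-1])[0] == pytest.approx(-1.0)

    def test_matches_pearson_on_midranks(self):
        from scipy.stats import pearsonr, rankdata

        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 8.0]
        rho, _ = spearman(x, y)
        oracle = pearsonr(rankdata(x), rankdata(y)).statistic
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
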