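"""Grading statistics: identities, oracles, and boundary conventions."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fracperf.grading_stats import (CutoffTable, classify_grade, compare_auc,
                                    efficiency_cutoff, group_tests,
                                    interobserver, linear_correlation,
                                    multiclass_auc, roc_dichotomized)


def _records(fd, groups, adc=None):
    df = pd.DataFrame({"lesion_id": [f"L{i}" for i in range(len(fd))],
                       "fd_margin": fd, "isup_group": groups})
    if adc is not None:
        df["adc_q25"] = adc
    return df


class TestGroupTests:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2.3, 0.05, 30)
        df = pd.DataFrame({"fd": vals, "group": np.repeat([1, 2, 3], 10)})
        out = group_tests(df)
        assert (out["pairwise"]["p_adjusted"] > 0.2).all()

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "fd": np.concatenate([rng.normal(m, 0.1, 5) for m in (0, 5, 10)]),
            "group": np.repeat([1, 2, 3], 5)})
        out = group_tests(df)
        assert (out["pairwise"]["p_adjusted"] < 0.05).all()

    def test_small_group_excluded_with_warning(self):
        df = pd.DataFrame({"fd": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "group": [1, 1, 2, 2, 3]})
        with pytest.warns(UserWarning, match="excluded"):
            out = group_tests(df)
        pairs = set(map(tuple, out["pairwise"][["group_a", "group_b"]].values))
        assert pairs == {(1, 2)}


class TestLinearCorrelation:
    def test_collinear_points(self):
        df = pd.DataFrame({"fd": [2.1, 2.2, 2.3, 2.4, 2.5], "group": [1, 2, 3, 4, 5]})
        r2, p = linear_correlation(df)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_flat_fd_gives_zero(self):
        df = pd.DataFrame({"fd": [2.3] * 6 + [2.35], "group": [1, 1, 2, 2, 3, 3, 3]})
        with pytest.raises(ValueError):
            linear_correlation(df.assign(fd=2.3))
        r2, _ = linear_correlation(df)
        assert r2 < 0.6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form(self, seed):
        """r^2 equals the squared Pearson correlation computed from raw sums."""
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 6, 40)
        y = 2.2 + 0.03 * x + rng.normal(0, 0.05, 40)
        df = pd.DataFrame({"fd": y, "group": x})
        r2, _ = linear_correlation(df)
        sx, sy = x.astype(float), y
        num = (len(sx) * (sx * sy).sum() - sx.sum() * sy.sum()) ** 2
        den = ((len(sx) * (sx**2).sum() - sx.sum() ** 2)
               * (len(sy) * (sy**2).sum() - sy.sum() ** 2))
        assert r2 == pytest.approx(num / den, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        df = _records([2.1, 2.15, 2.18, 2.5, 2.6, 2.7], [1, 1, 1, 3, 4, 5])
        r = roc_dichotomized(df, split=2, n_boot=200, seed=0)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_shuffled_labels_near_half(self):
        """Permutation: AUC under label shuffling centers on 0.5."""
        rng = np.random.default_rng(2)
        fd = rng.uniform(2.0, 3.0, 40)
        aucs = []
        for _ in range(100):
            groups = rng.permutation(np.repeat([1, 3], 20))
            r = roc_dichotomized(_records(fd, groups), split=2, n_boot=0, seed=1)
            aucs.append(r.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_u_statistic(self, seed):
        """AUC = U / (n1 * n2): the Mann-Whitney identity, checked exactly."""
        rng = np.random.default_rng(seed)
        n1, n2 = 12, 17
        fd = np.round(rng.uniform(2, 3, n1 + n2), 3)  # ties included
        groups = np.array([1] * n1 + [3] * n2)
        r = roc_dichotomized(_records(fd, groups), split=2, n_boot=100, seed=0)
        u = sps.mannwhitneyu(fd[n1:], fd[:n1], alternative="two-sided").statistic
        assert r.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_dichotomized(_records([2.2, 2.3], [1, 1]), split=2)


class TestEfficiencyCutoff:
    def test_perfect_gap_midpoint(self):
        c = efficiency_cutoff([2.1, 2.2, 2.4, 2.5], [0, 0, 1, 1])
        assert c == pytest.approx(0.5 * (2.2 + 2.4))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        """Exhaustive candidate scan agrees with an independent brute force."""
        rng = np.random.default_rng(seed)
        x = np.round(rng.uniform(2, 3, 30), 2)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p = float(np.mean(y))
        c = efficiency_cutoff(x, y)
        uniq = np.unique(x)
        best_ef, best_c = -1.0, None
        for cand in (uniq[:-1] + uniq[1:]) / 2:
            se = np.sum((x >= cand) & (y == 1)) / (y == 1).sum()
            sp = np.sum((x < cand) & (y == 0)) / (y == 0).sum()
            ef = p * se + (1 - p) * sp
            if ef > best_ef + 1e-12:
                best_ef, best_c = ef, cand
        assert c == pytest.approx(best_c)

    @pytest.mark.parametrize("seed", range(10))
    def test_half_prevalence_equals_youden(self, seed):
        """With p = 0.5, Ef-maximization coincides with Youden's J."""
        rng = np.random.default_rng(seed + 100)
        x = np.round(rng.uniform(2, 3, 25), 2)
        y = (x + rng.normal(0, 0.2, 25) > 2.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        c_ef = efficiency_cutoff(x, y, prevalence=0.5)
        uniq = np.unique(x)
        best_j, best_c = -2.0, None
        for cand in (uniq[:-1] + uniq[1:]) / 2:
            se = np.sum((x >= cand) & (y == 1)) / (y == 1).sum()
            sp = np.sum((x < cand) & (y == 0)) / (y == 0).sum()
            if se + sp - 1 > best_j + 1e-12:
                best_j, best_c = se + sp - 1, cand
        assert c_ef == pytest.approx(best_c)


class TestClassifyGrade:
    table = CutoffTable((2.20, 2.31, 2.40))

    def test_below_first_cutoff_is_group1(self):
        assert classify_grade(2.10, self.table) == 1

    def test_exact_threshold_goes_to_higher_band(self):
        assert classify_grade(2.20, self.table) == 2
        assert classify_grade(2.31, self.table) == 3
        assert classify_grade(2.40, self.table) == 4

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_grade(1.9, self.table)
        with pytest.raises(ValueError):
            classify_grade(3.1, self.table)

    def test_cutoffs_must_increase(self):
        with pytest.raises(ValueError):
            CutoffTable((2.3, 2.2, 2.4))


class TestMulticlassAuc:
    def test_perfect_ordering(self):
        fd = [2.1, 2.12, 2.25, 2.27, 2.35, 2.37, 2.45, 2.47, 2.6, 2.62]
        groups = np.repeat([1, 2, 3, 4, 5], 2)
        m, (lo, hi) = multiclass_auc(_records(fd, groups), n_boot=200, seed=0)
        assert m == 1.0

    def test_two_class_reduces_to_roc_auc(self):
        rng = np.random.default_rng(5)
        fd = rng.uniform(2, 3, 30)
        groups = np.array([1] * 15 + [3] * 15)
        m, _ = multiclass_auc(_records(fd, groups), n_boot=100, seed=0)
        r = roc_dichotomized(_records(fd, groups), split=2, n_boot=100, seed=0)
        assert m == pytest.approx(r.auc, abs=1e-12)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(100):
            fd = rng.uniform(2, 3, 30)
            groups = rng.integers(1, 4, 30)
            if len(np.unique(groups)) < 2:
                continue
            m, _ = multiclass_auc(_records(fd, groups), n_boot=0, seed=0)
            vals.append(m)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)


class TestCompareAuc:
    def test_identical_scores_not_significant(self):
        rng = np.random.default_rng(7)
        fd = rng.uniform(2, 3, 40)
        groups = np.where(fd > 2.5, 3, 1)
        groups[0], groups[-1] = 1, 3
        df = _records(fd, groups, adc=-fd)  # same information, ADC orientation
        out = compare_auc(df, n_boot=500, seed=0)
        assert out["p"] > 0.5

    def test_informative_vs_noise_significant(self):
        rng = np.random.default_rng(8)
        n = 100
        groups = np.repeat([1, 3], n // 2)
        fd = 2.2 + 0.3 * (groups == 3) + rng.normal(0, 0.01, n)
        adc = rng.normal(1000, 100, n)  # uninformative comparator
        out = compare_auc(_records(fd, groups, adc=adc), n_boot=500, seed=0)
        assert out["auc_a"] == 1.0
        assert out["p"] < 0.01

    def test_seed_stability(self):
        """The bootstrap p of a clear AUC difference is stable across seeds."""
        rng = np.random.default_rng(9)
        n = 80
        groups = np.repeat([1, 3], n // 2)
        fd = 2.25 + 0.18 * (groups == 3) + rng.normal(0, 0.05, n)
        adc = 1000 - 120 * (groups == 3) + rng.normal(0, 150, n)
        ps = [compare_auc(_records(fd, groups, adc=adc), n_boot=2000,
                          seed=s)["p"] for s in (1, 2, 3)]
        assert max(ps) - min(ps) <= 0.01


class TestInterobserver:
    def test_identical_readers(self):
        fd = [2.1, 2.25, 2.35, 2.45, 2.6]
        out = interobserver(fd, fd)
        assert out["kappa"] == 1.0
        assert out["bias"] == 0.0

    def test_constant_offset_bias(self):
        fd = np.array([2.1, 2.25, 2.35, 2.45, 2.6])
        out = interobserver(fd, fd + 0.02)
        assert out["bias"] == pytest.approx(0.02)
        lo, hi = out["loa"]
        assert lo == pytest.approx(0.02) and hi == pytest.approx(0.02)

    def test_kappa_matches_confusion_matrix_formula(self):
        """Kappa recomputed from the confusion matrix by the closed formula."""
        rng = np.random.default_rng(10)
        r1 = rng.uniform(2.05, 2.6, 50)
        r2 = np.clip(r1 + rng.normal(0, 0.05, 50), 2.0, 3.0)
        out = interobserver(r1, r2)
        b1 = np.array([classify_grade(v) for v in r1])
        b2 = np.array([classify_grade(v) for v in r2])
        cats = np.unique(np.concatenate([b1, b2]))
        n = len(b1)
        po = np.mean(b1 == b2)
        pe = sum((np.sum(b1 == c) / n) * (np.sum(b2 == c) / n) for c in cats)
        assert out["kappa"] == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interobserver([2.1, 2.2], [2.1])
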