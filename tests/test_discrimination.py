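import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from locrad import (
    FEATURE_KEYS,
    CohortTable,
    Modality,
    auc_ci,
    holm_bonferroni,
    informedness,
    lasso_select,
    operating_point,
    roc_curve_auc,
    run_discrimination,
    standardize,
    wilcoxon_rank_sum,
)
from locrad.imaging import Group


def make_table(X, y, modality=Modality.PET):
    X = pd.DataFrame(X, columns=list(FEATURE_KEYS), index=[f"s{i}" for i in range(len(X))])
    labels = pd.Series([Group.LRRC if yi else Group.NO_LRRC for yi in y], index=X.index)
    return CohortTable(features=X, labels=labels, modality=modality)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        t = make_table(rng.normal(3, 7, size=(12, 144)), [0, 1] * 6)
        z = standardize(t)
        np.testing.assert_allclose(z.features.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.features.std(ddof=1), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        t = make_table(rng.normal(size=(10, 144)), [0, 1] * 5)
        z1 = standardize(t)
        z2 = standardize(z1)
        np.testing.assert_allclose(z2.features.to_numpy(), z1.features.to_numpy(), atol=1e-12)

    def test_constant_feature_dropped(self, rng):
        X = rng.normal(size=(8, 144))
        X[:, 3] = 5.0
        z = standardize(make_table(X, [0, 1] * 4))
        assert FEATURE_KEYS[3] not in z.features.columns
        assert z.features.shape == (8, 143)

    def test_single_sample_rejected(self, rng):
        t = make_table(rng.normal(size=(2, 144)), [0, 1])
        t.features = t.features.iloc[:1]
        t.labels = t.labels.iloc[:1]
        with pytest.raises(ValueError):
            standardize(t)


class TestLassoSelect:
    def test_perfectly_separating_feature_is_selected(self, rng):
        n = 30
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 144))
        X[:, 7] = y * 2.0 + rng.normal(0, 0.05, size=n)  # feature = label + small noise
        z = standardize(make_table(X, y))
        selected, coefs, info = lasso_select(z, seed=0)
        assert FEATURE_KEYS[7] in selected
        assert abs(coefs[FEATURE_KEYS[7]]) > 0

    def test_null_cohorts_select_little(self, rng):
        sizes = []
        for rep in range(20):
            y = rng.permutation([0] * 12 + [1] * 12)
            X = rng.normal(size=(24, 144))
            z = standardize(make_table(X, y))
            selected, _, _ = lasso_select(z, seed=rep)
            sizes.append(len(selected))
        assert np.median(sizes) <= 10

    def test_weighting_none_equals_prior_on_balanced(self, rng):
        y = np.array([0, 1] * 15)
        X = rng.normal(size=(30, 144))
        X[:, 0] += y
        z = standardize(make_table(X, y))
        a, _, _ = lasso_select(z, seed=3, weighting="prior")
        b, _, _ = lasso_select(z, seed=3, weighting="none")
        assert a == b

    def test_unstratifiable_rejected(self, rng):
        y = np.array([1, 1, 1, 0] + [1] * 8)
        z = standardize(make_table(rng.normal(size=(12, 144)), y))
        with pytest.raises(ValueError):
            lasso_select(z, folds=5, seed=0)


class TestWilcoxon:
    def test_textbook_exact_case(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=9) + 0.8
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(deadline=None, max_examples=15)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_full_enumeration(self, seed):
        """Exact p equals brute-force enumeration of all rank assignments."""
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 7))
        ny = int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # tie-free
        x, y = pooled[:nx], pooled[nx:]
        u_obs = sum((xi > yj) for xi in x for yj in y)
        n = nx + ny
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            xs = pooled[list(combo)]
            ys = np.delete(pooled, list(combo))
            u = sum((xi > yj) for xi in xs for yj in ys)
            total += 1
            if min(u, nx * ny - u) <= min(u_obs, nx * ny - u_obs):
                count += 1
        assert wilcoxon_rank_sum(x, y) == pytest.approx(count / total, rel=1e-9)


class TestHolm:
    def test_worked_example_five_pvalues(self):
        adj = holm_bonferroni([0.005, 0.006, 0.006, 0.010, 0.017])
        np.testing.assert_allclose(adj, [0.025, 0.025, 0.025, 0.025, 0.025])
        assert (adj < 0.05).all()

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])

    def test_cap_at_one(self):
        np.testing.assert_allclose(holm_bonferroni([0.5, 0.9]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_from_definition_stepdown(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        adj = holm_bonferroni(p)
        # step-down from definition: sort, multiply by (m - i), running max, cap
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 0.0
        for i, idx in enumerate(order):
            running = max(running, (m - i) * p[idx])
            expected[idx] = min(running, 1.0)
        np.testing.assert_allclose(adj, expected, rtol=1e-12)
        assert (adj >= p - 1e-15).all()


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_curve_auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_is_chance(self):
        _, auc = roc_curve_auc([5, 5, 5, 5], [1, 0, 1, 0])
        assert auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        _, auc = roc_curve_auc([2, 3, 1, 2.5], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_anti_discriminating_reported_below_half(self):
        _, auc = roc_curve_auc([1, 2, 3, 4], [1, 1, 0, 0])
        assert auc == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 2], [1, 1])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_all_pairs_count(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 12))
        n_neg = int(rng.integers(2, 12))
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # induce ties
        y = np.array([1] * n_pos + [0] * n_neg)
        _, auc = roc_curve_auc(scores, y)
        pos, neg = scores[:n_pos], scores[n_pos:]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
        assert auc == pytest.approx(np.mean(pairs), rel=1e-12)


class TestAucCI:
    def test_perfect_separation_upper_is_one(self, rng):
        scores = np.concatenate([rng.uniform(2, 3, 20), rng.uniform(0, 1, 20)])
        y = np.array([1] * 20 + [0] * 20)
        lo, hi = auc_ci(scores, y, seed=0)
        assert hi == 1.0

    def test_contains_point_estimate(self, rng):
        scores = rng.normal(size=30) + np.array([0.8] * 15 + [0.0] * 15)
        y = np.array([1] * 15 + [0] * 15)
        _, auc = roc_curve_auc(scores, y)
        lo, hi = auc_ci(scores, y, seed=1)
        assert lo <= auc <= hi

    def test_seeded_and_deterministic(self, rng):
        scores = rng.normal(size=24)
        y = np.array([1, 0] * 12)
        assert auc_ci(scores, y, seed=7) == auc_ci(scores, y, seed=7)
        assert auc_ci(scores, y, seed=7) != auc_ci(scores, y, seed=8)


class TestOperatingPoint:
    def test_published_operating_points_obey_identity(self):
        # (SN, SP, I) triples as printed in the benchmark discrimination study
        printed = [
            (0.57, 1.00, 0.57),
            (0.67, 0.71, 0.38),
            (0.75, 0.59, 0.34),
            (0.75, 0.63, 0.38),
            (0.79, 0.56, 0.35),
            (0.83, 0.56, 0.39),
            (0.71, 0.59, 0.30),
        ]
        for sn, sp, i_printed in printed:
            assert informedness(sn, sp) == pytest.approx(i_printed, abs=5e-3)

    def test_boundary_and_chance(self):
        assert informedness(1.0, 1.0) == 1.0
        assert informedness(0.5, 0.5) == 0.0

    def test_youden_maximum_with_sp_tiebreak(self):
        curve = pd.DataFrame(
            {
                "threshold": [np.inf, 3.0, 2.0, 1.0],
                "fpr": [0.0, 0.0, 0.5, 1.0],
                "tpr": [0.0, 0.5, 1.0, 1.0],
            }
        )
        sn, sp, inf, thr = operating_point(curve)
        assert (sn, sp) == (0.5, 1.0)  # J ties at 0.5; higher SP wins
        assert inf == sn + sp - 1.0

    def test_identity_holds_on_real_curves(self, rng):
        scores = rng.normal(size=40) + np.array([0.6] * 20 + [0.0] * 20)
        y = np.array([1] * 20 + [0] * 20)
        curve, _ = roc_curve_auc(scores, y)
        sn, sp, inf, _ = operating_point(curve)
        assert inf == sn + sp - 1.0


class TestRunDiscrimination:
    def test_strong_feature_found_and_report_consistent(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 144))
        X[:, 10] += 2.5 * y
        t = make_table(X, y)
        report = run_discrimination(t, seed=0, bootstrap_reps=200)
        key = FEATURE_KEYS[10]
        assert key in report.selected
        res = {r.feature: r for r in report.results}
        assert res[key].p_holm < 0.05
        assert res[key].auc > 0.9
        for r in report.results:
            assert r.informedness == r.sn + r.sp - 1.0
            assert r.p_holm >= r.p_raw - 1e-15
            assert r.auc_ci_low <= r.auc <= r.auc_ci_high
            assert 0 <= r.auc <= 1
        ranks = [r.rank for r in sorted(report.results, key=lambda r: (r.p_holm, r.p_raw))]
        assert ranks == sorted(ranks)

    def test_deterministic_reports(self, rng):
        X = rng.normal(size=(20, 144))
        y = np.array([0, 1] * 10)
        X[:, 5] += 1.5 * y
        t = make_table(X, y)
        a = run_discrimination(t, seed=11, bootstrap_reps=100)
        b = run_discrimination(t, seed=11, bootstrap_reps=100)
        assert a.to_json() == b.to_json()

    def test_empty_selection_falls_back_to_all_features(self, rng):
        X = rng.normal(size=(24, 144))
        y = np.array([0, 1] * 12)
        t = make_table(X, y)
        report = run_discrimination(t, seed=2, bootstrap_reps=0)
        if report.selection_empty:
            assert len(report.results) == len(standardize(t).features.columns)
        else:  # seed-dependent; the flag must agree with the selection either way
            assert len(report.results) == len(report.selected)
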