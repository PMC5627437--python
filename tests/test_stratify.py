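"""Clustering, subgroup comparison, cross-validation and the cutpoint oracle."""

import numpy as np
import pandas as pd
import pytest

from favsig import (FavorabilityMatrix, TumorSimConfig, cluster_subgroups,
                    compare_subgroup_ic50, compare_subgroup_survival,
                    cross_validate, optimal_cutpoint, simulate_tumor_cohort)
from tests.oracles import brute_logrank


def _fm(scores: np.ndarray) -> FavorabilityMatrix:
    df = pd.DataFrame(scores.astype(np.int8),
                      index=[f"s{j}" for j in range(scores.shape[0])],
                      columns=[f"g{i}" for i in range(scores.shape[1])])
    thr = pd.Series(0.0, index=df.columns)
    return FavorabilityMatrix(df, anchor="survival", mode="gene_direction",
                              thresholds=thr)


class TestClusterSubgroups:
    def test_separable_blocks(self):
        scores = np.vstack([np.ones((10, 6)), -np.ones((10, 6))])
        g = cluster_subgroups(_fm(scores), seed=0)
        assert (g.labels.iloc[:10] == "favorable_group").all()
        assert (g.labels.iloc[10:] == "unfavorable_group").all()
        assert g.mean_favorability["favorable_group"] == 1.0

    def test_all_zero_flags_nonseparable(self):
        g = cluster_subgroups(_fm(np.zeros((12, 4))), seed=0)
        assert not g.separable

    def test_sample_order_invariance(self, rng):
        scores = rng.integers(-1, 2, size=(30, 8))
        f1 = _fm(scores)
        g1 = cluster_subgroups(f1, seed=1)
        perm = rng.permutation(30)
        f2 = FavorabilityMatrix(f1.scores.iloc[perm], anchor="survival",
                                mode="gene_direction", thresholds=f1.thresholds)
        g2 = cluster_subgroups(f2, seed=1)
        joined = pd.concat([g1.labels.rename("a"),
                            g2.labels.rename("b")], axis=1)
        assert (joined["a"] == joined["b"]).all()

    def test_min_samples_guard(self):
        with pytest.raises(ValueError):
            cluster_subgroups(_fm(np.ones((3, 2))), k=2)


class TestCompareSubgroupSurvival:
    def test_relabeling_inverts_hr(self, rng):
        n = 60
        surv = pd.DataFrame({
            "time": rng.exponential(100, n),
            "event": rng.binomial(1, 0.8, n),
        }, index=[f"s{j}" for j in range(n)])
        lab = pd.Series(["A"] * 30 + ["B"] * 30, index=surv.index)
        c1 = compare_subgroup_survival(lab, surv, with_km=False)
        c2 = compare_subgroup_survival(lab.map({"A": "B", "B": "A"}), surv,
                                       with_km=False)
        assert np.isclose(c1.hazard_ratio, 1.0 / c2.hazard_ratio, rtol=1e-6)
        assert np.isclose(c1.p_value, c2.p_value, rtol=1e-6)

    def test_zero_event_group_flagged(self, rng):
        surv = pd.DataFrame({
            "time": np.r_[rng.exponential(50, 20), rng.exponential(50, 20)],
            "event": np.r_[np.ones(20), np.zeros(20)].astype(int),
        }, index=[f"s{j}" for j in range(40)])
        lab = pd.Series(["A"] * 20 + ["B"] * 20, index=surv.index)
        cmp = compare_subgroup_survival(lab, surv, with_km=False)
        assert not cmp.stable

    def test_km_curves_emitted(self, planted_cohort):
        _, surv, truth = planted_cohort
        lab = truth.planted_subgroup.map({"good": "favorable_group",
                                          "poor": "unfavorable_group"})
        cmp = compare_subgroup_survival(lab, surv)
        assert cmp.hazard_ratio > 1  # unfavorable vs favorable orientation
        assert set(cmp.km_curves["group"].unique()) == {
            "favorable_group", "unfavorable_group"}
        assert (cmp.km_curves["survival"].between(0, 1)).all()


class TestCompareSubgroupIC50:
    def test_disjoint_groups_exact_p(self):
        ic50 = pd.Series([1, 2, 3, 4, 5, 10, 20, 30, 40, 50.0],
                         index=[f"c{i}" for i in range(10)])
        lab = pd.Series(["favorable_group"] * 5 + ["unfavorable_group"] * 5,
                        index=ic50.index)
        cmp = compare_subgroup_ic50(lab, ic50)
        assert np.isclose(cmp.p_value, 2 / 252, rtol=1e-9)
        assert cmp.median_diff > 0  # unfavorable group more resistant

    def test_all_tied_p_one(self):
        ic50 = pd.Series([3.0] * 8, index=[f"c{i}" for i in range(8)])
        lab = pd.Series(["A"] * 4 + ["B"] * 4, index=ic50.index)
        assert compare_subgroup_ic50(lab, ic50).p_value == 1.0


class TestCrossValidate:
    def test_planted_signal_generalizes(self):
        # strong planted program (subgroup HR ~ e^1.6, the regime the
        # method is designed for): held-out folds stay significant
        m, surv, _ = simulate_tumor_cohort(
            TumorSimConfig(seed=42, effect_log_hazard=1.0))
        cv = cross_validate(m, surv, seed=2)
        assert cv.median_test_p < 0.05
        assert cv.median_train_p <= cv.median_test_p  # leakage guard
        assert (cv.folds["n_signature_genes"] > 0).all()

    def test_null_cohort_not_significant(self, null_cohort):
        m, surv, _ = null_cohort
        cv = cross_validate(m, surv, seed=3)
        assert cv.median_test_p >= 0.05

    def test_same_seed_identical(self, null_cohort):
        m, surv, _ = null_cohort
        a = cross_validate(m, surv, seed=5)
        b = cross_validate(m, surv, seed=5)
        pd.testing.assert_frame_equal(a.folds, b.folds)


class TestOptimalCutpoint:
    def _surv(self, rng, n=30, x=None):
        risk = 1.2 * (x - x.mean()) / x.std() if x is not None else np.zeros(n)
        te = rng.exponential(1.0 / (0.01 * np.exp(risk)))
        tc = rng.exponential(200.0, n)
        return pd.DataFrame({"time": np.minimum(te, tc),
                             "event": (te <= tc).astype(int)},
                            index=[f"s{j}" for j in range(n)])

    def test_matches_bruteforce_argmax(self, rng):
        for rep in range(3):
            x = rng.normal(size=30)
            surv = self._surv(rng, x=x)
            cut, _ = optimal_cutpoint(x, surv, min_group_frac=0.1)
            t = surv["time"].to_numpy()
            e = surv["event"].to_numpy()
            best, best_stat = None, -1
            for c in np.unique(x):
                low = x <= c
                if low.sum() < 3 or low.sum() > 27:
                    continue
                stat = brute_logrank(t[low], e[low], t[~low], e[~low])
                if stat > best_stat:
                    best, best_stat = c, stat
            assert np.isclose(cut, best)

    def test_perfect_separation_cut_in_gap(self, rng):
        x = np.r_[np.zeros(15), np.ones(15) + 9]
        te = np.r_[rng.uniform(100, 200, 15), rng.uniform(1, 10, 15)]
        surv = pd.DataFrame({"time": te, "event": np.ones(30, int)},
                            index=[f"s{j}" for j in range(30)])
        cut, cmp = optimal_cutpoint(x, surv)
        assert 0 <= cut < 10
        assert cmp.hazard_ratio > 1  # high expression, faster progression

    def test_guards(self, rng):
        x = rng.normal(size=30)
        surv = self._surv(rng, x=x)
        with pytest.raises(ValueError):
            optimal_cutpoint(x[:5], surv.iloc[:5])
        with pytest.raises(ValueError):
            optimal_cutpoint(np.ones(30), surv)  # no admissible cut
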