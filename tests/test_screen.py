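"""Survival screen: agreement with lifelines, calibration, confounder filter."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from favsig import (ExpressionMatrix, cox_screen_batch, cox_univariate,
                    filter_confounders, screen_genes)


def _sim_surv(rng, n, risk=None):
    risk = np.zeros(n) if risk is None else risk
    te = rng.exponential(1.0 / (0.002 * np.exp(risk)))
    tc = rng.exponential(800.0, n)
    return pd.DataFrame({
        "time": np.minimum(te, tc),
        "event": (te <= tc).astype(int),
    }, index=[f"s{j}" for j in range(n)])


class TestCoxAgainstLifelines:
    """The vectorized Efron Newton solver must match the reference fitter."""

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_coefficients_and_p(self, rng, with_ties):
        n, G = 120, 25
        X = rng.standard_normal((G, n))
        surv = _sim_surv(rng, n, risk=0.8 * X[0])
        if with_ties:
            surv["time"] = np.ceil(surv["time"] / 50.0)  # heavy ties
        fit = cox_screen_batch(X, surv["time"], surv["event"])
        for g in range(0, G, 5):
            df = pd.DataFrame({"t": surv["time"].to_numpy(),
                               "e": surv["event"].to_numpy(), "x": X[g]})
            ref = CoxPHFitter().fit(df, "t", "e",
                                    fit_options={"precision": 1e-10})
            assert np.isclose(fit["coefficient"].iloc[g], ref.params_["x"],
                              atol=1e-5)
            assert np.isclose(fit["p_wald"].iloc[g], ref.summary["p"]["x"],
                              atol=1e-6)

    def test_likelihood_ratio_p_matches(self, rng):
        n = 80
        x = rng.standard_normal(n)
        surv = _sim_surv(rng, n, risk=0.5 * x)
        fit = cox_screen_batch(x, surv["time"], surv["event"])
        df = pd.DataFrame({"t": surv["time"].to_numpy(),
                           "e": surv["event"].to_numpy(), "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.isclose(fit["p_lr"].iloc[0],
                          ref.log_likelihood_ratio_test().p_value, atol=1e-6)


class TestCoxUnivariate:
    def test_constant_expression_flagged(self, rng):
        surv = _sim_surv(rng, 30)
        res = cox_univariate(np.ones(30), surv)
        assert res.flagged and res.p_value == 1.0 and res.coefficient == 0.0

    def test_direction_sign_convention(self, rng):
        surv = _sim_surv(rng, 200)
        x = pd.Series(-np.log(surv["time"].to_numpy()), index=surv.index,
                      name="g")  # high x ~ early event ~ unfavorable
        res = cox_univariate(x, surv)
        assert res.direction == "unfavorable" and res.coefficient > 0
        assert np.isclose(res.hazard_ratio, np.exp(res.coefficient))

    def test_too_few_events_rejected(self, rng):
        surv = _sim_surv(rng, 20)
        surv["event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_univariate(np.arange(20.0), surv)


class TestScreenGenes:
    def test_null_p_uniform(self, null_cohort):
        m, surv, _ = null_cohort
        tab = screen_genes(m, surv)
        ks = stats.kstest(tab["p_value"], "uniform")
        assert ks.pvalue > 0.01
        assert 0.03 < tab["hit"].mean() < 0.08

    def test_planted_recall_and_direction(self, planted_cohort):
        m, surv, truth = planted_cohort
        tab = screen_genes(m, surv)
        hits = tab[tab["hit"]]
        recall = len(truth.signal_genes & set(hits.index)) / 50
        assert recall >= 0.6
        unfav_hits = hits.loc[hits.index.intersection(truth.unfavorable_genes)]
        assert (unfav_hits["coefficient"] > 0).mean() >= 0.95

    def test_alpha_one_keeps_everything(self, null_cohort):
        m, surv, _ = null_cohort
        tab = screen_genes(m.subset_genes(m.gene_ids[:50]), surv, alpha=1.0)
        assert tab["hit"].sum() == tab["converged"].sum()

    def test_sample_mismatch_rejected(self, null_cohort):
        m, surv, _ = null_cohort
        with pytest.raises(ValueError, match="missing"):
            screen_genes(m, surv.iloc[:-5])

    def test_sign_invariant_holds_for_all_rows(self, planted_cohort):
        m, surv, _ = planted_cohort
        tab = screen_genes(m.subset_genes(m.gene_ids[:100]), surv)
        fav = tab["direction"] == "favorable"
        assert ((tab["coefficient"] < 0) == fav).all()
        assert ((tab["hazard_ratio"] < 1) == fav).all()


class TestFilterConfounders:
    def test_removes_confounded_keeps_hazard(self, confounded_cohort):
        m, surv, truth = confounded_cohort
        tab = screen_genes(m, surv, alpha=1.0)  # screen everything through
        conf = tab.loc[truth.confounded_genes]
        kept = filter_confounders(conf, m, surv,
                                  binary_covariates=["tp53_mutant"])
        assert len(kept) / len(conf) <= 0.1
        hazard = tab.loc[list(truth.signal_genes)]
        kept_h = filter_confounders(hazard, m, surv,
                                    binary_covariates=["tp53_mutant"],
                                    ordinal_or_continuous_covariates=["stage"])
        assert len(kept_h) / len(hazard) >= 0.85

    def test_null_removal_rate_matches_binomial(self, null_cohort):
        m, surv, _ = null_cohort
        tab = screen_genes(m, surv, alpha=1.0)
        kept = filter_confounders(
            tab, m, surv, binary_covariates=["tp53_mutant"],
            ordinal_or_continuous_covariates=["stage", "age"])
        removed_frac = 1 - len(kept) / len(tab)
        expect = 1 - 0.95 ** 3
        assert abs(removed_frac - expect) < 0.05

    def test_empty_hits_and_order_independence(self, confounded_cohort):
        m, surv, _ = confounded_cohort
        tab = screen_genes(m, surv)
        hits = tab[tab["hit"]]
        empty = filter_confounders(hits.iloc[:0], m, surv, ["tp53_mutant"])
        assert empty.empty
        ab = filter_confounders(
            filter_confounders(hits, m, surv, binary_covariates=["tp53_mutant"]),
            m, surv, ordinal_or_continuous_covariates=["stage"])
        ba = filter_confounders(
            filter_confounders(hits, m, surv,
                               ordinal_or_continuous_covariates=["stage"]),
            m, surv, binary_covariates=["tp53_mutant"])
        assert set(ab.index) == set(ba.index)

    def test_single_level_covariate_skipped(self, confounded_cohort):
        m, surv, _ = confounded_cohort
        surv2 = surv.copy()
        surv2["tp53_mutant"] = 1
        tab = screen_genes(m, surv2)
        hits = tab[tab["hit"]]
        kept = filter_confounders(hits, m, surv2,
                                  binary_covariates=["tp53_mutant"])
        assert len(kept) == len(hits)  # test skipped, nothing removed

    def test_spearman_matches_scipy(self, rng):
        from favsig.screen import _spearman_p_vectorized
        X = rng.standard_normal((10, 40))
        y = rng.integers(1, 5, 40).astype(float)
        mine = _spearman_p_vectorized(X, y)
        for i in range(10):
            ref = stats.spearmanr(X[i], y).pvalue
            assert np.isclose(mine[i], ref, atol=1e-10)
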