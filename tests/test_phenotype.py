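"""Growth-rate identity, Spearman/BH machinery, drug similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import brentq

from favsig import (DoseResponsePanel, core_vs_sensitivity,
                    correlate_sensitivity, drug_similarity, growth_rate,
                    simulate_phenotype_panel)
from tests.oracles import brute_bh


class TestGrowthRate:
    def test_doubling_example(self):
        assert growth_rate(2.0, np.log(2.0)) == 2.0
        assert np.isclose(growth_rate(1.0, 0.6931), 1.0, atol=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.1, 1e4), st.floats(0.01, 10), st.floats(0.1, 100))
    def test_homogeneous_in_volume(self, V0, kp, a):
        assert np.isclose(growth_rate(a * V0, kp), a * growth_rate(V0, kp),
                          rtol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(10, 5000), st.floats(0.05, 5))
    def test_forward_simulation_identity(self, V0, kp):
        # linear growth V(t) = V0 + kg t; division when V = 2 V0; the
        # inter-division time must equal the doubling time ln2 / kp
        kg = growth_rate(V0, kp)
        td = brentq(lambda t: V0 + kg * t - 2 * V0, 1e-12, 1e9,
                    xtol=1e-15, rtol=1e-15)
        assert abs(td - np.log(2) / kp) / (np.log(2) / kp) < 1e-9

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            growth_rate(-1.0, 1.0)
        with pytest.raises(ValueError):
            growth_rate(1.0, 0.0)


class TestBenjaminiHochberg:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_q_values_match_stepup_definition(self, ps):
        from favsig.phenotype import _add_q
        df = pd.DataFrame({"trait": "t", "drug": range(len(ps)),
                           "rho": 0.0, "p_value": ps, "n": 10})
        q = _add_q(df)["q_value"].to_numpy()
        np.testing.assert_allclose(q, brute_bh(ps), rtol=1e-12)


class TestCorrelateSensitivity:
    def test_self_transform_gives_rho_one(self):
        panel = simulate_phenotype_panel(seed=1)
        ph = panel.phenotypes.copy()
        ph["self"] = np.exp(-np.log10(panel.ic50.iloc[:, 0]))  # monotone
        p2 = DoseResponsePanel(panel.ic50, ph)
        tab = correlate_sensitivity(p2, "self")
        row = tab[tab["drug"] == panel.drug_ids[0]].iloc[0]
        assert np.isclose(row["rho"], 1.0)

    def test_kp_strong_kg_null(self, phenotype_panel):
        kp = correlate_sensitivity(phenotype_panel, "kp")
        kg = correlate_sensitivity(phenotype_panel, "kg")
        assert kp["significant"].mean() >= 0.8
        assert kg["significant"].mean() <= 0.1

    def test_spearman_monotone_invariance(self, phenotype_panel):
        tab1 = correlate_sensitivity(phenotype_panel, "kp")
        ph = phenotype_panel.phenotypes.copy()
        ph["kp"] = ph["kp"] ** 3  # strictly monotone transform
        tab2 = correlate_sensitivity(
            DoseResponsePanel(phenotype_panel.ic50, ph), "kp")
        np.testing.assert_allclose(tab1["rho"], tab2["rho"], atol=1e-12)

    def test_missing_trait_rejected(self, phenotype_panel):
        with pytest.raises(ValueError):
            correlate_sensitivity(phenotype_panel, "nope")


class TestCoreVsSensitivity:
    def test_planted_release_resistance_signal(self, phenotype_panel):
        tab = core_vs_sensitivity(phenotype_panel)
        pc = tab[(tab["trait"] == "CORE_phosphocholine") & tab["significant"]]
        fam0 = [d for d in phenotype_panel.drug_ids if d.endswith("fam0")]
        assert len(set(pc["drug"]) & set(fam0)) >= len(fam0) // 2
        assert (pc[pc["drug"].isin(fam0)]["rho"] < 0).all()  # release ~ resistance

    def test_constant_metabolite_skipped(self, phenotype_panel):
        ph = phenotype_panel.phenotypes.copy()
        ph["CORE_constant"] = 1.0
        tab = core_vs_sensitivity(DoseResponsePanel(phenotype_panel.ic50, ph))
        assert "CORE_constant" not in set(tab["trait"])

    def test_fdr_scopes(self, phenotype_panel):
        g = core_vs_sensitivity(phenotype_panel, fdr_scope="global")
        pm = core_vs_sensitivity(phenotype_panel, fdr_scope="per_metabolite")
        assert len(g) == len(pm)
        with pytest.raises(ValueError):
            core_vs_sensitivity(phenotype_panel, fdr_scope="nope")


class TestDrugSimilarity:
    def test_matrix_properties(self, phenotype_panel):
        sim = drug_similarity(phenotype_panel)
        S = sim.similarity.to_numpy()
        np.testing.assert_allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_identical_drugs_merge_first(self, rng):
        base = rng.lognormal(0, 1, (20, 1))
        ic50 = pd.DataFrame(
            np.hstack([base, base, rng.lognormal(0, 1, (20, 2))]),
            index=[f"c{i}" for i in range(20)],
            columns=["a", "a2", "b", "c"])
        sim = drug_similarity(DoseResponsePanel(ic50))
        assert np.isclose(sim.similarity.loc["a", "a2"], 1.0)
        first = sim.linkage_matrix[0, :2].astype(int)
        assert set(first) == {0, 1}

    def test_input_order_invariance(self, phenotype_panel):
        sim1 = drug_similarity(phenotype_panel)
        perm = list(phenotype_panel.drug_ids[::-1])
        p2 = DoseResponsePanel(phenotype_panel.ic50[perm],
                               phenotype_panel.phenotypes)
        sim2 = drug_similarity(p2)
        c1 = sim1.cut(3)
        c2 = sim2.cut(3).loc[c1.index]
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(c1, c2) == 1.0

    def test_newick_roundtrip(self, phenotype_panel):
        nwk = drug_similarity(phenotype_panel).to_newick()
        assert nwk.endswith(";")
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(nwk), "newick")
        names = {t.name for t in tree.get_terminals()}
        assert names == set(phenotype_panel.drug_ids)

    def test_zero_variance_drug_excluded(self, rng):
        ic50 = pd.DataFrame(rng.lognormal(0, 1, (15, 3)),
                            columns=["a", "b", "c"],
                            index=[f"c{i}" for i in range(15)])
        ic50["d"] = 2.0
        sim = drug_similarity(DoseResponsePanel(ic50))
        assert "d" not in sim.similarity.columns
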