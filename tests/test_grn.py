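"""ODE network inference, consensus filtering, hubs, family enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import mesotraject as mt


class TestFitOdeGrn:
    def test_pseudotime_outside_unit_interval_rejected(self):
        expr = np.random.default_rng(0).normal(size=(6, 20))
        t = np.linspace(0, 1.2, 20)
        with pytest.raises(mt.ParameterError):
            mt.grn.fit_ode_grn(expr, t, z=4, n_runs=2)

    def test_too_few_tfs_rejected(self):
        expr = np.ones((3, 10))
        with pytest.raises(mt.ParameterError):
            mt.grn.fit_ode_grn(expr, np.linspace(0, 1, 10), z=4)

    def test_coupled_pair_outranks_independent_pair(self):
        """A strongly coupled TF pair gets higher |A| than decoupled TFs."""
        n, C = 6, 200
        A = np.diag(np.full(n, -0.3))
        A[1, 0] = 2.0      # TF1 drives TF2 strongly
        truth = mt.GrnTruth(tf_ids=[f"TF{i + 1:03d}" for i in range(n)],
                            targets=[], A_true=A,
                            edge_list=[("TF001", "TF002", 1)], sparsity=0.0)
        expr, t = mt.syndata.simulate_latent_expression(truth, C, seed=0)
        ode = mt.grn.fit_ode_grn(expr, t, z=4, n_runs=20, seed=0)
        coupled = abs(ode.A.loc["TF002", "TF001"])
        decoupled = abs(ode.A.loc["TF004", "TF003"])
        assert coupled > decoupled

    def test_seed_reproducibility_and_run_mean(self, small_grn):
        expr, t = mt.syndata.simulate_latent_expression(small_grn, 100,
                                                        seed=3)
        a = mt.grn.fit_ode_grn(expr, t, z=4, n_runs=8, seed=5)
        b = mt.grn.fit_ode_grn(expr, t, z=4, n_runs=8, seed=5)
        pd.testing.assert_frame_equal(a.A, b.A)
        np.testing.assert_allclose(a.A.to_numpy(),
                                   a.per_run_A.mean(axis=0), atol=1e-12)

    def test_run_averaging_reduces_variance(self, small_grn):
        """Averaged weights vary less across repetitions than single runs."""
        expr, t = mt.syndata.simulate_latent_expression(small_grn, 150,
                                                        seed=4)
        reps_avg, reps_single = [], []
        for rep in range(6):
            avg = mt.grn.fit_ode_grn(expr, t, z=4, n_runs=20,
                                     seed=100 + rep, keep_runs=False)
            single = mt.grn.fit_ode_grn(expr, t, z=4, n_runs=1,
                                        seed=200 + rep, keep_runs=False)
            reps_avg.append(avg.A.to_numpy())
            reps_single.append(single.A.to_numpy())
        var_avg = np.var(np.stack(reps_avg), axis=0).mean()
        var_single = np.var(np.stack(reps_single), axis=0).mean()
        assert var_avg < var_single


class TestConsensus:
    @staticmethod
    def _toy_networks():
        tf_ids = [f"TF{i + 1:03d}" for i in range(5)]
        A = pd.DataFrame(np.zeros((5, 5)), index=tf_ids, columns=tf_ids)
        A.loc["TF002", "TF001"] = 0.8     # TF001 -> TF002
        A.loc["TF003", "TF001"] = 0.3
        A.loc["TF004", "TF002"] = -0.6
        A.loc["TF005", "TF004"] = 0.05
        ode = mt.OdeGrn(tf_ids=tf_ids, z=4, W=np.zeros((5, 4)),
                        b=np.zeros(4), A=A, n_runs=1)
        tom = pd.DataFrame(np.ones((5, 5)), index=tf_ids, columns=tf_ids)
        edges = {frozenset(("TF001", "TF002")), frozenset(("TF002", "TF004")),
                 frozenset(("TF004", "TF005"))}
        co = mt.CoexprNetwork(beta=6.0, adjacency=tom, tom=tom,
                              modules=pd.Series("M1", index=tf_ids),
                              edge_threshold=0.5, edges=edges)
        return ode, co

    def test_empty_coexpression_empty_consensus(self):
        ode, co = self._toy_networks()
        co.edges = set()
        net = mt.grn.consensus_network(ode, co, 0.1)
        assert net.edges == []

    def test_matches_exhaustive_intersection(self):
        ode, co = self._toy_networks()
        net = mt.grn.consensus_network(ode, co, 0.1)
        expected = set()
        for reg in ode.tf_ids:
            for tgt in ode.tf_ids:
                if reg != tgt and abs(ode.A.loc[tgt, reg]) >= 0.1 \
                        and frozenset((reg, tgt)) in co.edges:
                    expected.add((reg, tgt))
        assert {(a, b) for a, b, _ in net.edges} == expected
        assert expected == {("TF001", "TF002"), ("TF002", "TF004")}

    def test_stricter_cutoff_is_subset(self):
        ode, co = self._toy_networks()
        loose = {(a, b) for a, b, _ in
                 mt.grn.consensus_network(ode, co, 0.1).edges}
        strict = {(a, b) for a, b, _ in
                  mt.grn.consensus_network(ode, co, 0.5).edges}
        assert strict <= loose

    def test_consensus_subset_of_both_parents(self):
        ode, co = self._toy_networks()
        net = mt.grn.consensus_network(ode, co, 0.1)
        for reg, tgt, w in net.edges:
            assert abs(ode.A.loc[tgt, reg]) >= 0.1
            assert co.has_edge(reg, tgt)
            assert w == ode.A.loc[tgt, reg]


class TestHubs:
    def test_star_center_ranked_first(self):
        edges = [("HUB", f"N{i}", 1.0) for i in range(5)]
        net = mt.ConsensusNetwork(edges=edges, cutoff=0.1)
        ranked = mt.grn.hub_nodes(net, top_k=3)
        assert ranked.loc[0, "node"] == "HUB"
        assert ranked.loc[0, "degree"] == 5

    def test_degree_matches_adjacency_list_oracle(self, small_grn):
        rng = np.random.default_rng(8)
        nodes = [f"TF{i:03d}" for i in range(1, 9)]
        edges = [(a, b, float(rng.normal()))
                 for a in nodes for b in nodes
                 if a < b and rng.random() < 0.4]
        net = mt.ConsensusNetwork(edges=edges, cutoff=0.0)
        ranked = mt.grn.hub_nodes(net, top_k=100)
        oracle = {}
        for a, b, _ in edges:
            oracle.setdefault(a, set()).add(b)
            oracle.setdefault(b, set()).add(a)
        for _, row in ranked.iterrows():
            assert row["degree"] == len(oracle[row["node"]])
        assert len(ranked) == len(oracle)   # top_k > node count -> full list

    def test_nonpositive_top_k_rejected(self):
        net = mt.ConsensusNetwork(edges=[("a", "b", 1.0)], cutoff=0.0)
        with pytest.raises(mt.ParameterError):
            mt.grn.hub_nodes(net, top_k=0)


class TestFamilyEnrichment:
    @staticmethod
    def _family_map(n_hsf=20, n_total=100):
        fam = {}
        for i in range(1, n_total + 1):
            fam[f"TF{i:03d}"] = "HSF" if i <= n_hsf else "OTHER"
        return fam

    def test_expected_count_formula(self):
        fam = self._family_map()
        high = [f"TF{i:03d}" for i in range(1, 51)]
        tab = mt.grn.tf_family_enrichment(high, high[:10], fam)
        assert tab.loc["HSF", "expected_M"] == pytest.approx(50 * 20 / 100)

    def test_worked_chi2_table(self):
        """Observed (20,30) vs expected (10,40): chi2 = 12.5, df=1."""
        fam = self._family_map()
        high = ([f"TF{i:03d}" for i in range(1, 21)]         # 20 in HSF
                + [f"TF{i:03d}" for i in range(21, 51)])     # 30 outside
        tab = mt.grn.tf_family_enrichment(high, high, fam)
        assert tab.loc["HSF", "chi2_M"] == pytest.approx(12.5)
        assert tab.loc["HSF", "p_M"] == pytest.approx(chi2.sf(12.5, 1),
                                                      rel=1e-8)

    def test_observed_equal_expected_gives_p_one(self):
        fam = self._family_map()
        high = ([f"TF{i:03d}" for i in range(1, 11)]          # 10 HSF
                + [f"TF{i:03d}" for i in range(21, 61)])      # 40 OTHER
        tab = mt.grn.tf_family_enrichment(high, high, fam)
        np.testing.assert_allclose(tab["p_M"], 1.0)

    def test_expected_sums_to_high_count(self):
        fam = self._family_map()
        rng = np.random.default_rng(0)
        high_M = list(rng.choice(sorted(fam), 37, replace=False))
        high_BS = list(rng.choice(sorted(fam), 12, replace=False))
        tab = mt.grn.tf_family_enrichment(high_M, high_BS, fam)
        assert tab["expected_M"].sum() == pytest.approx(len(high_M))
        assert tab["expected_BS"].sum() == pytest.approx(len(high_BS))

    def test_unannotated_tf_rejected(self):
        with pytest.raises(mt.ParameterError):
            mt.grn.tf_family_enrichment(["TFX"], [], {"TF001": "HSF"})
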