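from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thymonet import network, select, simulate_dataset
from thymonet.types import GREY

from conftest import make_matrix, make_meta


def _adjacency(a, genes=None):
    genes = genes or [f"g{i}" for i in range(a.shape[0])]
    return network.Adjacency(genes, a, 1, "unsigned")


def _modules(mapping):
    return network.ModuleAssignment(pd.Series(mapping))


class TestIntramodularConnectivity:
    def test_three_gene_single_module_closed_form(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        conn = select.intramodular_connectivity(
            _adjacency(a), _modules({"g0": "tan", "g1": "tan", "g2": "tan"}))
        assert (conn["kTotal"] == 1.0).all()
        assert (conn["kWithin"] == 1.0).all()
        assert (conn["kOut"] == 0.0).all()

    def test_singleton_module_has_zero_kwithin(self):
        a = np.full((3, 3), 0.4)
        np.fill_diagonal(a, 1.0)
        conn = select.intramodular_connectivity(
            _adjacency(a), _modules({"g0": "tan", "g1": "blue", "g2": "blue"}))
        assert conn.loc["g0", "kWithin"] == 0.0
        assert conn.loc["g0", "kTotal"] == pytest.approx(0.8)

    def test_grey_genes_get_zero_kwithin(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        conn = select.intramodular_connectivity(
            _adjacency(a),
            _modules({"g0": GREY, "g1": GREY, "g2": "tan", "g3": "tan"}))
        assert conn.loc["g0", "kWithin"] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        n = 12
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        labels = {f"g{i}": ["tan", "blue", "brown"][i % 3] for i in range(n)}
        conn = select.intramodular_connectivity(_adjacency(a),
                                                _modules(labels))
        for i in range(n):
            kt = sum(a[i, j] for j in range(n) if j != i)
            kw = sum(a[i, j] for j in range(n)
                     if j != i and labels[f"g{j}"] == labels[f"g{i}"])
            assert conn.loc[f"g{i}", "kTotal"] == pytest.approx(kt, abs=1e-12)
            assert conn.loc[f"g{i}", "kWithin"] == pytest.approx(kw, abs=1e-12)
        assert (conn["kWithin"] <= conn["kTotal"] + 1e-12).all()


class TestSelectHubs:
    def _conn(self, kwithin, module="tan"):
        return pd.DataFrame({
            "module": module, "kWithin": kwithin,
            "kTotal": np.asarray(kwithin) + 0.5,
            "kOut": 0.5,
        }, index=[f"g{i:03d}" for i in range(len(kwithin))])

    def test_five_percent_of_hundred_gives_five(self, rng):
        conn = self._conn(rng.uniform(0, 10, 100))
        hubs = select.select_hubs(conn, ["tan"], hub_quantile=0.05)
        assert len(hubs) == 5
        assert hubs["kWithin"].min() >= conn["kWithin"].quantile(0.95)

    def test_all_ties_break_lexicographically(self):
        conn = self._conn([2.0] * 10)
        hubs = select.select_hubs(conn, ["tan"], hub_quantile=0.3)
        assert list(hubs.index) == ["g000", "g001", "g002"]  # ceil(0.3*10)=3

    def test_only_significant_modules_considered(self, rng):
        conn = pd.concat([self._conn(rng.uniform(0, 1, 20), "tan"),
                          self._conn(rng.uniform(5, 9, 20), "blue")
                          .set_index(pd.Index([f"h{i}" for i in range(20)]))])
        hubs = select.select_hubs(conn, ["tan"], hub_quantile=0.1)
        assert set(hubs["module"]) == {"tan"}

    def test_planted_strong_genes_dominate_hub_slots(self):
        wins = total = 0
        for seed in range(10):
            mrna, _, _, _, truth = simulate_dataset(
                seed=seed, n_genes=120, module_sizes=(100,),
                trait_effects=(), w_range=(0.5, 0.95),
                mirna_spec=(20, 3, 5.3), tf_spec=(4, 2))
            r = network.correlation_matrix(mrna)
            adj = network.adjacency_from_correlation(r, 6)
            labels = {g: ("tan" if m == 1 else GREY)
                      for g, m in truth.module_of_gene.items()}
            conn = select.intramodular_connectivity(adj, _modules(labels))
            hubs = select.select_hubs(conn, ["tan"], hub_quantile=0.1)
            # hubs should be the highest-w members; compare against the top
            # decile of planted weights via kWithin ranking of all members
            members = conn[conn["module"] == "tan"]["kWithin"]
            top = set(members.nlargest(len(hubs)).index)
            wins += len(set(hubs.index) & top)
            total += len(hubs)
        assert wins / total >= 0.8


class TestSelectHGS:
    def _inputs(self, n=120, n_pass=120):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(n)]
        gs = pd.DataFrame({
            "GS": rng.uniform(0.2, 0.9, n) * rng.choice([-1, 1], n),
            "p": np.where(np.arange(n) < n_pass, 0.01, 0.5),
        }, index=genes)
        mm = pd.DataFrame({"tan": rng.uniform(-1, 1, n)}, index=genes)
        modules = _modules({g: "tan" for g in genes})
        return gs, mm, modules

    def test_cap_fifty_of_many_candidates(self):
        gs, mm, modules = self._inputs()
        hgs = select.select_hgs({"E": gs}, mm, modules, [("tan", "E")],
                                alpha=0.05, cap=50)
        assert hgs["gene"].nunique() == 50
        # ranked by |GS| descending
        assert (hgs["GS"].abs().diff().dropna() <= 1e-12).all()

    def test_no_candidate_passes_alpha(self):
        gs, mm, modules = self._inputs(n_pass=0)
        hgs = select.select_hgs({"E": gs}, mm, modules, [("tan", "E")],
                                alpha=0.05, cap=50)
        assert len(hgs) == 0

    def test_direction_follows_gs_sign(self):
        gs, mm, modules = self._inputs(n=10)
        hgs = select.select_hgs({"A": gs}, mm, modules, [("tan", "A")],
                                alpha=0.05, cap=10)
        for _, row in hgs.iterrows():
            assert row["direction"] == ("hyper" if row["GS"] > 0 else "hypo")

    def test_gene_can_carry_two_traits_within_cap(self):
        genes = ["g1", "g2"]
        gs_a = pd.DataFrame({"GS": [0.9, 0.1], "p": [0.001, 0.9]}, index=genes)
        gs_e = pd.DataFrame({"GS": [-0.8, 0.7], "p": [0.002, 0.01]},
                            index=genes)
        mm = pd.DataFrame({"tan": [0.9, 0.8]}, index=genes)
        modules = _modules({g: "tan" for g in genes})
        hgs = select.select_hgs({"A": gs_a, "E": gs_e}, mm, modules,
                                [("tan", "A"), ("tan", "E")], cap=2)
        assert hgs["gene"].nunique() == 2
        assert len(hgs[hgs["gene"] == "g1"]) == 2  # both traits kept


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    stats_all = [ranks[list(c)].sum()
                 for c in combinations(range(len(pooled)), n)]
    extreme = sum(abs(s - mu) >= abs(obs - mu) - 1e-9 for s in stats_all)
    return extreme / len(stats_all)


class TestWilcoxonDE:
    meta = make_meta({"A": ["a1", "a2", "a3"], "E": ["e1", "e2", "e3"]})

    def test_fully_separated_groups(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]],
                        samples=["a1", "a2", "a3", "e1", "e2", "e3"])
        p = select.wilcoxon_de(m, self.meta)
        assert p.iloc[0] == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_identical_groups(self):
        m = make_matrix([[1, 2, 3, 1, 2, 3]],
                        samples=["a1", "a2", "a3", "e1", "e2", "e3"])
        p = select.wilcoxon_de(m, self.meta)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_4v4(self, rng):
        meta = make_meta({"A": [f"a{i}" for i in range(4)],
                          "E": [f"e{i}" for i in range(4)]})
        x = rng.standard_normal((5, 8))
        m = make_matrix(x, samples=list(meta.sample_ids))
        p = select.wilcoxon_de(m, meta)
        for i in range(5):
            assert p.iloc[i] == pytest.approx(
                wilcoxon_enumeration_oracle(x[i, :4], x[i, 4:]), abs=1e-12)


class TestAnovaDE:
    def test_zero_noise_equal_means(self):
        meta = make_meta({"A": ["a1", "a2"], "B": ["b1", "b2"],
                          "E": ["e1", "e2"]})
        m = make_matrix([[3.0] * 6], samples=list(meta.sample_ids))
        out = select.anova_de(m, meta)
        assert out["anova_p"].iloc[0] == 1.0

    def test_two_groups_equals_t_test(self, rng):
        meta = make_meta({"A": [f"a{i}" for i in range(5)],
                          "E": [f"e{i}" for i in range(5)]})
        x = rng.standard_normal((4, 10))
        m = make_matrix(x, samples=list(meta.sample_ids))
        out = select.anova_de(m, meta, adjust="none")
        for i in range(4):
            t_p = stats.ttest_ind(x[i, :5], x[i, 5:]).pvalue
            assert out["anova_p"].iloc[i] == pytest.approx(t_p, abs=1e-10)

    def test_bh_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_bh_monotone_and_bounded(self, rng, small_sim):
        mrna, _, _, meta, _ = small_sim
        out = select.anova_de(mrna, meta)
        assert (out["anova_p_adj"] <= 1.0).all()
        ranked = out.sort_values("anova_p")
        assert (ranked["anova_p_adj"].diff().dropna() >= -1e-12).all()


class TestFoldChange:
    meta = make_meta({"A": ["a1", "a2"], "E": ["e1", "e2"]})

    @pytest.mark.parametrize("delta,expected", [(1.0, 2.0), (-1.0, -2.0),
                                                (0.0, 1.0), (0.5, 2 ** 0.5)])
    def test_signed_convention(self, delta, expected):
        m = make_matrix([[5.0 + delta, 5.0 + delta, 5.0, 5.0]],
                        samples=["a1", "a2", "e1", "e2"])
        fc = select.fold_change(m, self.meta)
        assert fc.iloc[0] == pytest.approx(expected)

    def test_antisymmetry(self, rng):
        m = make_matrix(rng.standard_normal((6, 4)) + 8,
                        samples=["a1", "a2", "e1", "e2"])
        ae = select.fold_change(m, self.meta, "A", "E")
        ea = select.fold_change(m, self.meta, "E", "A")
        nz = ae[np.abs(ae) > 1 + 1e-9]
        assert np.allclose(nz, -ea[nz.index])

    def test_magnitude_at_least_one(self, rng, small_sim):
        mrna, _, _, meta, _ = small_sim
        fc = select.fold_change(mrna, meta)
        assert (np.abs(fc) >= 1.0).all()


def test_de_results_hyper_group_assignment(small_sim):
    mrna, _, _, meta, _ = small_sim
    de = select.de_results(mrna.subset_features(mrna.feature_ids[:50]), meta)
    sig = de[de["wilcoxon_p"] < 0.05]
    assert (sig.loc[sig["fold_change"] > 1, "hyper_group"] == "A").all()
    assert (sig.loc[sig["fold_change"] < -1, "hyper_group"] == "E").all()
    assert (de.loc[de["wilcoxon_p"] >= 0.05, "hyper_group"] == "none").all()
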