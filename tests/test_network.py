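import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thymonet import network
from thymonet.types import GREY

from conftest import make_matrix


def pearson_oracle(x, y):
    """Textbook two-pass Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap reference."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                       if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestCorrelationMatrix:
    def test_duplicated_gene_has_r_one(self, rng):
        x = rng.standard_normal(6)
        m = make_matrix([x, x, rng.standard_normal(6)])
        r = network.correlation_matrix(m)
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_gene_has_r_minus_one(self, rng):
        x = rng.standard_normal(6)
        r = network.correlation_matrix(make_matrix([x, -x]))
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self, rng):
        m = make_matrix(rng.standard_normal((4, 6)))
        r = network.correlation_matrix(m)
        for i in range(4):
            for j in range(4):
                assert r.iloc[i, j] == pytest.approx(
                    pearson_oracle(m.values[i], m.values[j]), abs=1e-12)

    def test_pairwise_complete_over_missing(self, rng):
        x = rng.standard_normal((3, 10))
        m = make_matrix(x)
        m.data.iloc[0, 0] = np.nan
        r = network.correlation_matrix(m)
        assert r.iloc[0, 1] == pytest.approx(
            pearson_oracle(x[0, 1:], x[1, 1:]), abs=1e-12)

    def test_zero_variance_feature_errors_by_name(self, rng):
        m = make_matrix([np.ones(5), rng.standard_normal(5)],
                        features=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            network.correlation_matrix(m)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            network.correlation_matrix(make_matrix([[1.0, 2.0], [2.0, 1.0]]))


class TestAdjacency:
    def test_unsigned_power_rule(self):
        r = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"),
                         columns=list("ab"))
        a = network.adjacency_from_correlation(r, beta=9)
        assert a.a[0, 1] == pytest.approx(0.5 ** 9)
        assert a.a[0, 0] == 1.0

    def test_negative_r_sign_discarded_unsigned(self):
        r = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"),
                         columns=list("ab"))
        a = network.adjacency_from_correlation(r, beta=9)
        assert a.a[0, 1] == pytest.approx(0.5 ** 9)

    def test_perfect_correlation_stays_one(self):
        r = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"),
                         columns=list("ab"))
        for beta in (1, 9, 35):
            a = network.adjacency_from_correlation(r, beta=beta)
            assert a.a[0, 1] == 1.0

    def test_signed_transform(self):
        r = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=list("ab"),
                         columns=list("ab"))
        a = network.adjacency_from_correlation(r, 2, "signed")
        assert a.a[0, 1] == 0.0

    @given(r=st.floats(-0.99, 0.99), beta=st.integers(1, 34))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjacency_nonincreasing_in_beta(self, r, beta):
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=list("ab"),
                          columns=list("ab"))
        a1 = network.adjacency_from_correlation(rm, beta).a[0, 1]
        a2 = network.adjacency_from_correlation(rm, beta + 1).a[0, 1]
        assert a2 <= a1 + 1e-15


class TestScaleFreeFit:
    def test_exact_power_law_gives_r2_one(self):
        # counts 2520/v at connectivity v: log10(freq) is linear in log10(k)
        k = np.concatenate([np.full(2520 // v, float(v))
                            for v in range(1, 11)])
        r2, slope = network.scale_free_fit(k, n_bins=10)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert slope < 0

    def test_constant_k_errors(self):
        with pytest.raises(ValueError, match="single bin"):
            network.scale_free_fit(np.full(100, 3.0))

    def test_matches_binning_regression_oracle(self, rng):
        k = rng.uniform(0.5, 20, size=400)
        r2, slope = network.scale_free_fit(k, n_bins=10)
        # independent re-implementation
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = k[idx == b]
            if len(sel):
                xs.append(np.log10(sel.mean()))
                ys.append(np.log10(len(sel) / len(k)))
        coef = np.polyfit(xs, ys, 1)
        resid = np.array(ys) - np.polyval(coef, xs)
        r2_o = 1 - resid @ resid / ((ys - np.mean(ys)) @ (ys - np.mean(ys)))
        assert r2 == pytest.approx(r2_o, abs=1e-9)
        assert slope == pytest.approx(coef[0], abs=1e-9)


class TestPickSoftThreshold:
    def test_first_qualifying_beta_matches_full_scan(self, small_sim, config):
        mrna = small_sim[0]
        r = network.correlation_matrix(mrna)
        report = network.pick_soft_threshold(r, grid=range(1, 21),
                                             r2_cutoff=0.87)
        t = report.table
        qualifying = t[(t["r2"] >= 0.87) & (t["slope"] < 0)]["beta"]
        assert report.chosen_beta == int(qualifying.iloc[0])
        assert report.reached_cutoff

    def test_zero_cutoff_picks_smallest_negative_slope_beta(self, small_sim):
        r = network.correlation_matrix(small_sim[0])
        report = network.pick_soft_threshold(r, grid=range(1, 6),
                                             r2_cutoff=1e-9)
        t = report.table
        first_neg = int(t[t["slope"] < 0]["beta"].iloc[0])
        assert report.chosen_beta == first_neg

    def test_report_covers_whole_grid(self, small_sim):
        r = network.correlation_matrix(small_sim[0])
        grid = [1, 5, 9, 13]
        report = network.pick_soft_threshold(r, grid=grid)
        assert list(report.table["beta"]) == grid
        assert report.table["r2"].notna().all()

    def test_unreachable_cutoff_falls_back_with_warning(self, small_sim,
                                                        caplog):
        r = network.correlation_matrix(small_sim[0])
        with caplog.at_level("WARNING", logger="thymonet.network"):
            report = network.pick_soft_threshold(r, grid=[1, 2],
                                                 r2_cutoff=0.999999)
        assert not report.reached_cutoff
        assert report.chosen_beta in (1, 2)


class TestTopologicalOverlap:
    def test_saturated_three_node_graph(self):
        a = network.Adjacency(list("abc"), np.ones((3, 3)), 1, "unsigned")
        tom = network.topological_overlap(a)
        assert np.allclose(tom.tom, 1.0)

    def test_empty_graph(self):
        a = network.Adjacency(list("abc"), np.eye(3), 1, "unsigned")
        tom = network.topological_overlap(a)
        assert np.allclose(tom.tom, np.eye(3))

    def test_matches_triple_loop_oracle(self, rng):
        a = random_adjacency(rng, 10)
        tom = network.topological_overlap(
            network.Adjacency([f"g{i}" for i in range(10)], a, 1, "unsigned"))
        assert np.max(np.abs(tom.tom - tom_oracle(a))) < 1e-12


def block_tom(rng, sizes=(40, 40), within=0.8, between=0.05, jitter=0.02):
    n = sum(sizes)
    t = rng.uniform(between - jitter, between + jitter, size=(n, n))
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = rng.uniform(
            within - jitter, within + jitter, size=(s, s))
        start += s
    t = (t + t.T) / 2
    np.fill_diagonal(t, 1.0)
    return network.TOMatrix([f"g{i:03d}" for i in range(n)], t)


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_pure(self, rng):
        tom = block_tom(rng)
        modules = network.cluster_and_cut(tom, min_module_size=10)
        colors = modules.module_colors()
        assert len(colors) == 2
        for color in colors:
            idx = sorted(int(g[1:]) for g in modules.genes_in(color))
            assert idx in (list(range(40)), list(range(40, 80)))

    def test_min_size_above_n_genes_gives_all_grey(self, rng):
        tom = block_tom(rng, sizes=(10, 10))
        modules = network.cluster_and_cut(tom, min_module_size=50)
        assert (modules.labels == GREY).all()

    def test_largest_module_is_turquoise(self, rng):
        tom = block_tom(rng, sizes=(50, 30))
        modules = network.cluster_and_cut(tom, min_module_size=10)
        sizes = modules.labels.value_counts()
        assert sizes.idxmax() == "turquoise"
        assert modules.labels["g000"] == "turquoise"

    def test_grey_conservation(self, rng):
        tom = block_tom(rng, sizes=(40, 25, 12))
        modules = network.cluster_and_cut(tom, min_module_size=20)
        sizes = modules.sizes()
        assert sum(sizes.values()) == 77


class TestEigengenes:
    def _modules(self, labels, genes):
        return network.ModuleAssignment(pd.Series(labels, index=genes))

    def test_identical_genes_rank_one_module(self, rng):
        x = rng.standard_normal(8)
        m = make_matrix([x, x, x])
        me = network.module_eigengenes(
            m, self._modules(["blue"] * 3, m.feature_ids))
        assert me.variance_explained["blue"] == pytest.approx(1.0)
        std = (x - x.mean()) / x.std()
        assert np.allclose(me.me.loc["blue"], std)

    def test_me_standardized_and_aligned_to_mean(self, small_sim, config):
        mrna = small_sim[0]
        res = __import__("thymonet.pipeline", fromlist=["run_network"]) \
            .run_network(mrna, config)
        for color in res.modules.module_colors():
            e = res.eigengenes.me.loc[color].to_numpy()
            assert abs(e.mean()) < 1e-10
            assert e.std() == pytest.approx(1.0)
            mean_prof = mrna.subset_features(
                res.modules.genes_in(color)).values.mean(axis=0)
            assert np.corrcoef(e, mean_prof)[0, 1] > 0

    def test_negating_members_flips_eigengene(self, rng):
        x = rng.standard_normal((5, 12))
        base = x[0] + 0.2 * rng.standard_normal((5, 12))
        mods = self._modules(["tan"] * 5, [f"g{i}" for i in range(5)])
        me_pos = network.module_eigengenes(make_matrix(base), mods)
        me_neg = network.module_eigengenes(make_matrix(-base), mods)
        assert np.allclose(me_pos.me.loc["tan"], -me_neg.me.loc["tan"],
                           atol=1e-10)

    def test_against_power_iteration_oracle(self, rng):
        x = rng.standard_normal((20, 15))
        mods = self._modules(["brown"] * 20, [f"g{i}" for i in range(20)])
        me = network.module_eigengenes(make_matrix(x), mods)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        # power iteration on the sample covariance z.T z
        c = z.T @ z
        v = np.ones(15)
        for _ in range(500):
            v = c @ v
            v /= np.linalg.norm(v)
        r = np.corrcoef(me.me.loc["brown"], v)[0, 1]
        assert abs(r) > 1 - 1e-10

    def test_single_gene_module_warns(self, rng, caplog):
        m = make_matrix(rng.standard_normal((1, 6)))
        with caplog.at_level("WARNING", logger="thymonet.network"):
            me = network.module_eigengenes(
                m, self._modules(["red"], m.feature_ids))
        assert "single gene" in caplog.text
        assert me.variance_explained["red"] == 1.0


class TestModuleMembership:
    def test_gene_equal_to_me_has_kme_one(self, rng):
        x = rng.standard_normal(10)
        m = make_matrix([x, x])
        me = network.EigengeneMatrix(
            me=pd.DataFrame([(x - x.mean()) / x.std()], index=["blue"],
                            columns=m.sample_ids),
            variance_explained=pd.Series({"blue": 1.0}))
        kme = network.module_membership(m, me)
        assert kme.loc["g0", "blue"] == pytest.approx(1.0)

    def test_orthogonal_gene_has_kme_zero(self):
        n = 10
        x = np.sin(np.arange(n))
        y = np.cos(np.arange(n))
        y -= y.mean()
        x -= x.mean()
        y -= (x @ y) / (x @ x) * x  # make empirically orthogonal
        m = make_matrix([y])
        me = network.EigengeneMatrix(
            me=pd.DataFrame([x / x.std()], index=["blue"],
                            columns=m.sample_ids),
            variance_explained=pd.Series({"blue": 1.0}))
        kme = network.module_membership(m, me)
        assert kme.loc["g0", "blue"] == pytest.approx(0.0, abs=1e-12)

    def test_strong_members_outrank_background(self, small_sim, config):
        mrna, _, _, _, truth = small_sim
        from thymonet.pipeline import run_network
        res = run_network(mrna, config)
        labels = truth.module_labels(mrna.feature_ids)
        # planted module 1 vs background genes on module 1's detected colour
        planted = [g for g, lab in zip(mrna.feature_ids, labels) if lab == 1]
        bg = [g for g, lab in zip(mrna.feature_ids, labels) if lab == 0]
        color = res.modules.labels[planted].mode()[0]
        kme = res.kme[color]
        frac = np.mean([kme[p] > kme[b] for p in planted[:30]
                        for b in bg[:30]])
        assert frac >= 0.99
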