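"""SparCC inference, permutation FDR, thresholding and graph topology."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rotastoich.network import (
    CorrelationEstimate,
    aggregate_taxa,
    bh_fdr,
    build_network,
    permutation_pvalues,
    sparcc_correlations,
    topology,
)
from rotastoich.synthetic import CountMatrix, CountSpec, SyntheticConfig, generate_count_matrix


def _null_matrix(n_taxa=10, n_samples=60, seed=0, depth=2000):
    cfg = SyntheticConfig(
        seed=seed,
        treatments=("A",),
        count_spec=CountSpec(n_taxa=n_taxa, read_depth=depth,
                             n_samples_per_treatment=n_samples),
    )
    return generate_count_matrix(cfg)


class TestSparcc:
    def test_diagonal_and_symmetry(self):
        est = sparcc_correlations(_null_matrix())
        r = est.rho.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert (np.abs(r) <= 1.0).all()

    def test_recovers_planted_correlation(self, recovery_count_matrix):
        est = sparcc_correlations(recovery_count_matrix)
        r = est.rho.to_numpy().copy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.abs(r).argmax(), r.shape)
        assert {i, j} == {0, 1}
        assert r[i, j] > 0.6

    def test_null_shuffled_rows_stay_weak(self, recovery_count_matrix):
        rng = np.random.default_rng(99)
        counts = recovery_count_matrix.counts.to_numpy().copy()
        for row in counts:
            rng.shuffle(row)
        shuffled = CountMatrix(
            counts=pd.DataFrame(counts,
                                index=recovery_count_matrix.counts.index,
                                columns=recovery_count_matrix.counts.columns),
            sample_treatments=recovery_count_matrix.sample_treatments,
        )
        est = sparcc_correlations(shuffled)
        off = np.abs(est.rho.to_numpy()[np.triu_indices(40, 1)])
        assert np.quantile(off, 0.95) < 0.4

    def test_dirichlet_mode_close_to_pseudocount(self):
        m = _null_matrix(seed=3)
        a = sparcc_correlations(m, method="pseudocount").rho.to_numpy()
        b = sparcc_correlations(m, method="dirichlet",
                                n_inner_iterations=10, seed=1).rho.to_numpy()
        assert np.abs(a - b).max() < 0.3

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4 taxa"):
            m = _null_matrix(n_taxa=4)
            trimmed = CountMatrix(counts=m.counts.iloc[:3],
                                  sample_treatments=m.sample_treatments)
            sparcc_correlations(trimmed)
        with pytest.raises(ValueError, match="5 samples"):
            m = _null_matrix()
            small = CountMatrix(counts=m.counts.iloc[:, :4],
                                sample_treatments=m.sample_treatments.iloc[:4])
            sparcc_correlations(small)


class TestPermutationP:
    def test_determinism_and_bounds(self):
        m = _null_matrix(seed=5, n_samples=30)
        est = sparcc_correlations(m)
        p1 = permutation_pvalues(m, est, n_permutations=49, seed=7)
        p2 = permutation_pvalues(m, est, n_permutations=49, seed=7)
        pd.testing.assert_frame_equal(p1, p2)
        iu = np.triu_indices(10, 1)
        vals = p1.to_numpy()[iu]
        assert (vals >= 1 / 50).all() and (vals <= 1.0).all()

    def test_minimum_permutations_enforced(self):
        m = _null_matrix()
        est = sparcc_correlations(m)
        with pytest.raises(ValueError, match="19"):
            permutation_pvalues(m, est, n_permutations=10)

    def test_null_pvalues_roughly_uniform(self):
        m = _null_matrix(seed=8, n_taxa=10, n_samples=60)
        est = sparcc_correlations(m)
        p = permutation_pvalues(m, est, n_permutations=99, seed=2)
        vals = p.to_numpy()[np.triu_indices(10, 1)]
        ks = sps.kstest(vals, "uniform")
        assert ks.pvalue > 0.01


class TestBhFdr:
    def _frame(self, pvals):
        n = len(pvals)
        # embed the upper triangle of a (k x k) matrix
        k = int((1 + np.sqrt(1 + 8 * n)) / 2)
        mat = np.full((k, k), np.nan)
        mat[np.triu_indices(k, 1)] = pvals
        mat[np.tril_indices(k, -1)] = mat.T[np.tril_indices(k, -1)]
        idx = pd.Index([f"t{i}" for i in range(k)])
        return pd.DataFrame(mat, index=idx, columns=idx)

    def test_step_up_arithmetic(self):
        q = bh_fdr(self._frame([0.01, 0.02, 0.03]))
        vals = q.to_numpy()[np.triu_indices(3, 1)]
        assert np.allclose(vals, [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        # single comparison: q = p
        mat = self._frame([0.2, 1.0, 1.0])
        q = bh_fdr(self._frame([0.2]))
        assert q.to_numpy()[0, 1] == pytest.approx(0.2)
        q1 = bh_fdr(self._frame([1.0, 1.0, 1.0]))
        assert (q1.to_numpy()[np.triu_indices(3, 1)] == 1.0).all()

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=10))
        q = bh_fdr(self._frame(p)).to_numpy()[np.triu_indices(5, 1)]
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(self._frame([1.5]))


def _manual_estimate(rho_pairs, q_pairs, taxa):
    k = len(taxa)
    rho = np.eye(k)
    q = np.full((k, k), np.nan)
    for (i, j), v in rho_pairs.items():
        rho[i, j] = rho[j, i] = v
    for (i, j), v in q_pairs.items():
        q[i, j] = q[j, i] = v
    idx = pd.Index(taxa)
    est = CorrelationEstimate(rho=pd.DataFrame(rho, index=idx, columns=idx))
    est.q = pd.DataFrame(q, index=idx, columns=idx)
    return est


class TestBuildNetwork:
    taxa = ["a", "b", "c", "d"]

    def test_threshold_cases(self):
        est = _manual_estimate({(0, 1): 0.7}, {(0, 1): 0.001, (0, 2): 1, (0, 3): 1,
                                               (1, 2): 1, (1, 3): 1, (2, 3): 1},
                               self.taxa)
        assert build_network(est).number_of_edges() == 1

        est2 = _manual_estimate({(0, 1): 0.7}, {(0, 1): 0.05, (0, 2): 1, (0, 3): 1,
                                                (1, 2): 1, (1, 3): 1, (2, 3): 1},
                                self.taxa)
        assert build_network(est2).number_of_edges() == 0

        est3 = _manual_estimate({(0, 1): -0.65}, {(0, 1): 0.001, (0, 2): 1, (0, 3): 1,
                                                  (1, 2): 1, (1, 3): 1, (2, 3): 1},
                                self.taxa)
        net = build_network(est3)
        assert net.number_of_edges() == 1
        assert net.edges["a", "b"]["sign"] == "negative"

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(4)
        rho_pairs, q_pairs = {}, {}
        for i, j in itertools.combinations(range(4), 2):
            rho_pairs[(i, j)] = rng.uniform(-1, 1)
            q_pairs[(i, j)] = rng.uniform(0, 0.2)
        est = _manual_estimate(rho_pairs, q_pairs, self.taxa)
        base = build_network(est, rho_min=0.3, q_max=0.1).number_of_edges()
        stricter_rho = build_network(est, rho_min=0.6, q_max=0.1).number_of_edges()
        stricter_q = build_network(est, rho_min=0.3, q_max=0.05).number_of_edges()
        assert stricter_rho <= base and stricter_q <= base

    def test_isolate_policy(self):
        est = _manual_estimate({(0, 1): 0.9}, {(0, 1): 0.001, (0, 2): 1, (0, 3): 1,
                                               (1, 2): 1, (1, 3): 1, (2, 3): 1},
                               self.taxa)
        assert build_network(est).number_of_nodes() == 2
        assert build_network(est, keep_isolates=True).number_of_nodes() == 4

    def test_missing_q_rejected(self):
        est = CorrelationEstimate(
            rho=pd.DataFrame(np.eye(4), index=self.taxa, columns=self.taxa)
        )
        with pytest.raises(ValueError, match="q-values"):
            build_network(est)


def _brute_force_transitivity(g):
    nodes = list(g.nodes)
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        edges = [g.has_edge(a, b), g.has_edge(a, c), g.has_edge(b, c)]
        if all(edges):
            triangles += 1
            triples += 3
        elif sum(edges) == 2:
            triples += 1
    return 3 * triangles / triples if triples else 0.0


def _brute_force_modularity(g):
    """Exhaustive maximum modularity over all partitions (small graphs)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
            yield [[head]] + part

    return max(
        nx.community.modularity(g, [set(b) for b in part])
        for part in partitions(nodes)
    )


class TestTopology:
    def test_triangle(self):
        t = topology(nx.complete_graph(3))
        assert (t.n_nodes, t.n_edges, t.average_degree, t.transitivity) == (3, 3, 2.0, 1.0)

    def test_path_has_zero_transitivity(self):
        assert topology(nx.path_graph(3)).transitivity == 0.0

    def test_two_disjoint_triangles_modularity_half(self):
        g = nx.union(nx.complete_graph(3), nx.complete_graph(3), rename=("a", "b"))
        t = topology(g)
        assert t.modularity == pytest.approx(0.5)
        assert t.modularity == pytest.approx(_brute_force_modularity(g))

    def test_random_suite_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8),
                                    seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            t = topology(g)
            assert t.average_degree == pytest.approx(2 * g.number_of_edges() / n)
            assert t.transitivity == pytest.approx(_brute_force_transitivity(g))
            assert t.density == pytest.approx(
                g.number_of_edges() / (n * (n - 1) / 2)
            )
            assert -0.5 <= t.modularity <= 1.0

    def test_empty_network_flagged(self):
        t = topology(nx.Graph())
        assert t.empty and t.n_nodes == 0


def test_aggregate_taxa_by_lineage():
    counts = pd.DataFrame(
        {"s1": [10, 20, 5, 1], "s2": [1, 2, 3, 4]},
        index=pd.Index(["a1", "a2", "b1", "u1"], name="taxon_id"),
    )
    lineages = pd.Series(
        ["k__X;p__Alpha", "k__X;p__Alpha", "k__X;p__Beta", "k__X;"],
        index=counts.index,
    )
    m = CountMatrix(counts=counts,
                    sample_treatments=pd.Series({"s1": "A", "s2": "A"}),
                    lineages=lineages)
    agg = aggregate_taxa(m, level=1)
    assert set(agg.counts.index) == {"p__Alpha", "p__Beta", "unclassified"}
    assert agg.counts.loc["p__Alpha", "s1"] == 30
    top1 = aggregate_taxa(m, level=1, top=1)
    assert list(top1.counts.index) == ["p__Alpha"]
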