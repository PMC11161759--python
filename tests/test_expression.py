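"""StatTools: TPM, profiles, correlation mining, clustering, ddCt."""

import math

import numpy as np
import pytest

from vinekit.io_formats import CountsTable, SampleMetadata
from vinekit.expression import (NormalizedMatrix, QPCRRecord, cluster_heatmap,
                                correlation_circle_layout,
                                correlation_gene_finder, correlation_network,
                                ddct_relative_expression, expression_profile,
                                log_transform, normalize_tpm, pearson)
from vinekit.simulate import SimulationConfig, simulate_expression


def table(rows, lengths, genes=None, samples=None):
    rows = np.array(rows, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return CountsTable(genes, samples, rows, np.array(lengths, dtype=np.int64))


class TestNormalization:
    def test_equal_length_normalized_rates_split_the_million(self):
        m = normalize_tpm(table([[10], [20]], [1000, 2000]))
        assert np.allclose(m.values[:, 0], [500_000, 500_000])

    def test_single_gene_gets_the_whole_million(self):
        m = normalize_tpm(table([[7]], [123]))
        assert m.values[0, 0] == pytest.approx(1e6)

    def test_scale_invariance_within_a_sample(self):
        t1 = table([[10, 5], [3, 8]], [500, 900])
        t2 = table([[20, 5], [6, 8]], [500, 900])
        m1, m2 = normalize_tpm(t1), normalize_tpm(t2)
        assert np.allclose(m1.values[:, 0], m2.values[:, 0])

    def test_all_zero_sample_errors_with_its_name(self):
        with pytest.raises(ValueError, match="s1"):
            normalize_tpm(table([[1, 0], [2, 0]], [100, 100]))

    def test_columns_sum_to_one_million(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=(30, 8))
            counts[:, 0] = np.maximum(counts[:, 0], 1)
            counts[rng.random(size=counts.shape) < 0.6] = 0
            counts[0, :] = np.maximum(counts[0, :], 1)  # keep columns nonzero
            t = table(counts, rng.integers(200, 5000, size=30))
            m = normalize_tpm(t)
            assert np.allclose(m.values.sum(axis=0), 1e6, rtol=1e-6)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [
        (0.0, 0.0), (1.0, 1.0), (1023.0, 10.0), (3.0, 2.0),
    ])
    def test_log2_plus_one(self, value, expected):
        m = NormalizedMatrix(["g"], ["s"], np.array([[value]]))
        assert log_transform(m).values[0, 0] == pytest.approx(expected)

    def test_double_transform_refused(self):
        m = NormalizedMatrix(["g"], ["s"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="already"):
            log_transform(log_transform(m))


class TestProfile:
    def _setup(self):
        m = NormalizedMatrix(["g1"], ["s1", "s2", "s3"],
                             np.array([[2.0, 4.0, 9.0]]))
        meta = [SampleMetadata("s1", organ="berry"),
                SampleMetadata("s2", organ="berry"),
                SampleMetadata("s3", organ="leaf")]
        return m, meta

    def test_group_mean_and_sample_sd(self):
        m, meta = self._setup()
        p = expression_profile(m, meta, "g1", "organ")
        assert p.conditions == ["berry", "leaf"]
        assert p.mean == [pytest.approx(3.0), pytest.approx(9.0)]
        assert p.sd[0] == pytest.approx(math.sqrt(2.0))  # ddof=1
        assert p.sd[1] == 0.0  # single-sample group
        assert p.n == [2, 1]

    def test_unknown_gene_errors(self):
        m, meta = self._setup()
        with pytest.raises(KeyError):
            expression_profile(m, meta, "nope", "organ")


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_product_moment_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r)
        assert pearson(3.0 * x + 7.0, y) == pytest.approx(r)


class TestFinder:
    def _matrix(self, rng, n_noise=50, n=30):
        target = rng.uniform(1.0, 9.0, size=n)
        vals = np.vstack([target, target * 2.0 + 5.0,
                          rng.uniform(0.0, 10.0, size=(n_noise, n))])
        genes = ["target", "copy"] + [f"n{i}" for i in range(n_noise)]
        return NormalizedMatrix(genes, [f"s{j}" for j in range(n)], vals)

    def test_exact_copy_ranks_first_with_r_one(self, rng):
        m = self._matrix(rng)
        res = correlation_gene_finder(m, "target", threshold=0.9)
        assert res[0].gene_id == "copy"
        assert res[0].r == pytest.approx(1.0)

    def test_threshold_monotonicity(self, rng):
        m = self._matrix(rng)
        lo = {r.gene_id for r in correlation_gene_finder(m, "target", 0.3)}
        hi = {r.gene_id for r in correlation_gene_finder(m, "target", 0.6)}
        assert hi <= lo

    def test_bad_threshold_rejected(self, rng):
        m = self._matrix(rng)
        with pytest.raises(ValueError, match="threshold"):
            correlation_gene_finder(m, "target", threshold=1.5)

    def test_planted_module_recovered_on_study_fixture(self):
        sim = simulate_expression(SimulationConfig(seed=0))
        m = log_transform(normalize_tpm(sim.counts))
        hits = {r.gene_id for r in
                correlation_gene_finder(m, sim.regulator, threshold=0.75)}
        module = set(sim.module_genes)
        assert module <= hits
        assert len(hits - module) <= 1
        top10 = {r.gene_id for r in correlation_gene_finder(
            m, sim.regulator, mode="topk", top_k=10)}
        assert module <= top10


class TestCircleLayout:
    def test_radius_is_one_minus_r(self):
        from vinekit.expression import CorrelationResult
        res = [CorrelationResult("a", 1.0, 10),
               CorrelationResult("b", 0.0, 10),
               CorrelationResult("c", -1.0, 10)]
        layout = dict((g, r) for g, r, _ in correlation_circle_layout(res, "t"))
        assert layout == {"t": 0.0, "a": 0.0, "b": 1.0, "c": 2.0}


class TestClustering:
    def test_duplicate_rows_merge_first_at_distance_zero(self, rng):
        vals = rng.normal(size=(4, 6))
        vals[1] = vals[0]
        m = NormalizedMatrix([f"g{i}" for i in range(4)],
                             [f"s{j}" for j in range(6)], np.abs(vals))
        out = cluster_heatmap(m, distance="euclidean")
        z = out["gene_linkage"]
        assert z[0, 2] == pytest.approx(0.0)
        assert sorted(z[0, :2]) == [0, 1]

    def test_disjoint_expression_blocks_separate_samples(self):
        vals = np.zeros((4, 6))
        vals[:2, :3] = 50.0
        vals[2:, 3:] = 50.0
        vals += np.arange(6) * 0.01  # break exact ties deterministically
        m = NormalizedMatrix([f"g{i}" for i in range(4)],
                             [f"s{j}" for j in range(6)], vals)
        out = cluster_heatmap(m, distance="euclidean")
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(out["sample_linkage"], t=2, criterion="maxclust")
        assert len({tuple(labels[:3]), tuple(labels[3:])}) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_zero_variance_row_under_pearson_names_gene(self):
        m = NormalizedMatrix(["flat", "ok"], ["s0", "s1", "s2"],
                             np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="flat"):
            cluster_heatmap(m, distance="pearson")


class TestNetwork:
    def _matrix(self, rng):
        base = rng.normal(size=24)
        rows = [base + rng.normal(scale=0.3, size=24) for _ in range(5)]
        rows += [rng.normal(size=24) for _ in range(20)]
        genes = [f"m{i}" for i in range(5)] + [f"n{i}" for i in range(20)]
        return NormalizedMatrix(genes, [f"s{j}" for j in range(24)],
                                np.abs(np.vstack(rows)))

    def test_beta_one_reduces_to_absolute_correlation(self, rng):
        m = self._matrix(rng)
        net = correlation_network(m, ["m0"], beta=1.0, min_weight=0.5)
        vals = m.values
        for a, b, w in net.edges:
            r = np.corrcoef(vals[m.gene_ids.index(a)],
                            vals[m.gene_ids.index(b)])[0, 1]
            assert w == pytest.approx(abs(r))

    def test_soft_threshold_power(self):
        assert 0.5 ** 6 == pytest.approx(0.015625)

    def test_raising_beta_never_raises_weights(self, rng):
        m = self._matrix(rng)
        w1 = {(a, b): w for a, b, w in
              correlation_network(m, ["m0"], beta=2.0, min_weight=0.1).edges}
        w2 = {(a, b): w for a, b, w in
              correlation_network(m, ["m0"], beta=6.0, min_weight=0.1).edges}
        for edge, w in w2.items():
            assert w <= w1[edge] + 1e-12

    def test_planted_module_forms_connected_component_with_seed(self):
        sim = simulate_expression(SimulationConfig(seed=0))
        m = log_transform(normalize_tpm(sim.counts))
        net = correlation_network(m, [sim.regulator], beta=6.0, min_weight=0.3)
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from((a, b) for a, b, _ in net.edges)
        comp = nx.node_connected_component(g, sim.regulator)
        assert set(sim.module_genes) <= comp


class TestDdct:
    def test_worked_delta_ct_case(self):
        t = QPCRRecord("g", "red", [18.0], {"ACT": [15.0]})
        c = QPCRRecord("g", "white", [20.0], {"ACT": [15.0]})
        assert ddct_relative_expression(t, c) == pytest.approx(4.0)

    def test_delta_cts_three_vs_five(self):
        t = QPCRRecord("g", "a", [23.0], {"ACT": [20.0]})   # dCt = 3
        c = QPCRRecord("g", "b", [25.0], {"ACT": [20.0]})   # dCt = 5
        assert ddct_relative_expression(t, c) == pytest.approx(4.0)

    def test_calibrator_against_itself_is_one(self):
        c = QPCRRecord("g", "x", [19.5, 20.5],
                       {"ACT": [15.0], "EF1": [16.0], "UBQ": [14.0]})
        assert ddct_relative_expression(c, c) == pytest.approx(1.0)

    def test_reference_genes_averaged_per_gene_then_across(self):
        t = QPCRRecord("g", "a", [20.0], {"ACT": [14.0, 16.0], "EF1": [17.0]})
        # dCt = 20 - mean(15, 17) = 4
        assert t.delta_ct() == pytest.approx(4.0)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            QPCRRecord("g", "a", [], {"ACT": [15.0]})
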