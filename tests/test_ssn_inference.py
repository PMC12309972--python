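"""Network-inference tests with independent brute-force oracles."""

import math

import numpy as np
import pytest

from ssnetkit.io_formats import ExpressionMatrix
from ssnetkit.sweet import (
    SampleNetwork,
    SweetParams,
    compute_pcc_matrix,
    compute_sample_weight,
    degree_distribution_r2,
    infer_sample_network,
    interpolate,
    network_density,
    sample_pcc_matrix,
    scale_free_r2,
    zscore_threshold,
)
from ssnetkit.synthetic import SyntheticConfig, generate_cohort, subsample_cohort


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Direct evaluation of the Pearson formula."""
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


class TestPccMatrix:
    def test_identical_and_negated_vectors(self, toy_expr):
        corr = compute_pcc_matrix(toy_expr)
        assert corr.weights[0, 1] == pytest.approx(1.0)
        assert corr.weights[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((6, 4))
        em = ExpressionMatrix([f"G{i}" for i in range(6)], list("ABCD"), vals)
        corr = compute_pcc_matrix(em)
        for i in range(6):
            for j in range(6):
                assert corr.weights[i, j] == pytest.approx(
                    pearson_oracle(vals[i], vals[j]), abs=1e-12
                )

    def test_too_few_samples_rejected(self, toy_expr):
        with pytest.raises(ValueError, match=">=3"):
            compute_pcc_matrix(toy_expr, ["S1", "S2"])

    def test_zero_variance_gene_named(self):
        em = ExpressionMatrix(
            ["GA", "GB"], ["S1", "S2", "S3"], np.array([[1.0, 1.0, 1.0], [1, 2, 3]])
        )
        with pytest.raises(ValueError, match="GA"):
            compute_pcc_matrix(em)


class TestSampleWeight:
    def test_all_equal_pccs_give_unit_weight(self):
        # identical samples: every pairwise PCC equal, so mu = min = max and W = x/x
        rng = np.random.default_rng(0)
        base = rng.standard_normal(30)
        vals = np.stack([base, base, base], axis=1)
        em = ExpressionMatrix([f"G{i}" for i in range(30)], ["A", "B", "C"], vals)
        sw = compute_sample_weight(em, "A")
        assert sw.w == pytest.approx(1.0)

    def test_mu_equal_max_gives_one(self):
        # W = (mu - min + x)/(max - min + x) = 1 when mu = max
        params = SweetParams()
        w = (0.8 - 0.2 + params.x) / (0.8 - 0.2 + params.x)
        assert w == 1.0

    def test_direct_arithmetic(self):
        # mu = min = 0.2, max = 0.8, x = 0.01 -> 0.01/0.61
        assert (0.2 - 0.2 + 0.01) / (0.8 - 0.2 + 0.01) == pytest.approx(
            0.016393, abs=1e-6
        )

    def test_weight_positive_for_cohort(self, random_expr):
        for s in random_expr.sample_ids:
            assert compute_sample_weight(random_expr, s).w > 0


class TestInterpolation:
    def test_fixed_point_when_networks_agree(self):
        v = interpolate(np.array([[0.0, 0.3], [0.3, 0.0]]),
                        np.array([[0.0, 0.3], [0.3, 0.0]]), w=0.7, num=10, k=0.1)
        assert v[0, 1] == pytest.approx(0.3)

    def test_unit_gain_recovers_aggregate(self):
        # W * num * K = 1: N(S) = N(G)
        assert interpolate(np.array(0.6), np.array(0.4), w=1.0, num=10, k=0.1) == pytest.approx(0.6)

    def test_direct_arithmetic(self):
        assert interpolate(np.array(0.6), np.array(0.4), w=0.5, num=10, k=0.1) == pytest.approx(0.5)

    def test_k_to_zero_recovers_leave_one_out(self, random_expr):
        agg = compute_pcc_matrix(random_expr)
        loo = compute_pcc_matrix(random_expr, random_expr.sample_ids[1:])
        sup = []
        for k in (0.1, 0.01, 0.001):
            ns = interpolate(agg.weights, loo.weights, w=0.6, num=9, k=k)
            sup.append(np.abs(ns - loo.weights).max())
        assert sup[0] > sup[1] > sup[2]
        assert sup[2] < sup[0] / 50  # sup-norm shrinks linearly with K


class TestZThreshold:
    def test_all_equal_weights_empty(self, caplog):
        raw = np.full((4, 4), 0.5)
        with caplog.at_level("WARNING"):
            edges = zscore_threshold(raw, list("ABCD"), SweetParams())
        assert edges == {}
        assert "degenerate" in caplog.text

    def test_normal_tail_fraction(self):
        # 10^4 upper-triangle weights ~ N(0,1): retained fraction ~ 2*(1-Phi(2.58))
        rng = np.random.default_rng(0)
        n = 142  # C(142,2) = 10011 pairs
        raw = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        raw[iu] = rng.standard_normal(iu[0].size)
        raw = raw + raw.T
        edges = zscore_threshold(raw, [f"G{i}" for i in range(n)], SweetParams())
        frac = len(edges) / iu[0].size
        p = 0.009892  # 2 * (1 - Phi(2.58))
        se = math.sqrt(p * (1 - p) / iu[0].size)
        assert abs(frac - p) < 3 * se

    def test_single_extreme_edge_survives(self):
        n = 20
        raw = np.zeros((n, n))
        raw[0, 1] = raw[1, 0] = 100.0
        edges = zscore_threshold(raw, [f"G{i:02d}" for i in range(n)], SweetParams())
        # brute-force z: only the extreme entry exceeds 2.58 sd of the triangle
        assert set(edges) == {("G00", "G01")}

    def test_strict_inequality_at_threshold(self):
        # an entry landing exactly at |z| = threshold is excluded
        raw = np.zeros((3, 3))
        raw[0, 1] = raw[1, 0] = 1.0
        raw[0, 2] = raw[2, 0] = -1.0
        raw[1, 2] = raw[2, 1] = 0.0
        tri = np.array([1.0, -1.0, 0.0])
        z_max = float(np.max(np.abs((tri - tri.mean()) / tri.std())))
        edges = zscore_threshold(raw, list("ABC"), SweetParams(z_threshold=z_max))
        assert edges == {}  # ties at the threshold are excluded
        edges = zscore_threshold(
            raw, list("ABC"), SweetParams(z_threshold=z_max * 0.999)
        )
        assert set(edges) == {("A", "B"), ("A", "C")}


class TestOracleEquivalence:
    def test_sweet_matches_brute_force(self, random_expr):
        """Full inference equals an independent entrywise recomputation.

        A 2.0 threshold is used because at 10 samples the per-sample z of a
        bounded correlation cannot reach 2.58, which would make the edge
        comparison vacuous.
        """
        params = SweetParams(z_threshold=2.0)
        target = random_expr.sample_ids[3]
        net = infer_sample_network(random_expr, target, params)

        # --- brute force, sharing no code path with the implementation ---
        vals = random_expr.values
        n_genes, n = vals.shape
        idx = random_expr.sample_ids.index(target)
        keep = [j for j in range(n) if j != idx]

        def corr(mat):
            out = np.empty((n_genes, n_genes))
            for i in range(n_genes):
                for j in range(n_genes):
                    out[i, j] = pearson_oracle(mat[i], mat[j])
            return out

        n_g = corr(vals)
        n_gs = corr(vals[:, keep])
        # sample weight from sample-sample correlations over genes
        spcc = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                spcc[i, j] = pearson_oracle(vals[:, i], vals[:, j])
        mu = np.mean([spcc[idx, j] for j in keep])
        pairs = [spcc[i, j] for i in range(n) for j in range(i + 1, n)]
        w = (mu - min(pairs) + params.x) / (max(pairs) - min(pairs) + params.x)
        raw = w * (n - 1) * params.k * (n_g - n_gs) + n_gs
        tri = [raw[i, j] for i in range(n_genes) for j in range(i + 1, n_genes)]
        mean, sd = np.mean(tri), np.std(tri)
        expected = {}
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                z = (raw[i, j] - mean) / sd
                if abs(z) > params.z_threshold:
                    a, b = sorted((random_expr.gene_ids[i], random_expr.gene_ids[j]))
                    expected[(a, b)] = (raw[i, j], z)

        assert set(net.edges) == set(expected)
        for e in expected:
            assert net.edges[e][0] == pytest.approx(expected[e][0], abs=1e-10)
            assert net.edges[e][1] == pytest.approx(expected[e][1], abs=1e-10)


class TestQC:
    def _net(self, edges, n_genes):
        return SampleNetwork("S", {e: (0.5, 3.0) for e in edges}, n_genes)

    def test_density_examples(self):
        genes = [f"G{i}" for i in range(5)]
        complete = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        assert network_density(self._net(complete, 5)) == pytest.approx(1.0)
        assert network_density(self._net([], 5)) == 0.0
        assert network_density(self._net(complete[:2], 5)) == pytest.approx(0.2)

    def test_scale_free_exact_power_law(self):
        # p(k) proportional to k^-2 over degrees {1, 2, 4}: exact log-log line
        degrees = np.array([1] * 16 + [2] * 4 + [4] * 1, dtype=float)
        assert degree_distribution_r2(degrees) == pytest.approx(1.0)

    def test_regular_graph_undefined(self):
        # triangle: all degrees equal -> single occupied bin
        net = self._net([("A", "B"), ("A", "C"), ("B", "C")], 3)
        assert scale_free_r2(net) is None

    def test_dense_erdos_renyi_not_power_law(self):
        rng = np.random.default_rng(0)
        n, p = 500, 0.1
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1)
        degrees = (adj + adj.T).sum(axis=1)
        r2 = degree_distribution_r2(degrees.astype(float))
        assert r2 is not None and r2 < 0.5


class TestCohortProperties:
    def test_leave_one_out_mean_approaches_aggregate(self):
        """Mean |avg(N^(G-S)) - N^G| shrinks as the cohort grows."""
        devs = []
        for n in (10, 20, 40):
            cfg = SyntheticConfig(
                n_samples=n, n_genes=60, n_blocks=1, block_size=12,
                planted_set_size=6, n_decoy_sets=2, seed=5,
            )
            expr = generate_cohort(cfg).expression
            agg = compute_pcc_matrix(expr).weights
            loos = []
            for s in expr.sample_ids:
                others = [x for x in expr.sample_ids if x != s]
                loos.append(compute_pcc_matrix(expr, others).weights)
            mean_loo = np.mean(loos, axis=0)
            iu = np.triu_indices(expr.n_genes, 1)
            devs.append(np.abs(mean_loo - agg)[iu].mean())
        assert devs[0] > devs[1] > devs[2]

    def test_scale_free_r2_degrades_with_smaller_cohorts(self):
        """Mean scale-free R^2 is non-increasing as cohort size shrinks
        (at most one inversion across the size ladder)."""
        sizes = [120, 80, 40]
        means = []
        for size in sizes:
            r2s = []
            for seed in range(10):
                cfg = SyntheticConfig(
                    n_samples=120, n_genes=150, n_blocks=1, block_size=30,
                    planted_set_size=10, n_decoy_sets=2, seed=100 + seed,
                )
                cohort = generate_cohort(cfg)
                sub = subsample_cohort(cohort, size, seed=seed)
                expr = sub.expression
                agg = compute_pcc_matrix(expr)
                spcc = sample_pcc_matrix(expr)
                for s in expr.sample_ids[:4]:
                    net = infer_sample_network(expr, s, _agg=agg, _sample_pcc=spcc)
                    r2 = scale_free_r2(net)
                    if r2 is not None:
                        r2s.append(r2)
            means.append(np.mean(r2s))
        inversions = sum(means[i + 1] > means[i] for i in range(len(means) - 1))
        assert inversions <= 1
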