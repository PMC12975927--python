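"""Partial-correlation estimation, p-values and edge sparsification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stratnet as sn
from stratnet.pcorr import EstimationError, PartialCorrelationResult
from stratnet.schema import VariableDef, VariableSchema


def residual_pcorr_oracle(x: np.ndarray) -> np.ndarray:
    """Independent oracle: partial correlation of each pair as the Pearson
    correlation of the residuals from regressing both on all others."""
    n, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            z = np.column_stack([np.ones(n), x[:, others]])
            ri = x[:, i] - z @ np.linalg.lstsq(z, x[:, i], rcond=None)[0]
            rj = x[:, j] - z @ np.linalg.lstsq(z, x[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def _continuous_schema(p):
    return VariableSchema(
        tuple(
            VariableDef(f"x{i}", f"x{i}", "psychopathology", "continuous")
            for i in range(p)
        )
    )


def _cohort(values):
    schema = _continuous_schema(values.shape[1])
    return sn.CohortTable(values, np.ones(len(values), int), schema)


class TestPartialCorrelations:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((60, 17)) @ rng.standard_normal((17, 17))
        pc = sn.partial_correlations(_cohort(x))
        oracle = residual_pcorr_oracle(x)
        np.testing.assert_allclose(pc.r, oracle, atol=1e-10)

    def test_two_variables_reduce_to_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 2))
        pc = sn.partial_correlations(_cohort(x))
        assert pc.k == 0
        assert pc.r[0, 1] == pytest.approx(np.corrcoef(x.T)[0, 1], abs=1e-12)

    def test_three_equicorrelated_variables(self):
        # population pairwise r = 0.5 -> r_12|3 = (0.5 - 0.25)/(1 - 0.25) = 1/3
        rng = np.random.default_rng(11)
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        pc = sn.partial_correlations(_cohort(x))
        assert pc.r[0, 1] == pytest.approx(1 / 3, abs=0.01)

    def test_df_convention(self):
        rng = np.random.default_rng(5)
        pc = sn.partial_correlations(_cohort(rng.standard_normal((78, 17))))
        assert pc.k == 15 and pc.df == 61

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        pc = sn.partial_correlations(_cohort(rng.standard_normal((40, 8))))
        np.testing.assert_array_equal(pc.r, pc.r.T)
        np.testing.assert_array_equal(pc.p, pc.p.T)
        assert np.all(np.abs(pc.r) <= 1) and np.all((pc.p >= 0) & (pc.p <= 1))
        np.testing.assert_array_equal(np.diag(pc.r), 1.0)

    def test_constant_column_named(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 5))
        x[:, 2] = 3.0
        with pytest.raises(EstimationError, match="x2"):
            sn.partial_correlations(_cohort(x))

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 5))
        x[:, 4] = x[:, 0] + x[:, 1]
        with pytest.raises(EstimationError, match="singular"):
            sn.partial_correlations(_cohort(x))

    def test_sample_too_small(self):
        rng = np.random.default_rng(2)
        with pytest.raises(EstimationError, match="df"):
            sn.partial_correlations(_cohort(rng.standard_normal((19, 17))))

    def test_null_p_values_uniform(self):
        # pooled off-diagonal p-values under independence: KS distance < 0.05
        rng = np.random.default_rng(2024)
        pooled = []
        while len(pooled) < 10_000:
            x = rng.standard_normal((131, 17))
            pc = sn.partial_correlations(_cohort(x))
            iu = np.triu_indices(17, 1)
            pooled.extend(pc.p[iu])
        pooled = np.sort(np.asarray(pooled[:10_000]))
        grid = (np.arange(1, len(pooled) + 1)) / len(pooled)
        ks = np.max(np.abs(pooled - grid))
        assert ks < 0.05


class TestEdgeThreshold:
    def test_study_stratum_size(self):
        # n=78 with 15 controls: two-sided p = 0.25 at |r| ~ 0.147
        assert sn.edge_p_threshold(78, 15, 0.25) == pytest.approx(0.147, abs=5e-4)

    def test_liberal_limit_goes_to_zero(self):
        assert sn.edge_p_threshold(78, 15, 0.999) < 1e-3

    def test_monotone_in_alpha(self):
        assert sn.edge_p_threshold(78, 15, 0.05) > sn.edge_p_threshold(78, 15, 0.25)

    def test_threshold_consistent_with_p_values(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((78, 17))
        pc = sn.partial_correlations(_cohort(x))
        thr = sn.edge_p_threshold(78, 15, 0.25)
        iu = np.triu_indices(17, 1)
        retained = pc.p[iu] < 0.25
        assert np.array_equal(retained, np.abs(pc.r[iu]) > thr)


class TestSparsify:
    def _pc(self, r, p, n=78):
        r = np.asarray(r, float)
        return PartialCorrelationResult(r=r, p=np.asarray(p, float),
                                        n=n, k=r.shape[0] - 2)

    def test_all_null_keeps_nodes_no_edges(self):
        p = np.ones((17, 17))
        g = sn.sparsify(self._pc(np.eye(17), p))
        assert g.n_nodes == 17 and g.n_edges == 0

    def test_all_significant_gives_complete_graph(self):
        r = np.full((17, 17), 0.5)
        np.fill_diagonal(r, 1.0)
        p = np.zeros((17, 17))
        g = sn.sparsify(self._pc(r, p))
        assert g.n_edges == 136  # the complete-graph count for 17 nodes

    def test_boundary_p_excluded(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.3
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 0.25
        g = sn.sparsify(self._pc(r, p))
        assert g.n_edges == 0

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((40, 6))
        pc = sn.partial_correlations(_cohort(x))
        a1, a2 = sorted(rng.uniform(0.05, 0.95, size=2))
        g1, g2 = sn.sparsify(pc, a1), sn.sparsify(pc, a2)
        assert set(g1.edges) <= set(g2.edges)

    def test_idempotent_via_estimate(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((60, 17))
        c = _cohort(x)
        g1 = sn.estimate_stratum_network(c)
        g2 = sn.estimate_stratum_network(c)
        assert g1.edges == g2.edges

    def test_duplicated_rows_same_support(self):
        # exact row duplication changes df but the r-ranking of pairs not
        rng = np.random.default_rng(12)
        x = rng.standard_normal((60, 17))
        pc1 = sn.partial_correlations(_cohort(x))
        pc2 = sn.partial_correlations(_cohort(np.vstack([x, x])))
        np.testing.assert_allclose(pc1.r, pc2.r, atol=1e-10)
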