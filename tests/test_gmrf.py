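"""Field construction: precisions, covariances, scaling, exact sampling."""

import numpy as np
import pytest
import scipy.linalg as sla

from carfield import gmrf
from carfield.gmrf import CARSpec, covariance, precision, sample_field, scaling, valid_range
from carfield.lattice import build_grid, structure_matrix


class TestCARSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="nosuch", sigma=1.0),
            dict(model="lcar", sigma=1.0),  # missing c
            dict(model="lcar", c=1.5, sigma=1.0),
            dict(model="icar", c=0.5, sigma=1.0),  # icar takes no c
            dict(model="pcar", c=0.5),  # missing sigma
            dict(model="bym", sigma=1.0),  # bym needs component scales
            dict(model="bym", sigma_s=0.3, sigma_h=-0.1),
            dict(model="mbym", c=0.5, sigma=1.0, sigma_s=0.2),
            dict(model="adaptive_mbym", c=0.5, sigma=1.0),  # needs vector
        ],
    )
    def test_rejects_inconsistent_parameterizations(self, kwargs):
        with pytest.raises(ValueError):
            CARSpec(**kwargs)

    def test_adaptive_entries_must_be_interior(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            CARSpec(model="adaptive_mbym", c=np.array([0.5, 1.0]), sigma=1.0)


class TestPrecision:
    def test_lcar_c_zero_is_iid(self, grid33):
        law = precision(grid33, CARSpec(model="lcar", c=0.0, sigma=1.0))
        assert np.allclose(law.Omega, np.eye(9))

    def test_pcar_c_zero_is_degree_diagonal(self, grid33):
        law = precision(grid33, CARSpec(model="pcar", c=0.0, sigma=1.0))
        assert np.allclose(law.Omega, np.diag(grid33.wplus))

    def test_pcar_two_node_covariance(self, path2):
        # direct 2x2 inversion of Q(0.5)
        law = covariance(path2, CARSpec(model="pcar", c=0.5, sigma=1.0))
        assert np.allclose(law.Sigma, 4.0 / 3.0 * np.array([[1, 0.5], [0.5, 1]]))

    def test_icar_rank_and_constraint(self, grid33):
        law = precision(grid33, CARSpec(model="icar", sigma=0.7))
        assert law.rank == 8 and law.constraint == "sum_to_zero"
        assert np.linalg.matrix_rank(law.Omega) == 8

    def test_dependence_matrix_matches_conditional_means(self, grid33):
        """B_ik = c/w_i+ for pCAR and c/(1-c+c w_i+) for LCAR."""
        c = 0.7
        W = grid33.W.toarray()
        law = precision(grid33, CARSpec(model="pcar", c=c, sigma=0.5))
        expected = c / grid33.wplus[:, None] * W
        assert np.allclose(law.B, expected)
        law = precision(grid33, CARSpec(model="lcar", c=c, sigma=0.5))
        wc = 1 - c + c * grid33.wplus
        assert np.allclose(law.B, c / wc[:, None] * W)

    def test_pcar_out_of_range_rejected(self, path2):
        with pytest.raises(ValueError, match="validity range"):
            precision(path2, CARSpec(model="pcar", c=-2.0, sigma=1.0))

    def test_icar_island_rejected(self):
        from carfield.lattice import _graph_from_edges

        g = _graph_from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="island"):
            precision(g, CARSpec(model="icar", sigma=1.0))


class TestCovariance:
    def test_icar_two_node_pseudo_inverse(self, path2):
        law = covariance(path2, CARSpec(model="icar", sigma=1.0))
        assert np.allclose(law.Sigma, [[0.25, -0.25], [-0.25, 0.25]])

    def test_mbym_c_zero_is_iid(self, grid33):
        law = covariance(grid33, CARSpec(model="mbym", c=0.0, sigma=0.8))
        assert np.allclose(law.Sigma, 0.64 * np.eye(9))

    @pytest.mark.parametrize("c,s", [(0.3, 0.5), (0.7, 1.2), (0.95, 0.2)])
    def test_bym_reparameterization_equals_mbym(self, grid33, c, s):
        """BYM(sigma*sqrt(c), sigma*sqrt(1-c)) has the MBYM(c, sigma) covariance."""
        bym = covariance(
            grid33,
            CARSpec(model="bym", sigma_s=s * np.sqrt(c), sigma_h=s * np.sqrt(1 - c)),
        )
        mbym = covariance(grid33, CARSpec(model="mbym", c=c, sigma=s))
        assert np.max(np.abs(bym.Sigma - mbym.Sigma)) < 1e-10

    def test_adaptive_reduces_to_mbym_for_constant_weights(self, grid33):
        c = 0.6
        ada = covariance(
            grid33, CARSpec(model="adaptive_mbym", c=np.full(9, c), sigma=0.5)
        )
        non = covariance(grid33, CARSpec(model="mbym", c=c, sigma=0.5))
        assert np.allclose(ada.Sigma, non.Sigma)

    def test_scaled_mbym_block_uses_reference_sd(self, grid33):
        c, s = 0.6, 0.4
        info = scaling(grid33)
        expected = s**2 * (
            c * info.Sigma_star / info.s**2 + (1 - c) * np.eye(9)
        )
        law = covariance(grid33, CARSpec(model="scaled_mbym", c=c, sigma=s))
        assert np.allclose(law.Sigma, expected)

    def test_dense_cap_enforced(self, monkeypatch, grid33):
        monkeypatch.setattr(gmrf, "DENSE_CAP", 5)
        with pytest.raises(ValueError, match="cap"):
            covariance(grid33, CARSpec(model="icar", sigma=1.0))


class TestValidRange:
    def test_two_node(self, path2):
        r = valid_range(path2)
        assert np.allclose([r.cmin, r.cmax], [-1.0, 1.0])

    def test_triangle(self, triangle):
        """Adjacency eigenvalues {2, -1, -1} scaled by the degree 2."""
        r = valid_range(triangle)
        assert np.allclose([r.cmin, r.cmax], [-2.0, 1.0])

    @pytest.mark.parametrize("dims", [(2, 3), (4, 4), (1, 7)])
    def test_connected_graphs_have_cmax_one(self, dims):
        r = valid_range(build_grid(*dims, "rook"))
        assert r.cmax == pytest.approx(1.0) and r.cmin < 0


class TestScaling:
    def test_two_node_closed_form(self, path2):
        info = scaling(path2, tau=1.0)
        assert info.s == pytest.approx(0.5)
        assert np.allclose(np.diag(info.Sigma_star), [0.25, 0.25])

    @pytest.mark.parametrize("tau", [1.0, 4.0])
    def test_geometric_mean_identity(self, grid33, tau):
        """geometric mean of diag(Sigma_scaled) = 1/tau; oracle recomputes
        Sigma* by an independent dense pseudo-inverse."""
        info = scaling(grid33, tau=tau)
        gm = np.exp(np.mean(np.log(np.diag(info.Sigma_scaled))))
        assert gm == pytest.approx(1.0 / tau, abs=1e-8)
        oracle = sla.pinvh(structure_matrix(grid33, 1.0).toarray())
        assert np.allclose(info.Sigma_star, oracle, atol=1e-9)

    def test_disconnected_rejected(self):
        from carfield.lattice import _graph_from_edges

        g = _graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            scaling(g)


class TestSampleField:
    def test_icar_draws_sum_to_zero(self, grid33):
        d = sample_field(grid33, CARSpec(model="icar", sigma=1.3), 50, seed=0)
        assert np.max(np.abs(d.sum(axis=1))) < 1e-10

    def test_seeded_determinism(self, grid44):
        spec = CARSpec(model="mbym", c=0.4, sigma=0.6)
        a = sample_field(grid44, spec, 10, seed=123)
        b = sample_field(grid44, spec, 10, seed=123)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "spec",
        [
            CARSpec(model="lcar", c=0.8, sigma=1.0),
            CARSpec(model="pcar", c=0.9, sigma=0.7),
            CARSpec(model="icar", sigma=0.8),
            CARSpec(model="bym", sigma_s=0.5, sigma_h=0.4),
            CARSpec(model="scaled_mbym", c=0.6, sigma=0.9),
        ],
        ids=lambda s: s.model,
    )
    def test_empirical_covariance_matches_analytic(self, grid33, spec):
        d = sample_field(grid33, spec, 200_000, seed=7)
        emp = np.cov(d.T)
        ana = covariance(grid33, spec).Sigma
        assert np.max(np.abs(emp - ana)) < 0.02


class TestLimitsAndInverses:
    @pytest.mark.parametrize("model", ["pcar", "lcar"])
    def test_c_to_one_limit_is_icar(self, grid33, model):
        """Both proper CARs converge to the intrinsic precision as c -> 1."""
        near = precision(grid33, CARSpec(model=model, c=1 - 1e-8, sigma=0.5))
        icar = precision(grid33, CARSpec(model="icar", sigma=0.5))
        assert np.max(np.abs(near.Omega - icar.Omega)) < 1e-6

    @pytest.mark.parametrize(
        "graph_dims,spec",
        [
            ((5, 5), CARSpec(model="pcar", c=0.6, sigma=0.8)),
            ((5, 5), CARSpec(model="lcar", c=0.3, sigma=1.2)),
            ((7, 7), CARSpec(model="lcar", c=0.9, sigma=0.4)),
        ],
        ids=["pcar", "lcar", "lcar49"],
    )
    def test_precision_covariance_mutual_inverse(self, graph_dims, spec):
        g = build_grid(*graph_dims, "rook")
        Om = precision(g, spec).Omega
        Si = covariance(g, spec).Sigma
        assert np.allclose(Om @ Si, np.eye(g.n), atol=1e-8)

    def test_icar_pseudo_inverse_on_constrained_subspace(self, grid44):
        """Sigma Omega acts as identity on the sum-to-zero subspace."""
        spec = CARSpec(model="icar", sigma=0.9)
        Om = precision(grid44, spec).Omega
        Si = covariance(grid44, spec).Sigma
        n = grid44.n
        P = np.eye(n) - np.ones((n, n)) / n  # centering projector
        assert np.allclose(Si @ Om, P, atol=1e-8)
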