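"""Design/penalty construction for every additive term type."""

import numpy as np
import pytest

import ordstar as o
from ordstar.bases import TermBlock, penalty_nullspace, penalty_rank
from ordstar.graphs import ZoneGraph


class TestBSpline:
    def test_partition_of_unity_and_size(self):
        x = np.linspace(-2.0, 5.0, 400)
        B, knots = o.bspline_design(x, n_knots=20, degree=3)
        assert B.shape == (400, 22)  # (20 - 1) + 3 columns
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert len(knots) == 20 and np.allclose(np.diff(knots), np.diff(knots)[0])

    def test_closed_right_endpoint(self):
        B, _ = o.bspline_design(np.array([0.0, 1.0]), n_knots=5, degree=3)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_degree0_indicator_bins(self):
        B, _ = o.bspline_design(np.array([0.0, 0.25, 0.5, 0.75, 1.0]), 3, 0)
        # hand recursion base case: bins [0, 0.5) and [0.5, 1]
        assert np.array_equal(B, [[1, 0], [1, 0], [0, 1], [0, 1], [0, 1]])

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            o.bspline_design(np.ones(10))

    def test_grid_reuse_of_knots(self):
        x = np.linspace(0, 1, 50)
        _, knots = o.bspline_design(x, 8, 3)
        B2, _ = o.bspline_design(np.linspace(0, 1, 7), knots=knots)
        assert B2.shape[1] == 10
        with pytest.raises(ValueError, match="extrapolation"):
            o.bspline_design(np.array([1.5]), knots=knots)


class TestDiffPenalty:
    def test_first_order_hand_matrix(self):
        assert np.array_equal(
            o.diff_penalty(3, 1), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_second_order_annihilates_lines(self):
        K = o.diff_penalty(12, 2)
        line = 0.7 * np.arange(1, 13) + 3.0
        assert np.allclose(K @ line, 0.0, atol=1e-12)
        assert penalty_rank(K) == 10

    @pytest.mark.parametrize("order", [1, 2])
    def test_zero_row_sums(self, order):
        assert np.allclose(o.diff_penalty(9, order).sum(axis=1), 0.0)


class TestMrfPenalty:
    def test_two_zone_hand_matrix(self):
        g = ZoneGraph(("A", "B"), {("A", "B")})
        assert np.array_equal(o.mrf_penalty(g), [[1, -1], [-1, 1]])

    def test_path_equals_rw1_penalty(self):
        g = ZoneGraph(tuple("ABCDE"), {("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")})
        assert np.array_equal(o.mrf_penalty(g), o.diff_penalty(5, 1))

    def test_constant_in_nullspace(self, lattice8):
        K = o.mrf_penalty(lattice8)
        assert np.allclose(K @ np.ones(64), 0.0)
        assert penalty_rank(K) == 63

    def test_quadratic_form_is_edge_sum(self, lattice8):
        K = o.mrf_penalty(lattice8)
        idx = lattice8.index()
        rng = np.random.default_rng(2)
        for _ in range(5):
            b = rng.standard_normal(64)
            edge_sum = sum(
                (b[idx[a]] - b[idx[c]]) ** 2
                for a, c in (tuple(e) for e in lattice8.edges)
            )
            assert b @ K @ b == pytest.approx(edge_sum, rel=1e-10)

    def test_island_zero_row_and_rank(self):
        g = ZoneGraph(("A", "B", "C"), {("A", "B")})
        K = o.mrf_penalty(g)
        assert np.all(K[2] == 0)
        assert penalty_rank(K) == 1  # N - #components


class TestTensor:
    def test_column_count_and_8knot_variant(self):
        rng = np.random.default_rng(0)
        lon, lat = rng.random(30), rng.random(30)
        B, K, meta = o.tensor_design(lon, lat, n_knots=8, degree=3)
        assert meta["p_lon"] == meta["p_lat"] == 10  # (8-1)+3 per margin
        assert B.shape == (30, 100) and K.shape == (100, 100)

    def test_constant_coefficient_in_nullspace(self):
        rng = np.random.default_rng(1)
        _, K, _ = o.tensor_design(rng.random(20), rng.random(20), n_knots=5)
        assert np.allclose(K @ np.ones(K.shape[0]), 0.0, atol=1e-10)

    def test_collinear_centroids_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            o.tensor_design(np.ones(5), np.arange(5.0), n_knots=5)


class TestIidAndConstraint:
    def test_incidence_design(self):
        g = ZoneGraph(("A", "B"))
        blk = o.iid_block(["A", "A", "B"], g)
        assert np.array_equal(blk.design, [[1, 0], [1, 0], [0, 1]])
        assert np.array_equal(blk.penalty, np.eye(2))
        assert blk.rank == 2 and blk.nullspace_dim == 0

    def test_empty_zone_keeps_column(self):
        g = ZoneGraph(("A", "B", "C"))
        blk = o.iid_block(["A", "B"], g)
        assert blk.design.shape == (2, 3)

    def test_constraint_drops_one_column(self, lattice8):
        blk = o.iid_block([lattice8.zone_ids[0]] * 5, lattice8)
        con = o.absorb_constraint(blk, constraint=np.ones(blk.p))
        assert con.p == blk.p - 1

    def test_constrained_fitted_values_sum_to_zero(self):
        rng = np.random.default_rng(4)
        x = rng.random(80)
        B, _ = o.bspline_design(x, 10, 3)
        blk = TermBlock("s", B, o.diff_penalty(B.shape[1], 2), "pspline")
        con = o.absorb_constraint(blk)
        beta = rng.standard_normal(con.p)
        assert abs((con.design @ beta).sum()) < 1e-8

    def test_pspline_retains_linear_nullspace(self):
        x = np.linspace(0, 1, 60)
        B, _ = o.bspline_design(x, 10, 3)
        blk = TermBlock("s", B, o.diff_penalty(B.shape[1], 2), "pspline")
        con = o.absorb_constraint(blk)
        # order-2 penalty nullspace is 2-dim; the constraint removes one
        assert con.nullspace_dim == 1
        N = penalty_nullspace(con.penalty)
        # the remaining direction is exactly linear in the coefficient
        # index (the RW2 nullspace) ...
        full = con.transform @ N[:, 0]
        assert np.abs(np.diff(full, 2)).max() < 1e-10
        # ... whose fitted curve is a near-straight trend in x
        fitted = con.design @ N[:, 0]
        assert abs(np.corrcoef(fitted, x)[0, 1]) > 0.99

    def test_zero_constraint_is_identity(self):
        blk = TermBlock("p", np.eye(3) - 1 / 3, o.diff_penalty(3, 1), "mrf")
        same = o.absorb_constraint(blk, constraint=np.zeros(3))
        assert same is blk


@pytest.mark.parametrize("kind", ["pspline", "mrf", "tensor", "iid"])
def test_penalties_psd_and_rank_accounting(kind, lattice8):
    rng = np.random.default_rng(11)
    if kind == "pspline":
        B, _ = o.bspline_design(rng.random(100), 12, 3)
        blk = TermBlock("t", B, o.diff_penalty(B.shape[1], 2), kind)
        blk = o.absorb_constraint(blk)
    elif kind == "mrf":
        zl = list(lattice8.zone_ids)
        blk = TermBlock(
            "t", o.iid_block(zl, lattice8).design, o.mrf_penalty(lattice8), kind
        )
        blk = o.absorb_constraint(blk, constraint=np.ones(blk.p))
    elif kind == "tensor":
        B, K, _ = o.tensor_design(rng.random(40), rng.random(40), n_knots=5)
        blk = TermBlock("t", B, K, kind)
        blk = o.absorb_constraint(blk, constraint=B.sum(axis=0))
    else:
        blk = o.iid_block(list(lattice8.zone_ids), lattice8)
        blk = o.absorb_constraint(blk, constraint=np.ones(blk.p))
    ev = np.linalg.eigvalsh(blk.penalty)
    assert ev.min() > -1e-10
    assert blk.rank + blk.nullspace_dim == blk.p
    if kind in ("mrf", "iid"):
        assert blk.nullspace_dim == 0
    if kind == "tensor":
        # first-order marginals on a connected grid: constants were the
        # only nullspace, absorbed by the constraint
        assert blk.nullspace_dim == 0
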