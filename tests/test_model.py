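"""Fitting machinery: oracle equality, constraints, edf, curves, zones."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import ordstar as o
from ordstar.likelihood import category_probs, ordinal_loglik
from ordstar.model import (
    IID,
    MRF,
    ModelSpec,
    Parametric,
    PSpline,
    Tensor,
    _build_blocks,
    _FitState,
    _inner_loop,
    _score_fisher,
    fit,
    variance_partition,
)
from ordstar.prep import PanelDataset


def make_parametric_data(n=80, seed=0, link="probit", beta=(0.8, -0.5)):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    eta = beta[0] * x1 + beta[1] * x2
    pi = category_probs(eta, (-0.4, 0.5), link)
    y = (rng.random(n)[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    df = pd.DataFrame(
        {"household": range(n), "zone": "z0", "wave": 1, "level": y,
         "x1": x1, "x2": x2}
    )
    return df, y, x1, x2


class TestParametricFit:
    @pytest.mark.parametrize("link", ["probit", "logit"])
    def test_equals_direct_ml(self, link):
        df, y, x1, x2 = make_parametric_data(seed=1, link=link)
        fm = fit(df, ModelSpec(terms=[Parametric(["x1", "x2"])], link=link))

        def negll(p):
            t1, d, g1, g2 = p
            return -ordinal_loglik(y, g1 * x1 + g2 * x2, (t1, t1 + np.exp(d)), link)

        res = minimize(negll, np.zeros(4), method="BFGS")
        t1, d, g1, g2 = res.x
        assert fm.thresholds[0] == pytest.approx(t1, abs=1e-4)
        assert fm.thresholds[1] == pytest.approx(t1 + np.exp(d), abs=1e-4)
        assert fm.gamma == pytest.approx([g1, g2], abs=1e-4)
        assert fm.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_thresholds_strictly_ordered(self):
        df, *_ = make_parametric_data(seed=2)
        fm = fit(df, ModelSpec(terms=[Parametric(["x1"])]))
        assert fm.thresholds[0] < fm.thresholds[1]

    def test_empty_category_rejected(self):
        df, *_ = make_parametric_data(seed=3)
        df["level"] = np.where(df["level"] == 2, 1, df["level"])
        with pytest.raises(ValueError, match="separat"):
            fit(df, ModelSpec(terms=[Parametric(["x1"])]))

    def test_probit_logit_sign_agreement(self, small_panel, default_truth_s):
        data, truth = small_panel
        terms = [Parametric(["urban", "read_write", "employed", "small_land"])]
        zs = {}
        for link in ("probit", "logit"):
            fm = fit(data, ModelSpec(terms=terms, link=link), truth.graph)
            tab = fm.coef_table()
            zs[link] = tab.loc[[i for i in tab.index if i.startswith("theta") is False]]
        strong = zs["probit"]["z"].abs() > 2
        assert (
            np.sign(zs["probit"]["estimate"][strong])
            == np.sign(zs["logit"]["estimate"][strong])
        ).all()

    def test_gcv_consistent_with_definition(self, small_fit):
        fm = small_fit
        assert fm.gcv == pytest.approx(
            fm.n * fm.deviance / (fm.n - fm.total_edf) ** 2
        )


class TestInnerLoop:
    def test_penalized_loglik_monotone_per_step(self, small_panel, default_truth_s):
        data, truth = small_panel
        spec = ModelSpec(terms=[Parametric(["urban"]), MRF(), IID()])
        X_par, names, blocks = _build_blocks(data, spec, truth.graph)
        y = data.df["level"].to_numpy(int)
        state = _FitState(X_par, names, blocks, y, "probit")
        state.tau2 = [0.5, 0.1]
        S = state.penalty_matrix()
        Sf = np.zeros((state.P + 2, state.P + 2))
        Sf[2:, 2:] = S
        trace = []
        _inner_loop(state, Sf, 40, trace=trace)
        diffs = np.diff(trace)
        assert len(trace) > 2
        assert np.all(diffs >= -1e-9)


class TestEffectiveDf:
    def build_state(self, small_panel, truth, tau2):
        data, _ = small_panel
        spec = ModelSpec(terms=[Parametric(["urban"]), MRF()])
        X_par, names, blocks = _build_blocks(data, spec, truth.graph)
        y = data.df["level"].to_numpy(int)
        state = _FitState(X_par, names, blocks, y, "probit")
        state.tau2 = [tau2]
        Sf = np.zeros((state.P + 2, state.P + 2))
        Sf[2:, 2:] = state.penalty_matrix()
        _inner_loop(state, Sf, 40)
        _, F = _score_fisher(state)
        H = np.linalg.inv(F + Sf)
        sl = state.slices[0]
        edf = np.einsum("ij,ji->i", H, F)[2 + sl.start:2 + sl.stop].sum()
        return edf, state.blocks[0]

    def test_limits_in_tau2(self, small_panel, default_truth_s):
        edf_hi, blk = self.build_state(small_panel, default_truth_s, 1e8)
        assert edf_hi == pytest.approx(blk.p, rel=1e-3)
        edf_lo, blk = self.build_state(small_panel, default_truth_s, 1e-10)
        assert edf_lo == pytest.approx(blk.nullspace_dim, abs=1e-3)

    def test_monotone_in_tau2(self, small_panel, default_truth_s):
        grid = [1e-4, 1e-2, 1.0, 1e2]
        edfs = [self.build_state(small_panel, default_truth_s, t)[0] for t in grid]
        assert np.all(np.diff(edfs) > 0)

    def test_reported_edf_matches_dense_trace(self, small_fit):
        # recompute block traces of (F+S)^{-1} F from the stored
        # matrices with plain dense algebra
        fm = small_fit
        H = np.linalg.solve(fm.fisher + fm.penalty, fm.fisher)
        d = np.diag(H)
        for t in fm.terms:
            if not t.stopped:
                assert d[2 + t.cols.start:2 + t.cols.stop].sum() == pytest.approx(
                    t.edf, rel=1e-6
                )

    def test_total_edf_accounting(self, small_fit):
        fm = small_fit
        expected = 2 + len(fm.par_names) + sum(t.edf for t in fm.terms)
        assert fm.total_edf == pytest.approx(expected)


class TestSpatialEffects:
    def test_constrained_zone_effects_sum_to_zero(self, small_fit):
        ze = small_fit.zone_effects()
        assert abs(ze["structured"].sum()) < 1e-6
        assert abs(ze["unstructured"].sum()) < 1e-6

    def test_hot_cluster_recovered(self, default_truth_s):
        from dataclasses import replace

        g = default_truth_s.graph
        f = {z: 0.0 for z in g.zone_ids}
        block = ["z00", "z01", "z08", "z09"]  # 2x2 corner block
        for z in block:
            f[z] = 1.0
        shift = np.mean(list(f.values()))
        f = {z: v - shift for z, v in f.items()}
        truth = replace(
            default_truth_s, f_str=f, f_unstr={z: 0.0 for z in g.zone_ids}
        )
        data, _ = o.gen_panel(truth, n_households=1000, seed=5)
        fm = fit(
            data,
            ModelSpec(terms=[Parametric(["urban"]), MRF(), IID()]),
            g,
        )
        ze = fm.zone_effects()
        assert (ze.loc[block, "class"] == "hot").sum() >= 3

    def test_variance_partition_worked_examples(self):
        assert variance_partition(0.6104, 0.0675) == 90.04
        assert variance_partition(0.3, 0.0) == 100.0
        assert variance_partition(0.2, 0.2) == 50.0
        with pytest.raises(ValueError):
            variance_partition(0.0, 0.0)

    def test_island_served_by_unstructured_only(self, default_truth_s):
        from ordstar.graphs import ZoneGraph

        g0 = default_truth_s.graph
        # cut all edges of one zone to make it an island
        iso = "z63"
        edges = {e for e in g0.edges if iso not in e}
        g = ZoneGraph(g0.zone_ids, edges, centroids=g0.centroids)
        data, _ = o.gen_panel(default_truth_s, n_households=400, seed=2)
        fm = fit(data, ModelSpec(terms=[MRF(), IID()]), g)
        ze = fm.zone_effects()
        assert ze.loc[iso, "structured"] == 0.0
        assert fm.term("f_str(zone)").meta["islands"] == [iso]


class TestSmoothCurve:
    def test_centered_and_extrapolation_refused(self, small_fit):
        fm = small_fit
        curve = fm.smooth_curve("dependency_ratio", grid=fm.term("dependency_ratio").meta["x_obs"])
        assert abs(curve["estimate"].mean()) < 1e-6
        with pytest.raises(ValueError, match="extrapolation"):
            fm.smooth_curve("dependency_ratio", grid=np.array([1e3]))

    def test_band_covers_linear_truth(self, default_truth_s):
        # truth has a linear effect of the covariate; the spline band
        # should cover the centered truth at nearly all grid points
        from dataclasses import replace

        g = default_truth_s.graph
        zero = {z: 0.0 for z in g.zone_ids}
        truth = replace(
            default_truth_s,
            f_str=zero, f_unstr=zero,
            smooth_fns={"dependency_ratio": lambda d: 0.3 * (np.asarray(d) - 1.2)},
        )
        # order-1 penalty: the linear truth is NOT in the nullspace, so
        # the term stays an active smooth with a full band (an order-2
        # spline would correctly freeze to a 1-df line, whose band is a
        # different object than the smooth band under test here)
        coverages = []
        for seed in (11, 12, 13, 14):
            data, _ = o.gen_panel(truth, n_households=1200, seed=seed)
            fm = fit(
                data,
                ModelSpec(
                    terms=[Parametric(["urban"]), PSpline("dependency_ratio", order=1)]
                ),
                g,
            )
            grid = np.linspace(0.05, 4.0, 40)
            curve = fm.smooth_curve("dependency_ratio", grid=grid)
            x_obs = fm.term("dependency_ratio").meta["x_obs"]
            true_centered = 0.3 * (grid - 1.2) - np.mean(0.3 * (x_obs - 1.2))
            coverages.append(
                (
                    (curve["lower95"] <= true_centered)
                    & (true_centered <= curve["upper95"])
                ).mean()
            )
        assert np.mean(coverages) >= 0.9

    def test_band_width_shrinks_with_n(self, default_truth_s):
        widths = []
        for n_h in (400, 2000):
            data, _ = o.gen_panel(default_truth_s, n_households=n_h, seed=4)
            fm = fit(
                data,
                ModelSpec(terms=[Parametric(["urban"]), PSpline("dependency_ratio")]),
                default_truth_s.graph,
            )
            grid = np.linspace(0.2, 3.5, 25)
            c = fm.smooth_curve("dependency_ratio", grid=grid)
            widths.append((c["upper95"] - c["lower95"]).mean())
        assert widths[1] < widths[0]


class TestStopRule:
    def test_stopped_pspline_degrades_to_linear(self, default_truth_s):
        # a covariate with no effect in truth: its smooth should stop
        # and keep exactly the linear nullspace (df = 1)
        from dataclasses import replace

        g = default_truth_s.graph
        zero = {z: 0.0 for z in g.zone_ids}
        truth = replace(default_truth_s, f_str=zero, f_unstr=zero, smooth_fns={})
        data, _ = o.gen_panel(truth, n_households=800, seed=13)
        fm = fit(
            data,
            ModelSpec(terms=[Parametric(["urban"]), PSpline("age")]),
            g,
        )
        t = fm.term("age")
        if t.stopped:
            assert t.edf == pytest.approx(1.0)
            assert t.tau2 <= fm.spec.stop_tau2

    def test_stopped_flag_semantics(self, small_fit):
        for t in small_fit.terms:
            assert t.stopped == (t.tau2 <= small_fit.spec.stop_tau2)


class TestTensorVariant:
    def test_tensor_fit_runs_and_partition(self, small_panel, default_truth_s):
        data, truth = small_panel
        fm = fit(
            data,
            ModelSpec(terms=[Parametric(["urban"]), Tensor(n_knots=8), IID()]),
            truth.graph,
        )
        assert fm.converged
        t = fm.term("f_str(lon,lat)")
        assert t.kind == "tensor"
        assert np.isfinite(fm.variance_partition())
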