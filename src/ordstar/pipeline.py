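"""End-to-end analysis workflow.

``run_analysis`` drives the whole study on one dataset: prepare
(ordinal coding, longitudinal imputation), describe (cross-tabs),
test for spatial clustering (Moran's I on zone aggregates), fit the
requested model variants (pure additive; MRF + unstructured; tensor
product of centroids at 8 and/or 20 knots + unstructured), compare
them by GCV, and export every table as CSV plus a plain-text summary.
``simulate`` writes a synthetic study (data CSV, ``.gra`` graph,
centroid CSV, truth sidecar) from the generator defaults.

All randomness (Moran permutations, simulation) is derived from one
config seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import ZoneGraph, read_graph, write_graph, read_centroids, write_centroids
from .moran import SpatialWeights, morans_i
from .model import (
    IID,
    MRF,
    ModelSpec,
    Parametric,
    PSpline,
    Tensor,
    fit,
)
from .prep import OrdinalCoding, PanelDataset, cross_tab, longitudinal_impute, zone_aggregate
from .synthetic import default_truth, gen_panel

__all__ = ["AnalysisConfig", "run_analysis", "simulate", "load_config", "default_terms"]

KNOWN_VARIANTS = ("additive", "mrf", "tensor-8", "tensor-20")


@dataclass
class AnalysisConfig:
    """Flat configuration of one analysis run."""

    data: str = ""
    graph: str = ""
    centroids: str = ""
    outdir: str = "ordstar_out"
    cuts: tuple = (35.5, 49.0)
    direction: str = "insecurity-ascending"
    link: str = "probit"
    factors: tuple = ()
    linear: tuple = ()          # numeric columns entering linearly
    smooths: tuple = ()         # continuous covariates given P-splines
    n_knots: int = 20
    spline_order: int = 2
    variants: tuple = ("additive", "mrf")
    stop_tau2: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-7
    moran_variable: str = "insecure-proportion"
    moran_row_standardize: bool = False
    moran_permutations: int = 9999
    seed: int = 0
    # simulate-only knobs
    n_households: int = 3835
    waves: int = 3
    missing_rate: float = 0.0

    def __post_init__(self):
        for v in self.variants:
            if v not in KNOWN_VARIANTS:
                raise ValueError(f"unknown model variant {v!r}; choose from {KNOWN_VARIANTS}")


_TUPLE_KEYS = {"factors", "linear", "smooths", "variants", "cuts"}


def load_config(path) -> AnalysisConfig:
    """Read a flat ``key: value`` (YAML) config file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _TUPLE_KEYS:
            if isinstance(val, str):
                val = [v.strip() for v in val.split(",") if v.strip()]
            val = tuple(float(v) if key == "cuts" else v for v in val)
        kwargs[key] = val
    return AnalysisConfig(**kwargs)


def default_terms(cfg: AnalysisConfig, variant: str):
    """Model terms for one comparison variant."""
    terms = []
    par = list(cfg.factors) + list(cfg.linear)
    if par:
        terms.append(Parametric(par))
    terms += [
        PSpline(v, n_knots=cfg.n_knots, order=cfg.spline_order) for v in cfg.smooths
    ]
    if variant == "mrf":
        terms += [MRF(), IID()]
    elif variant == "tensor-8":
        terms += [Tensor(n_knots=8), IID()]
    elif variant == "tensor-20":
        terms += [Tensor(n_knots=20), IID()]
    elif variant != "additive":
        raise ValueError(f"unknown variant {variant!r}")
    return terms


def _seeds(cfg: AnalysisConfig):
    """Deterministic seed split: one child stream per random stage."""
    ss = np.random.SeedSequence(cfg.seed)
    moran_seed, sim_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    return {"moran": moran_seed, "simulate": sim_seed}


def run_analysis(cfg: AnalysisConfig, data: PanelDataset | None = None,
                 graph: ZoneGraph | None = None) -> dict:
    """Run the full workflow; returns a results dict and writes CSVs.

    Every number written to the report bundle is produced by one of the
    package operations (no ad-hoc computation in this layer).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []

    def say(msg):
        log.append(msg)

    stage = "load"
    try:
        if graph is None:
            graph = read_graph(cfg.graph)
        if cfg.centroids:
            cents = read_centroids(cfg.centroids)
            graph = ZoneGraph(graph.zone_ids, graph.edges, centroids=cents)
        if data is None:
            coding = OrdinalCoding(cuts=tuple(cfg.cuts), direction=cfg.direction)
            df = pd.read_csv(cfg.data, na_values=["", "NA"])
            data = PanelDataset(
                df, factors=list(cfg.factors), covariates=list(cfg.smooths),
                coding=coding,
            )
        data.check_zones(graph)
        say(f"coding: cuts={data.coding.cuts} direction={data.coding.direction}")

        stage = "prepare"
        n_before = data.n_records
        data = longitudinal_impute(data)
        say(f"imputation: {n_before} -> {data.n_records} records "
            f"(single-wave households dropped, longitudinal means filled)")

        stage = "describe"
        tables = {}
        marg = cross_tab(data, None)
        marg.to_csv(out / "table_marginal.csv")
        tables["marginal"] = marg
        for fac in data.factors:
            tab = cross_tab(data, fac)
            tab.to_csv(out / f"table_{fac}.csv")
            tables[fac] = tab

        stage = "moran"
        seeds = _seeds(cfg)
        agg = zone_aggregate(data, cfg.moran_variable)
        w = SpatialWeights.from_graph(graph, row_standardize=cfg.moran_row_standardize)
        mres = morans_i(
            agg, w, permutations=cfg.moran_permutations, seed=seeds["moran"]
        )
        say(
            f"moran: variable={cfg.moran_variable} weights="
            f"{'row-standardized' if cfg.moran_row_standardize else 'binary'} "
            f"I={mres.I:.4f} E[I]={mres.expected:.4f} "
            f"p_analytic={mres.p_analytic:.4g} p_perm={mres.p_permutation:.4g}"
        )

        stage = "fit"
        fits = {}
        for variant in cfg.variants:
            spec = ModelSpec(
                terms=default_terms(cfg, variant), link=cfg.link,
                stop_tau2=cfg.stop_tau2, max_iter=cfg.max_iter, tol=cfg.tol,
            )
            fm = fit(data, spec, graph)
            fits[variant] = fm
            vdir = out / f"model_{variant}"
            vdir.mkdir(exist_ok=True)
            fm.coef_table().to_csv(vdir / "coefficients.csv")
            fm.smooth_table().to_csv(vdir / "smooth_terms.csv")
            for t in fm.terms:
                if t.kind == "pspline":
                    fm.smooth_curve(t.name).to_csv(
                        vdir / f"curve_{t.meta['var']}.csv", index=False
                    )
            if any(t.kind in ("mrf", "tensor", "iid") for t in fm.terms):
                fm.zone_effects().to_csv(vdir / "zone_effects.csv")
            say(f"fit[{variant}]: converged={fm.converged} iters={fm.n_iter} "
                f"edf={fm.total_edf:.2f} deviance={fm.deviance:.2f} GCV={fm.gcv:.4f}")

        stage = "compare"
        comp = pd.DataFrame(
            {
                v: {"gcv": fm.gcv, "edf": fm.total_edf, "deviance": fm.deviance,
                    "converged": fm.converged}
                for v, fm in fits.items()
            }
        ).T
        # argmin by GCV; ties (within 1e-8) broken by smaller edf
        order = sorted(
            fits, key=lambda v: (round(fits[v].gcv / 1e-8) * 1e-8, fits[v].total_edf)
        )
        best = order[0]
        comp["best"] = [v == best for v in comp.index]
        comp.to_csv(out / "model_comparison.csv")
        say(f"selected: {best} (smallest GCV; ties broken by smaller edf)")

        partition = None
        bf = fits[best]
        if any(t.kind in ("mrf", "tensor") for t in bf.terms) and any(
            t.kind == "iid" for t in bf.terms
        ):
            partition = bf.variance_partition()
            say(f"variance partition: structured share = {partition:.2f}%")

        summary = "\n".join(
            ["ordstar analysis report", "=" * 60]
            + log
            + ["", "Model comparison:", comp.to_string(), ""]
            + [fits[best].summary()]
        )
        (out / "summary.txt").write_text(summary + "\n", encoding="utf-8")
        return {
            "data": data, "graph": graph, "tables": tables, "moran": mres,
            "fits": fits, "comparison": comp, "best": best,
            "variance_partition": partition, "log": log,
        }
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(
            f"analysis failed at stage '{stage}': {err}. "
            f"Check the inputs feeding that stage."
        ) from err


def simulate(cfg: AnalysisConfig, outdir: str | None = None) -> dict:
    """Generate a synthetic study and write its files.

    Writes ``data.csv``, ``zones.gra``, ``centroids.csv`` and a
    ``truth.json`` sidecar with the generating parameters.
    """
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(cfg)
    truth = default_truth(seed=seeds["simulate"])
    data, _ = gen_panel(
        truth, n_households=cfg.n_households, waves=cfg.waves,
        seed=seeds["simulate"], missing_rate=cfg.missing_rate,
    )
    data.df.to_csv(out / "data.csv", index=False)
    write_graph(truth.graph, out / "zones.gra")
    write_centroids(truth.graph.centroids, out / "centroids.csv")
    sidecar = {
        "offset": truth.offset,
        "thresholds": list(truth.thresholds),
        "link": truth.link,
        "tau2_str": truth.tau2_str,
        "tau2_unstr": truth.tau2_unstr,
        "structured_share": truth.structured_share,
        "gamma": truth.gamma,
        "prevalence": truth.prevalence,
        "wave_trend": truth.wave_trend,
        "f_str": truth.f_str,
        "f_unstr": truth.f_unstr,
        "seed": cfg.seed,
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")
    return {"data": data, "truth": truth, "outdir": out}
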