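"""Response coding, imputation and descriptive summaries.

The ordinal outcome is a 3-level food-insecurity classification of the
household food consumption score (FCS): scores at or below the lower
cut are *insecure*, scores above the upper cut are *secure*, scores in
between are *vulnerable*.  The study's locally adjusted cuts are
(35.5, 49).

The internal canonical level coding is insecurity-ascending:
0 = secure, 1 = vulnerable, 2 = insecure.  Under the cumulative link
P(Y <= r) = F(theta_r - eta) this makes a *positive* linear effect
increase the probability of the higher (more insecure) levels, which is
the sign convention used when reporting coefficient tables.  The
opposite direction is available and recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalCoding",
    "PanelDataset",
    "CATEGORY_ORDER",
    "categorize_fcs",
    "longitudinal_impute",
    "cross_tab",
    "zone_aggregate",
]

#: Category names ordered from most to least insecure, the layout used
#: in descriptive tables.
CATEGORY_ORDER = ("insecure", "vulnerable", "secure")


@dataclass(frozen=True)
class OrdinalCoding:
    """Cut points on the FCS scale and the direction of the level code.

    ``direction='insecurity-ascending'`` (default, canonical): level
    0 = secure, 1 = vulnerable, 2 = insecure.
    ``direction='insecurity-descending'``: level 0 = insecure, ...,
    2 = secure.
    """

    cuts: tuple = (35.5, 49.0)
    direction: str = "insecurity-ascending"

    def __post_init__(self):
        c1, c2 = self.cuts
        if not (np.isfinite(c1) and np.isfinite(c2) and c1 < c2):
            raise ValueError(f"cuts must be finite with c1 < c2, got {self.cuts}")
        if self.direction not in ("insecurity-ascending", "insecurity-descending"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def level_of(self, category: str) -> int:
        """Integer level of a named category under this coding."""
        if self.direction == "insecurity-ascending":
            return {"secure": 0, "vulnerable": 1, "insecure": 2}[category]
        return {"insecure": 0, "vulnerable": 1, "secure": 2}[category]

    def category_of(self, level: int) -> str:
        for cat in CATEGORY_ORDER:
            if self.level_of(cat) == level:
                return cat
        raise ValueError(f"level {level} outside 0..2")


def categorize_fcs(fcs, coding: OrdinalCoding | None = None):
    """Map FCS value(s) to ordinal level(s).

    Bands are half-open with the upper bound inclusive:
    ``fcs <= c1`` -> insecure, ``c1 < fcs <= c2`` -> vulnerable,
    ``fcs > c2`` -> secure.  Negative or non-finite scores raise.
    Accepts scalars or arrays; NaN propagates (missing stays missing)
    when the input is an array.
    """
    coding = coding or OrdinalCoding()
    c1, c2 = coding.cuts
    x = np.asarray(fcs, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    mask = ~np.isnan(x)
    if np.any(x[mask] < 0) or np.any(np.isinf(x[mask])):
        raise ValueError("FCS values must be finite and non-negative")
    out = np.full(x.shape, np.nan)
    out[mask & (x <= c1)] = coding.level_of("insecure")
    out[mask & (x > c1) & (x <= c2)] = coding.level_of("vulnerable")
    out[mask & (x > c2)] = coding.level_of("secure")
    if scalar:
        if np.isnan(out[0]):
            raise ValueError("FCS value is missing")
        return int(out[0])
    return out


@dataclass
class PanelDataset:
    """Household x wave records with the ordinal outcome.

    ``df`` must contain columns ``household``, ``zone``, ``wave`` and
    (at least one of) ``fcs`` / ``level``, plus the declared factor and
    covariate columns.  ``(household, wave)`` pairs are unique and
    every zone label must appear in the companion :class:`ZoneGraph`
    when one is supplied to downstream steps.
    """

    df: pd.DataFrame
    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    coding: OrdinalCoding = field(default_factory=OrdinalCoding)

    def __post_init__(self):
        required = {"household", "zone", "wave"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if "level" not in self.df.columns and "fcs" not in self.df.columns:
            raise ValueError("dataset needs a 'level' or 'fcs' column")
        dup = self.df.duplicated(subset=["household", "wave"])
        if dup.any():
            bad = self.df.loc[dup, ["household", "wave"]].iloc[0]
            raise ValueError(
                f"duplicate (household, wave) record: {tuple(bad)}"
            )
        for col in list(self.factors) + list(self.covariates):
            if col not in self.df.columns:
                raise ValueError(f"declared column {col!r} not in data")
        if "level" not in self.df.columns:
            self.df = self.df.assign(level=categorize_fcs(self.df["fcs"], self.coding))

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_households(self) -> int:
        return self.df["household"].nunique()

    def check_zones(self, graph) -> None:
        unknown = set(self.df["zone"]) - set(graph.zone_ids)
        if unknown:
            raise ValueError(f"records reference zones not in graph: {sorted(unknown)[:5]}")


def longitudinal_impute(data: PanelDataset) -> PanelDataset:
    """Fill missing values by longitudinal (within-household) means.

    Households observed in only one wave are dropped first.  Missing
    continuous values (fcs, covariates) are replaced by the household's
    across-wave mean, falling back to the overall variable mean when a
    household has no observed wave.  Missing categorical values go to
    the household mode, then the global mode.  The outcome level is
    re-derived from the imputed FCS where it was missing; levels are
    never pooled across households.  Non-missing values are untouched.
    """
    df = data.df.copy()
    counts = df.groupby("household")["wave"].transform("size")
    df = df[counts >= 2].copy()

    cont = [c for c in (["fcs"] if "fcs" in df.columns else []) + list(data.covariates)]
    for col in cont:
        if df[col].isna().all():
            raise ValueError(f"variable {col!r} missing for all records")
        hh_mean = df.groupby("household")[col].transform("mean")
        df[col] = df[col].fillna(hh_mean).fillna(df[col].mean())

    for col in data.factors:
        if df[col].isna().all():
            raise ValueError(f"factor {col!r} missing for all records")

        def _mode(s):
            m = s.mode()
            return m.iloc[0] if len(m) else np.nan

        hh_mode = df.groupby("household")[col].transform(_mode)
        df[col] = df[col].fillna(hh_mode).fillna(_mode(df[col]))

    if "fcs" in df.columns:
        lev = df["level"] if "level" in df.columns else pd.Series(np.nan, index=df.index)
        need = lev.isna()
        if need.any():
            df.loc[need, "level"] = categorize_fcs(
                df.loc[need, "fcs"].to_numpy(), data.coding
            )
    return replace(data, df=df.reset_index(drop=True))


def cross_tab(data: PanelDataset, factor: str, decimals: int = 1) -> pd.DataFrame:
    """Row percentages of the three insecurity categories per factor level.

    Columns are ordered (insecure, vulnerable, secure) as in standard
    descriptive tables; each row sums to 100% within rounding
    (half-up to ``decimals``).  Pass ``factor=None`` for the marginal
    distribution (single row labelled 'all').
    """
    df = data.df
    lev = df["level"].astype(int)
    cats = pd.Series(
        [data.coding.category_of(v) for v in lev], index=df.index, name="category"
    )
    group = df[factor].astype(str) if factor is not None else pd.Series("all", index=df.index)
    tab = pd.crosstab(group, cats)
    for c in CATEGORY_ORDER:
        if c not in tab.columns:
            tab[c] = 0
    tab = tab[list(CATEGORY_ORDER)]
    totals = tab.sum(axis=1)
    pct = tab.div(totals.replace(0, np.nan), axis=0) * 100.0
    # half-up rounding, matching conventional table style
    out = np.floor(pct * 10**decimals + 0.5) / 10**decimals
    out = out.fillna(0.0)
    out.index.name = factor if factor is not None else "group"
    return out


def zone_aggregate(data: PanelDataset, statistic: str = "insecure-proportion") -> pd.Series:
    """One value per zone; zones with no records are absent (no-data).

    ``statistic`` is one of ``mean-fcs``, ``insecure-proportion``
    (share of records in the most insecure category) or ``modal-level``.
    """
    df = data.df
    g = df.groupby("zone")
    if statistic == "mean-fcs":
        if "fcs" not in df.columns:
            raise ValueError("dataset has no 'fcs' column")
        out = g["fcs"].mean()
    elif statistic == "insecure-proportion":
        insec = data.coding.level_of("insecure")
        out = g["level"].apply(lambda s: float(np.mean(s == insec)))
    elif statistic == "modal-level":
        out = g["level"].apply(lambda s: int(s.mode().iloc[0]))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out.name = statistic
    return out
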