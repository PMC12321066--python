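"""Per-individual trait covariates: size adjustment, condition, instances.

Anatomical traits scale with body size, so analyses run on the residuals of
an ordinary least-squares regression of each trait against snout-vent length
(SVL), fitted per species over all capture events.  Body condition is the
residual of weight regressed on SVL (optionally on log-log scale).  Color
values (CIELAB) are used as measured.

Because individuals are measured at every capture, each trait yields a short
series of repeated measurements; the survival models use exactly one value
per individual, chosen by an *instance selector*: the first measurement, the
last, or the numeric median of all measurements (mean of the central pair for
even counts).  Single-capture individuals return their only value under all
three selectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .capture_io import Dataset

InstanceSelector = Literal["first", "median", "last"]
SELECTORS: tuple[InstanceSelector, ...] = ("first", "median", "last")


class TraitPrepError(ValueError):
    """Raised when a covariate or adjustment cannot be computed."""


@dataclass(frozen=True)
class TraitSeries:
    """Repeated measurements of one trait for one individual."""

    individual_id: str
    trait_name: str
    observations: tuple[tuple[int, float], ...]  # (occasion, value), occasions increasing

    def __post_init__(self) -> None:
        obs = tuple((int(o), float(v)) for o, v in self.observations)
        occs = [o for o, _ in obs]
        if any(b <= a for a, b in zip(occs, occs[1:])):
            raise ValueError("occasions must be strictly increasing")
        if any(not math.isfinite(v) for _, v in obs):
            raise ValueError("trait values must be finite")
        object.__setattr__(self, "observations", obs)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.observations])


@dataclass(frozen=True)
class SizeAdjustment:
    """Per-species OLS of a trait on SVL; residuals are the adjusted trait."""

    trait_name: str
    intercept: float
    slope: float
    n_events: int

    def residuals(self, svl: np.ndarray, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) - (
            self.intercept + self.slope * np.asarray(svl, dtype=float)
        )


def fit_size_adjustment(
    events: pd.DataFrame, trait_name: str, svl_col: str = "svl"
) -> SizeAdjustment:
    """OLS regression of ``trait_name`` on SVL over capture events of one species.

    Requires at least 3 complete (trait, SVL) pairs and non-degenerate SVL.
    Residuals of the returned fit have mean zero over the fitted events.
    """
    if trait_name not in events.columns or svl_col not in events.columns:
        raise TraitPrepError(f"columns {trait_name!r} and {svl_col!r} required")
    sub = events[[svl_col, trait_name]].dropna()
    if len(sub) < 3:
        raise TraitPrepError(
            f"{trait_name}: need >=3 complete (trait, SVL) pairs, have {len(sub)}"
        )
    x = sub[svl_col].to_numpy(dtype=float)
    y = sub[trait_name].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise TraitPrepError(f"{trait_name}: SVL has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    return SizeAdjustment(trait_name, float(intercept), float(slope), len(sub))


def condition_residuals(
    events: pd.DataFrame,
    svl_col: str = "svl",
    weight_col: str = "weight",
    log_log: bool = False,
) -> pd.Series:
    """Body condition per event: residual of weight on SVL (one species).

    With ``log_log=True`` the regression is log(weight) ~ log(SVL), the
    allometric variant; the default is the plain linear regression.
    """
    frame = events[[svl_col, weight_col]].astype(float)
    if log_log:
        frame = np.log(frame)
    frame = frame.rename(columns={weight_col: "condition"})
    adj = fit_size_adjustment(frame, "condition", svl_col)
    return pd.Series(
        adj.residuals(frame[svl_col].to_numpy(), frame["condition"].to_numpy()),
        index=events.index,
        name="condition",
    )


def size_adjust(
    ds: Dataset,
    traits: Sequence[str],
    svl_col: str = "svl",
    suffix: str = "_adj",
) -> Dataset:
    """Return a dataset with SVL-adjusted columns ``<trait><suffix>`` added.

    Adjustments are fitted per species, pooling all capture events; residuals
    are computed per event with the same-event SVL.  Events lacking the trait
    or SVL get a missing adjusted value.
    """
    frame = ds.events.copy()
    for trait in traits:
        frame[trait + suffix] = np.nan
    for sp, grp in frame.groupby("species"):
        for trait in traits:
            adj = fit_size_adjustment(grp, trait, svl_col)
            res = adj.residuals(grp[svl_col].to_numpy(), grp[trait].to_numpy())
            frame.loc[grp.index, trait + suffix] = res
    return Dataset(ds.design, frame)


def add_body_condition(
    ds: Dataset,
    svl_col: str = "svl",
    weight_col: str = "weight",
    log_log: bool = False,
    name: str = "condition",
) -> Dataset:
    """Return a dataset with a per-event body-condition column added."""
    frame = ds.events.copy()
    frame[name] = np.nan
    for sp, grp in frame.groupby("species"):
        complete = grp[[svl_col, weight_col]].notna().all(axis=1)
        sub = grp[complete]
        res = condition_residuals(sub, svl_col, weight_col, log_log=log_log)
        frame.loc[sub.index, name] = res
    return Dataset(ds.design, frame)


def trait_series(ds: Dataset, trait_name: str) -> list[TraitSeries]:
    """Extract the measurement series of one trait, one per individual.

    Individuals with no non-missing measurement of the trait are omitted.
    """
    out: list[TraitSeries] = []
    for ind, grp in sorted(ds.events.groupby("individual_id"), key=lambda kv: kv[0]):
        obs = grp[["occasion", trait_name]].dropna().sort_values("occasion")
        if obs.empty:
            continue
        out.append(
            TraitSeries(str(ind), trait_name,
                        tuple((int(o), float(v)) for o, v in obs.itertuples(index=False)))
        )
    return out


def select_instance(series: TraitSeries, selector: InstanceSelector) -> float:
    """Pick one covariate value from a measurement series.

    ``first``/``last`` take the value at the earliest/latest occasion;
    ``median`` is the numeric median of all values (mean of the two central
    values for even counts).  A single-capture series returns its only value
    under all three selectors.
    """
    if not series.observations:
        raise TraitPrepError("empty trait series")
    if selector == "first":
        return series.observations[0][1]
    if selector == "last":
        return series.observations[-1][1]
    if selector == "median":
        return float(np.median(series.values))
    raise TraitPrepError(f"unknown selector {selector!r}")


@dataclass(frozen=True)
class CovariateTable:
    """One covariate value per individual for a trait x selector pair."""

    trait_name: str
    selector: InstanceSelector
    values: pd.Series  # indexed by individual_id
    excluded: tuple[str, ...]  # individuals with no measurement of the trait
    mean: float
    sd: float
    standardized: bool


def build_covariate_table(
    ds: Dataset,
    trait_name: str,
    selector: InstanceSelector,
    standardize: bool = True,
) -> CovariateTable:
    """Build the per-individual covariate for one trait and instance selector.

    With ``standardize`` (the default) values are z-scored across the included
    individuals (sample SD, n-1 denominator) for optimizer conditioning;
    coefficient signs are unaffected.  Individuals lacking any measurement of
    the trait are excluded and reported.
    """
    if trait_name not in ds.events.columns:
        raise TraitPrepError(f"no trait column {trait_name!r}")
    if selector not in SELECTORS:
        raise TraitPrepError(f"unknown selector {selector!r}")
    sub = (
        ds.events[["individual_id", "occasion", trait_name]]
        .dropna(subset=[trait_name])
        .sort_values(["individual_id", "occasion"], kind="mergesort")
    )
    grouped = sub.groupby("individual_id")[trait_name]
    if selector == "first":
        raw = grouped.first()
    elif selector == "last":
        raw = grouped.last()
    else:  # numeric median; pandas averages the central pair for even counts
        raw = grouped.median()
    raw = raw.astype(float).sort_index()
    raw.name = trait_name
    excluded = tuple(i for i in ds.individuals if i not in raw.index)
    if len(raw) < 2:
        raise TraitPrepError(
            f"{trait_name}: need >=2 individuals with data, have {len(raw)}"
        )
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if standardize:
        if sd == 0.0:
            raise TraitPrepError(f"{trait_name}: zero variance across individuals")
        values = (raw - mean) / sd
    else:
        values = raw
    return CovariateTable(trait_name, selector, values, excluded, mean, sd, standardize)


def covariate_frame(tables: Iterable[CovariateTable], species: str | None = None) -> pd.DataFrame:
    """Long-format CSV-ready view of covariate tables."""
    rows = []
    for tab in tables:
        for ind, val in tab.values.items():
            rows.append(
                {"individual_id": ind, "species": species, "trait": tab.trait_name,
                 "selector": tab.selector, "value": val}
            )
    return pd.DataFrame(rows)
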