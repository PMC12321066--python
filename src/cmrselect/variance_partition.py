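"""Among- versus within-individual trait variance via one-way ANOVA.

For each trait, a one-way ANOVA with individual identity as the factor —
restricted to individuals with at least two measurements — partitions the
total sum of squares into an among-individual and a within-individual
(intraindividual) component.  The F statistic (MS_among / MS_within) and
R² (SS_among / SS_total) quantify how much of the observable trait variation
is attributable to differences among individuals rather than to fluctuation
within them.  The intraclass correlation (repeatability) follows from the
mean squares with the standard unbalanced-design effective group size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture_io import Dataset


class VariancePartitionError(ValueError):
    """Raised when the ANOVA preconditions are not met."""


@dataclass(frozen=True)
class VariancePartition:
    """One-way ANOVA decomposition of one trait by individual identity."""

    trait_name: str
    species: str | None
    F: float  # +inf when SS_within is exactly zero; nan when SS_total is zero
    R2: float
    df_among: int
    df_within: int
    n_individuals: int  # individuals with >=2 measurements
    n_events: int
    MS_among: float
    MS_within: float
    m0: float  # effective group size (n_events - sum n_i^2 / n_events) / (k - 1)

    @property
    def SS_among(self) -> float:
        return self.MS_among * self.df_among

    @property
    def SS_within(self) -> float:
        return self.MS_within * self.df_within


def anova_by_individual(
    measurements: pd.DataFrame,
    value_col: str = "value",
    id_col: str = "individual_id",
    trait_name: str = "trait",
    species: str | None = None,
) -> VariancePartition:
    """One-way ANOVA of a trait on individual identity.

    ``measurements`` is long-format with one row per measurement.  Individuals
    with a single measurement are excluded; at least two qualifying
    individuals are required.  If the within-group sum of squares is exactly
    zero, F is flagged +inf and R² is 1.
    """
    sub = measurements[[id_col, value_col]].dropna()
    sizes = sub.groupby(id_col)[value_col].size()
    keep = sizes[sizes >= 2].index
    sub = sub[sub[id_col].isin(keep)]
    k = len(keep)
    if k < 2:
        raise VariancePartitionError(
            f"{trait_name}: need >=2 individuals with >=2 measurements, have {k}"
        )
    y = sub[value_col].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    groups = sub.groupby(id_col)[value_col]
    n_i = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy(dtype=float)
    ss_among = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((y - grand) ** 2)) - ss_among
    ss_within = max(ss_within, 0.0)  # guard rounding
    df_among = k - 1
    df_within = n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    ss_total = ss_among + ss_within
    if ss_total == 0.0:
        F, r2 = float("nan"), 0.0
    elif ss_within == 0.0:
        F, r2 = float("inf"), 1.0
    else:
        F = ms_among / ms_within
        r2 = ss_among / ss_total
    m0 = (n - float(np.sum(n_i**2)) / n) / df_among
    return VariancePartition(
        trait_name=trait_name,
        species=species,
        F=F,
        R2=r2,
        df_among=df_among,
        df_within=df_within,
        n_individuals=k,
        n_events=n,
        MS_among=ms_among,
        MS_within=ms_within,
        m0=m0,
    )


def partition_trait(ds: Dataset, trait_name: str) -> list[VariancePartition]:
    """Run the ANOVA for one trait separately in every species of a dataset."""
    out = []
    for sp in ds.species:
        events = ds.for_species(sp).events
        out.append(
            anova_by_individual(
                events.rename(columns={trait_name: "value"}),
                trait_name=trait_name,
                species=sp,
            )
        )
    return out


def repeatability(vp: VariancePartition, mean_group_size: float | None = None) -> float:
    """Intraclass correlation (repeatability) from the ANOVA mean squares.

    ICC = (MS_among - MS_within) / (MS_among + (m0 - 1) MS_within), with m0
    the effective group size stored on the partition (override with
    ``mean_group_size``); clamped to [0, 1].  Zero within-individual variance
    gives 1.
    """
    m0 = vp.m0 if mean_group_size is None else float(mean_group_size)
    if vp.MS_within == 0.0 or np.isinf(vp.F):
        return 1.0
    icc = (vp.MS_among - vp.MS_within) / (vp.MS_among + (m0 - 1.0) * vp.MS_within)
    return float(min(1.0, max(0.0, icc)))


def partition_frame(partitions: list[VariancePartition]) -> pd.DataFrame:
    """CSV-ready view: one row per species x trait with F, R², repeatability."""
    rows = []
    for vp in partitions:
        rows.append(
            {"species": vp.species, "trait": vp.trait_name,
             "n_individuals": vp.n_individuals, "n_events": vp.n_events,
             "F": vp.F, "R2": vp.R2, "MS_among": vp.MS_among,
             "MS_within": vp.MS_within, "repeatability": repeatability(vp),
             "zero_within_ss": bool(np.isinf(vp.F))}
        )
    return pd.DataFrame(rows)
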