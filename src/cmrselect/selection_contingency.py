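"""Four-cell contingency verdicts on viability selection.

The classifier combines two lines of evidence about one trait:

* the variance partition (F and R² from the one-way ANOVA on individual
  identity), which says whether among-individual differences dominate
  intraindividual fluctuation, and
* the ΔAIC triplet of the survival-by-trait model against the null for the
  first, median and last measurement instance.

The column is "lower intraindividual variation" iff F ≥ F_high AND
R² ≥ R2_high (values exactly at a threshold count as high; an infinite F from
zero within-individual variance counts as high).  The row is "stronger
evidence of directional selection" iff every selector's ΔAIC is below
``-strict_margin``.  The four cells:

====================  ==========================  ================================
row \\ column          lower intraindividual var   higher intraindividual var
====================  ==========================  ================================
stronger (all neg.)   under_selection             possibly_spurious
weaker                not_under_selection         obscured_by_intraindividual_variation
====================  ==========================  ================================

Thresholds default to F ≥ 4.0 and R² ≥ 0.5 but are configuration-exposed:
they are a descriptive confidence heuristic, not a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cjs_core import ModelComparison, SELECTORS
from .variance_partition import VariancePartition

CELLS = (
    "under_selection",
    "not_under_selection",
    "obscured_by_intraindividual_variation",
    "possibly_spurious",
)

DIRECTIONS = ("positive", "negative", "mixed", "none")


class ContingencyError(ValueError):
    """Raised when the inputs for a verdict are incomplete or inconsistent."""


@dataclass(frozen=True)
class ContingencyThresholds:
    """Cutoffs for the contingency classification."""

    f_high: float = 4.0
    r2_high: float = 0.5
    require_all_negative: bool = True  # False: any negative dAIC puts a trait in the stronger row
    strict_margin: float = 0.0  # use 2.0 for the stricter dAIC <= -2 rule

    def __post_init__(self) -> None:
        if self.f_high <= 0 or self.r2_high <= 0:
            raise ValueError("thresholds must be positive")
        if self.strict_margin < 0:
            raise ValueError("strict_margin must be >= 0")


@dataclass(frozen=True)
class SelectionVerdict:
    """The contingency cell assigned to one trait, with its inputs echoed."""

    trait_name: str
    species: str | None
    cell: str
    direction: str
    F: float
    R2: float
    dAIC: tuple[float, ...]
    beta1: tuple[float, ...]


def classify_values(
    F: float,
    R2: float,
    dAIC: Sequence[float],
    beta1: Sequence[float],
    thresholds: ContingencyThresholds = ContingencyThresholds(),
) -> tuple[str, str]:
    """Pure kernel: map (F, R², ΔAIC triplet, β₁ triplet) to (cell, direction).

    Deterministic in its inputs; identical inputs give identical verdicts.
    """
    if len(dAIC) != 3 or len(beta1) != 3:
        raise ContingencyError("need dAIC and beta1 for all three instance selectors")
    if any(not np.isfinite(d) for d in dAIC):
        raise ContingencyError("all three dAIC values must be finite")
    low_iiv = (F >= thresholds.f_high) and (R2 >= thresholds.r2_high)
    negative = [d < -thresholds.strict_margin for d in dAIC]
    stronger = all(negative) if thresholds.require_all_negative else any(negative)
    if stronger:
        cell = "under_selection" if low_iiv else "possibly_spurious"
    else:
        cell = "not_under_selection" if low_iiv else "obscured_by_intraindividual_variation"

    if cell == "not_under_selection":
        direction = "none"
    elif all(b > 0 for b in beta1):
        direction = "positive"
    elif all(b < 0 for b in beta1):
        direction = "negative"
    else:
        direction = "mixed"
    return cell, direction


def classify(
    vp: VariancePartition,
    mc: ModelComparison,
    thresholds: ContingencyThresholds = ContingencyThresholds(),
) -> SelectionVerdict:
    """Assign one trait its contingency cell from ANOVA and model-scan results.

    Requires the variance partition and the model comparison to refer to the
    same trait and species, and all three selector fits to have succeeded.
    """
    if vp.trait_name != mc.trait_name:
        raise ContingencyError(
            f"trait mismatch: {vp.trait_name!r} vs {mc.trait_name!r}"
        )
    if vp.species is not None and vp.species != mc.species:
        raise ContingencyError(f"species mismatch: {vp.species!r} vs {mc.species!r}")
    missing = [s for s in SELECTORS if s not in mc.results or mc.results[s].error]
    if missing:
        raise ContingencyError(f"{mc.trait_name}: missing selector fit(s) {missing}")
    dAIC = mc.dAIC()
    beta1 = mc.beta1()
    cell, direction = classify_values(vp.F, vp.R2, dAIC, beta1, thresholds)
    return SelectionVerdict(
        trait_name=vp.trait_name,
        species=mc.species,
        cell=cell,
        direction=direction,
        F=vp.F,
        R2=vp.R2,
        dAIC=dAIC,
        beta1=beta1,
    )


def verdict_summary(verdicts: Sequence[SelectionVerdict]) -> str:
    """Human-readable four-cell summary listing traits per cell, per species."""
    lines: list[str] = []
    species = sorted({v.species or "" for v in verdicts})
    headers = {
        "under_selection": "Evidence trait is currently under selection",
        "not_under_selection": "Evidence trait is not currently under selection",
        "obscured_by_intraindividual_variation":
            "High intraindividual variation obscures or inhibits inference of selection",
        "possibly_spurious":
            "High intraindividual variation: possibly spurious evidence of selection",
    }
    for sp in species:
        lines.append(f"species: {sp}")
        for cell in CELLS:
            names = [
                f"{v.trait_name} ({v.direction})"
                for v in verdicts
                if (v.species or "") == sp and v.cell == cell
            ]
            lines.append(f"  [{headers[cell]}]")
            lines.append("    " + (", ".join(names) if names else "(none)"))
        lines.append("")
    return "\n".join(lines)
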