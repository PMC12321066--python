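"""Input, validation, and encounter-history construction for capture data.

Long-format capture data — one row per capture event carrying an individual
identifier, a species code, a 1-based sampling occasion, and any number of
numeric trait columns — are validated against a :class:`StudyDesign` and held
in a :class:`Dataset`.  Binary encounter histories (conditioned on first
capture) built from a dataset are the input to the survival models in
:mod:`cmrselect.cjs_core`.

Conventions
-----------
* Occasions are 1-based and follow the documented order of the design.
* Within-occasion duplicate captures of one individual are collapsed to a
  single detection with trait values averaged (a season is one occasion).
* Missing trait values are allowed per event and handled downstream per trait.
* CIELAB lightness columns (named ``L`` or ending in ``_L``) must lie in
  [0, 100]; ``svl`` and ``weight`` columns, when present, must be positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns with fixed meaning; everything else in a capture file is a trait.
ID_COLUMNS = ("individual_id", "species", "occasion", "date")


class CaptureDataError(ValueError):
    """Capture data failed validation against the study design."""


def _is_lightness(name: str) -> bool:
    return name == "L" or name.endswith("_L")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: ordered occasions and admissible species codes.

    Parameters
    ----------
    occasions
        Ordered ``(label, time)`` pairs, time in decimal years, strictly
        increasing.  At least two occasions are required.
    species_codes
        The species labels admissible in a capture file.
    """

    occasions: tuple[tuple[str, float], ...]
    species_codes: frozenset[str]

    def __post_init__(self) -> None:
        occ = tuple((str(lab), float(t)) for lab, t in self.occasions)
        if len(occ) < 2:
            raise ValueError("a study design needs at least 2 occasions")
        times = [t for _, t in occ]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("occasion times must be strictly increasing")
        object.__setattr__(self, "occasions", occ)
        object.__setattr__(self, "species_codes", frozenset(self.species_codes))

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.occasions)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, t in self.occasions], dtype=float)


@dataclass(frozen=True)
class CaptureEvent:
    """One capture of one individual on one occasion, with trait readings."""

    individual_id: str
    species: str
    occasion: int  # 1-based index into the design
    traits: Mapping[str, float]

    def validate(self, design: StudyDesign) -> None:
        if not 1 <= self.occasion <= design.n_occasions:
            raise CaptureDataError(
                f"individual {self.individual_id!r}: occasion {self.occasion} "
                f"outside design (1..{design.n_occasions})"
            )
        if self.species not in design.species_codes:
            raise CaptureDataError(
                f"individual {self.individual_id!r}: unknown species {self.species!r}"
            )
        for name, value in self.traits.items():
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            if not np.isfinite(value):
                raise CaptureDataError(
                    f"individual {self.individual_id!r}: non-finite {name}={value}"
                )
            if _is_lightness(name) and not 0.0 <= value <= 100.0:
                raise CaptureDataError(
                    f"individual {self.individual_id!r}: lightness {name}={value} "
                    "outside [0, 100]"
                )


@dataclass(frozen=True)
class EncounterHistory:
    """Per-individual binary detection vector over the study occasions."""

    individual_id: str
    detections: tuple[int, ...]

    def __post_init__(self) -> None:
        det = tuple(int(d) for d in self.detections)
        if not any(det):
            raise ValueError(f"{self.individual_id!r}: history has no detections")
        if any(d not in (0, 1) for d in det):
            raise ValueError(f"{self.individual_id!r}: detections must be 0/1")
        object.__setattr__(self, "detections", det)

    @property
    def first(self) -> int:
        """1-based occasion of first detection."""
        return self.detections.index(1) + 1

    @property
    def last(self) -> int:
        """1-based occasion of last detection."""
        return len(self.detections) - self.detections[::-1].index(1)

    @property
    def history(self) -> str:
        return "".join(str(d) for d in self.detections)

    @classmethod
    def from_string(cls, individual_id: str, history: str) -> "EncounterHistory":
        return cls(individual_id, tuple(int(c) for c in history.strip()))


@dataclass(frozen=True)
class Dataset:
    """Validated, collapsed capture events plus the design they belong to.

    ``events`` holds one row per individual x occasion after duplicate
    collapse, with columns ``individual_id``, ``species``, ``occasion`` and
    one column per trait.
    """

    design: StudyDesign
    events: pd.DataFrame

    @property
    def trait_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.events.columns if c not in ID_COLUMNS)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(sorted(self.events["individual_id"].unique()))

    @property
    def n_individuals(self) -> int:
        return self.events["individual_id"].nunique()

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.events["species"].unique()))

    def for_species(self, species: str) -> "Dataset":
        return Dataset(self.design, self.events[self.events["species"] == species].reset_index(drop=True))

    @classmethod
    def from_events(cls, design: StudyDesign, frame: pd.DataFrame) -> "Dataset":
        """Validate a long-format event frame and build a Dataset.

        Duplicate (individual, occasion) rows are collapsed to one detection
        with trait values averaged (missing values ignored in the mean).
        """
        frame = frame.copy()
        required = {"individual_id", "species", "occasion"}
        missing = required - set(frame.columns)
        if missing:
            raise CaptureDataError(f"missing required columns: {sorted(missing)}")
        frame["individual_id"] = frame["individual_id"].astype(str)
        frame["species"] = frame["species"].astype(str)

        trait_cols = [c for c in frame.columns if c not in ID_COLUMNS]
        for col in ("occasion", *trait_cols):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise CaptureDataError(
                    f"row {row}: non-numeric value {frame.loc[row, col]!r} in column {col!r}"
                )
            frame[col] = coerced
        frame["occasion"] = frame["occasion"].astype(int)

        bad_occ = ~frame["occasion"].between(1, design.n_occasions)
        if bad_occ.any():
            row = int(bad_occ.idxmax())
            raise CaptureDataError(
                f"row {row}: occasion {frame.loc[row, 'occasion']} outside design "
                f"(1..{design.n_occasions})"
            )
        bad_sp = ~frame["species"].isin(design.species_codes)
        if bad_sp.any():
            row = int(bad_sp.idxmax())
            raise CaptureDataError(
                f"row {row}: unknown species {frame.loc[row, 'species']!r}"
            )
        for col in trait_cols:
            values = frame[col]
            infinite = np.isinf(values.to_numpy(dtype=float, na_value=np.nan))
            if infinite.any():
                row = int(np.argmax(infinite))
                raise CaptureDataError(f"row {row}: non-finite value in column {col!r}")
            if _is_lightness(col):
                out = values.notna() & ~values.between(0.0, 100.0)
                if out.any():
                    row = int(out.idxmax())
                    raise CaptureDataError(
                        f"row {row}: lightness {col}={values[row]} outside [0, 100]"
                    )
            if col in ("svl", "weight"):
                bad = values.notna() & (values <= 0)
                if bad.any():
                    row = int(bad.idxmax())
                    raise CaptureDataError(f"row {row}: {col} must be positive")

        species_per_id = frame.groupby("individual_id")["species"].nunique()
        mixed = species_per_id[species_per_id > 1]
        if not mixed.empty:
            raise CaptureDataError(
                f"individual(s) {list(mixed.index)} recorded under multiple species"
            )

        dup = frame.duplicated(subset=["individual_id", "occasion"], keep=False)
        if dup.any():
            n_dup = int(dup.sum())
            logger.warning(
                "collapsing %d duplicate within-occasion rows (trait values averaged)",
                n_dup,
            )
            grouped = frame.groupby(["individual_id", "species", "occasion"], as_index=False)
            frame = grouped[trait_cols].mean() if trait_cols else grouped.size().drop(columns="size")

        if "date" in frame.columns:
            frame = frame.drop(columns=["date"])
        frame = frame.sort_values(["individual_id", "occasion"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        ordered = ["individual_id", "species", "occasion", *trait_cols]
        return cls(design, frame[ordered])


def read_captures(
    path: str | Path,
    design: StudyDesign,
    date_to_occasion: Mapping[str, int] | None = None,
) -> Dataset:
    """Read a long-format capture CSV and validate it against ``design``.

    The file must have a header with ``individual_id``, ``species`` and either
    an ``occasion`` column (1-based) or a ``date`` column mappable to occasions
    through ``date_to_occasion``.  Remaining columns are traits; empty cells
    are missing values, not errors.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if "occasion" not in frame.columns:
        if "date" not in frame.columns or date_to_occasion is None:
            raise CaptureDataError(
                f"{path}: need an 'occasion' column or a 'date' column plus a calendar"
            )
        unknown = ~frame["date"].astype(str).isin(date_to_occasion)
        if unknown.any():
            row = int(unknown.idxmax())
            raise CaptureDataError(f"row {row}: date {frame.loc[row, 'date']!r} not in calendar")
        frame["occasion"] = frame["date"].astype(str).map(date_to_occasion)
    return Dataset.from_events(design, frame)


def build_histories(ds: Dataset) -> list[EncounterHistory]:
    """Build one encounter history per individual, ordered by individual id."""
    T = ds.design.n_occasions
    out: list[EncounterHistory] = []
    for ind, grp in sorted(ds.events.groupby("individual_id"), key=lambda kv: kv[0]):
        det = [0] * T
        for occ in grp["occasion"]:
            det[int(occ) - 1] = 1
        out.append(EncounterHistory(str(ind), tuple(det)))
    return out


def write_histories(histories: Sequence[EncounterHistory], path: str | Path) -> None:
    """Write histories as CSV with a ``history`` string column."""
    frame = pd.DataFrame(
        {"individual_id": [h.individual_id for h in histories],
         "history": [h.history for h in histories]}
    )
    frame.to_csv(path, index=False)


def read_histories(path: str | Path) -> list[EncounterHistory]:
    frame = pd.read_csv(path, dtype=str)
    return [
        EncounterHistory.from_string(row.individual_id, row.history)
        for row in frame.itertuples()
    ]


@dataclass(frozen=True)
class DatasetSummary:
    """Bookkeeping counts for a dataset, overall and by species."""

    by_species: pd.DataFrame
    per_occasion: pd.DataFrame
    n_individuals: int
    n_events: int
    recapture_fraction: float


def summarize(ds: Dataset) -> DatasetSummary:
    """Count individuals, events, recapture fraction and per-occasion totals.

    The recapture fraction is the share of individuals detected on at least
    two occasions (0.0 for an empty dataset).
    """
    ev = ds.events
    if ev.empty:
        empty_sp = pd.DataFrame(
            columns=["n_individuals", "n_events", "recapture_fraction"]
        )
        occ = pd.DataFrame(0, index=pd.Index([], name="species"),
                           columns=list(range(1, ds.design.n_occasions + 1)))
        return DatasetSummary(empty_sp, occ, 0, 0, 0.0)

    rows = {}
    for sp, grp in ev.groupby("species"):
        counts = grp.groupby("individual_id")["occasion"].nunique()
        rows[sp] = {
            "n_individuals": int(counts.size),
            "n_events": int(len(grp)),
            "recapture_fraction": float((counts >= 2).mean()),
        }
    by_species = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_occasion = (
        ev.pivot_table(index="species", columns="occasion",
                       values="individual_id", aggfunc="count", fill_value=0)
        .reindex(columns=range(1, ds.design.n_occasions + 1), fill_value=0)
    )
    counts_all = ev.groupby("individual_id")["occasion"].nunique()
    return DatasetSummary(
        by_species,
        per_occasion,
        n_individuals=int(counts_all.size),
        n_events=int(len(ev)),
        recapture_fraction=float((counts_all >= 2).mean()),
    )
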