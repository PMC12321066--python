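"""End-to-end orchestration: data in, verdicts out.

A single run reads (or simulates) capture data, prepares trait covariates,
runs the CJS model scan per instance selector, partitions trait variance, and
classifies each trait into the four-cell contingency table, writing four
artifacts into the output directory:

* ``model_scan.csv`` — species, trait, selector, AICs, ΔAIC, β₁, SE, status
* ``variance_partition.csv`` — F, R², repeatability per species × trait
* ``verdicts.csv`` — the contingency cell and direction per species × trait
* ``summary.txt`` — a human-readable four-cell table plus provenance line

Configuration is a YAML or JSON mapping (see :func:`run`); all randomness
flows from a single seed, and identical configurations with identical seeds
produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capture_io import Dataset, StudyDesign, read_captures, summarize
from .cjs_core import SELECTORS, ModelComparison, scan_frame, scan_traits
from .selection_contingency import (
    ContingencyThresholds,
    SelectionVerdict,
    classify,
    verdict_summary,
)
from .synthetic_data import SimConfig, TraitSpec, preset, simulate
from .trait_prep import add_body_condition, size_adjust
from .variance_partition import (
    VariancePartitionError,
    anova_by_individual,
    partition_frame,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Base class; ``exit_code`` maps to the CLI process exit status."""

    exit_code = 1


class MissingInputError(PipelineError):
    exit_code = 2


class NoQualifyingTraitsError(PipelineError):
    exit_code = 3


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load a run configuration from a YAML/JSON file or pass a mapping through."""
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration for provenance lines."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def version_info(config: Mapping[str, Any] | None = None, seed: int | None = None) -> str:
    """Provenance string: package version, config hash, seed."""
    parts = [f"cmrselect {__version__}"]
    if config is not None:
        parts.append(f"config {config_hash(config)}")
    if seed is not None:
        parts.append(f"seed {seed}")
    return " | ".join(parts)


def _sim_config(block: Mapping[str, Any]) -> SimConfig:
    block = dict(block)
    selection = block.pop("selection", None)
    if "preset" in block:
        name = block.pop("preset")
        if "traits" in block:
            block["traits"] = tuple(TraitSpec(**t) for t in block["traits"])
        return preset(name, selection=selection, **block)
    if "traits" in block:
        block["traits"] = tuple(TraitSpec(**t) for t in block["traits"])
    cfg = SimConfig(**block)
    if selection:
        traits = tuple(
            dataclasses.replace(t, beta1=float(selection.get(t.name, t.beta1)))
            for t in cfg.traits
        )
        cfg = dataclasses.replace(cfg, traits=traits)
    return cfg


def _load_dataset(config: Mapping[str, Any], seed: int, out_dir: Path | None):
    if "simulate" in config:
        cfg = _sim_config(config["simulate"])
        sim = simulate(cfg, seed=seed)
        if out_dir is not None:
            sim.write(out_dir / "simulated")
        return sim.dataset
    if "input" in config:
        block = config["input"]
        path = Path(block["path"])
        if not path.exists():
            raise MissingInputError(f"capture file not found: {path}")
        design = StudyDesign(
            tuple((str(lab), float(t)) for lab, t in block["design"]["occasions"]),
            frozenset(block["design"]["species"]),
        )
        return read_captures(path, design, block.get("date_to_occasion"))
    raise MissingInputError("config needs a 'simulate' or 'input' section")


@dataclasses.dataclass
class RunResult:
    """Everything one pipeline run produced."""

    out_dir: Path | None
    scan: pd.DataFrame
    partition: pd.DataFrame
    verdicts: pd.DataFrame
    verdict_objects: list[SelectionVerdict]
    summary: str
    paths: dict[str, Path]


def run(
    config: str | Path | Mapping[str, Any],
    *,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    selectors: Sequence[str] | None = None,
    stages: Sequence[str] = ("scan", "partition", "classify"),
) -> RunResult:
    """Execute the full analysis described by ``config``.

    Recognized config keys: ``simulate`` (a preset name plus overrides) or
    ``input`` (CSV path plus design); ``traits`` (defaults to every trait
    column); ``adjust_svl`` (traits to residualize on SVL); ``condition``
    (add weight-on-SVL residuals); ``selectors``; ``thresholds``; ``seed``;
    ``out_dir``.  Command-line ``seed``/``out_dir``/``selectors`` arguments
    override the config.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or config.get("out_dir") or "cmrselect_out")
    out.mkdir(parents=True, exist_ok=True)
    selectors = tuple(selectors or config.get("selectors") or SELECTORS)

    ds = _load_dataset(config, seed, out)
    summary_counts = summarize(ds)
    logger.info(
        "dataset: %d individuals, %d events, recapture fraction %.3f",
        summary_counts.n_individuals, summary_counts.n_events,
        summary_counts.recapture_fraction,
    )

    svl_col = config.get("svl_col", "svl")
    weight_col = config.get("weight_col", "weight")
    if config.get("adjust_svl"):
        ds = size_adjust(ds, config["adjust_svl"], svl_col=svl_col)
    if config.get("condition"):
        ds = add_body_condition(
            ds, svl_col=svl_col, weight_col=weight_col,
            log_log=bool(config.get("condition_log_log", False)),
        )

    traits = list(config.get("traits") or [])
    if not traits:
        skip = {svl_col, weight_col} if config.get("adjust_svl") or config.get("condition") else set()
        traits = [
            t if not config.get("adjust_svl") or t not in config["adjust_svl"] else t + "_adj"
            for t in ds.trait_columns
            if t not in skip and not t.endswith("_adj")
        ]
        traits = list(dict.fromkeys(traits))
    unknown = [t for t in traits if t not in ds.trait_columns]
    if unknown:
        raise PipelineError(f"trait column(s) not found: {unknown}")
    if not traits:
        raise NoQualifyingTraitsError("no trait columns to analyze")

    th_block = config.get("thresholds", {})
    thresholds = ContingencyThresholds(
        f_high=float(th_block.get("f_high", 4.0)),
        r2_high=float(th_block.get("r2_high", 0.5)),
        require_all_negative=bool(th_block.get("require_all_negative", True)),
        strict_margin=float(th_block.get("strict_margin", 0.0)),
    )

    comparisons: list[ModelComparison] = []
    if "scan" in stages:
        comparisons = scan_traits(ds, traits, selectors=selectors)
    scan_df = scan_frame(comparisons)

    partitions = []
    if "partition" in stages:
        for sp in ds.species:
            events = ds.for_species(sp).events
            for trait in traits:
                try:
                    partitions.append(
                        anova_by_individual(
                            events.rename(columns={trait: "value"}),
                            trait_name=trait, species=sp,
                        )
                    )
                except VariancePartitionError as exc:
                    logger.warning("variance partition skipped: %s", exc)
    partition_df = partition_frame(partitions)

    verdicts: list[SelectionVerdict] = []
    if "classify" in stages and comparisons and partitions:
        if set(selectors) >= set(SELECTORS):
            vp_by_key = {(vp.species, vp.trait_name): vp for vp in partitions}
            for mc in comparisons:
                vp = vp_by_key.get((mc.species, mc.trait_name))
                if vp is None or not mc.complete:
                    logger.warning(
                        "no verdict for %s/%s (incomplete fits or no ANOVA)",
                        mc.species, mc.trait_name,
                    )
                    continue
                verdicts.append(classify(vp, mc, thresholds))
        else:
            logger.warning(
                "classification needs all three selectors; scan restricted to %s",
                selectors,
            )
    verdicts_df = verdicts_frame(verdicts)

    if scan_df.empty and partition_df.empty:
        raise NoQualifyingTraitsError("no trait could be analyzed")

    provenance = version_info(config, seed)
    summary_text = provenance + "\n\n" + verdict_summary(verdicts)
    paths = {
        "model_scan": out / "model_scan.csv",
        "variance_partition": out / "variance_partition.csv",
        "verdicts": out / "verdicts.csv",
        "summary": out / "summary.txt",
    }
    scan_df.to_csv(paths["model_scan"], index=False)
    partition_df.to_csv(paths["variance_partition"], index=False)
    verdicts_df.to_csv(paths["verdicts"], index=False)
    paths["summary"].write_text(summary_text + "\n")

    return RunResult(
        out_dir=out,
        scan=scan_df,
        partition=partition_df,
        verdicts=verdicts_df,
        verdict_objects=verdicts,
        summary=summary_text,
        paths=paths,
    )


def verdicts_frame(verdicts: Sequence[SelectionVerdict]) -> pd.DataFrame:
    """CSV-ready view of verdicts."""
    rows = []
    for v in verdicts:
        row = {"species": v.species, "trait": v.trait_name, "F": v.F, "R2": v.R2}
        for sel, d in zip(SELECTORS, v.dAIC):
            row[f"dAIC_{sel}"] = d
        row["cell"] = v.cell
        row["direction"] = v.direction
        rows.append(row)
    return pd.DataFrame(rows)


def classify_from_frames(
    scan_df: pd.DataFrame,
    partition_df: pd.DataFrame,
    thresholds: ContingencyThresholds = ContingencyThresholds(),
) -> pd.DataFrame:
    """Re-derive verdicts from previously written scan and partition CSVs."""
    from .cjs_core import SelectorResult
    from .variance_partition import VariancePartition

    verdicts = []
    for (sp, trait), grp in scan_df.groupby(["species", "trait"]):
        vp_rows = partition_df[
            (partition_df["species"] == sp) & (partition_df["trait"] == trait)
        ]
        if vp_rows.empty:
            continue
        mc = ModelComparison(sp, trait)
        for row in grp.itertuples():
            err = None if (pd.isna(row.error) or not row.error) else str(row.error)
            mc.results[row.selector] = SelectorResult(
                selector=row.selector, n=int(row.n), dAIC=float(row.dAIC),
                beta1=float(row.beta1), converged=bool(row.converged), error=err,
            )
        if not mc.complete:
            continue
        vp_row = vp_rows.iloc[0]
        vp = VariancePartition(
            trait_name=trait, species=sp, F=float(vp_row.F), R2=float(vp_row.R2),
            df_among=0, df_within=0,
            n_individuals=int(vp_row.n_individuals), n_events=int(vp_row.n_events),
            MS_among=float(vp_row.MS_among), MS_within=float(vp_row.MS_within),
            m0=2.0,
        )
        verdicts.append(classify(vp, mc, thresholds))
    return verdicts_frame(verdicts)
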