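"""End-to-end pipeline: ratios → founder estimates → group comparisons.

``run_report`` chains the full analysis on one input set and writes the
four summary tables (methylation summary, founder-cell estimates, fold
changes, plus the intermediate ratio table) together with a JSON manifest
recording inputs, parameters, seed and package version.  On any stage
failure, partial outputs are removed and the error re-raised, so an output
prefix is either complete or absent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .founder_estimation import founder_table
from .group_stats import fold_change_table, summarize_groups
from .io import read_table, write_table
from .ratio_core import compute_ratios
from .synthetic_data import CohortConfig, simulate_cohort
from .vocab import ScoreKind

__all__ = ["RunConfig", "run_simulate", "run_report"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Parameters shared by the pipeline stages."""

    out_prefix: Path
    intensity_path: Path | None = None
    ratio_path: Path | None = None
    ct_path: Path | None = None
    p_dmr: float = 0.1
    p_xi: float = 0.5
    ddof: int = 1
    fit_metric: str = "chi2_binned"
    n_min: int = 1
    n_max: int = 100
    seed: int = 0


def _write_manifest(prefix: Path, command: str, params: dict, outputs: list[Path]) -> Path:
    manifest = {
        "command": command,
        "package": "epifounder",
        "version": __version__,
        "parameters": params,
        "outputs": [p.name for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = prefix / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_simulate(config: CohortConfig, out_prefix) -> dict[str, Path]:
    """Generate a cohort and write its ratio and Ct tables plus a manifest."""
    prefix = Path(out_prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    ratios, cts = simulate_cohort(config)
    ratio_path = prefix / "ratios.csv"
    ct_path = prefix / "cts.csv"
    write_table(ratios, ratio_path)
    write_table(cts, ct_path)
    params = dataclasses.asdict(config)
    params["tissues"] = list(params["tissues"])
    _write_manifest(prefix, "simulate", params, [ratio_path, ct_path])
    return {"ratios": ratio_path, "cts": ct_path}


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run ratios → estimate → compare on one input set.

    Inputs: an intensity table (converted to ratios) or a precomputed ratio
    table, and optionally a Ct table for expression fold changes.  Outputs
    under ``config.out_prefix``: ``ratios.csv``, ``methylation_summary.csv``,
    ``founder_estimates.csv``, ``fold_changes.csv`` (when Ct data given) and
    ``manifest.json``.
    """
    if (config.intensity_path is None) == (config.ratio_path is None):
        raise ValueError("provide exactly one of intensity_path or ratio_path")
    prefix = Path(config.out_prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    try:
        if config.intensity_path is not None:
            intensities = read_table(config.intensity_path, "intensity")
            ratios = compute_ratios(intensities)
        else:
            ratios = read_table(config.ratio_path, "ratio")
        ratio_path = prefix / "ratios.csv"
        write_table(ratios, ratio_path)
        outputs.append(ratio_path)

        kinds = set(ratios["score_kind"])
        summaries = []
        for kind in (ScoreKind.MP, ScoreKind.PM):
            if kind.value in kinds:
                summaries.append(
                    summarize_groups(ratios, kind).assign(score_kind=kind.value)
                )
        summary_path = prefix / "methylation_summary.csv"
        write_table(
            pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame(),
            summary_path,
        )
        outputs.append(summary_path)

        assays = []
        if ScoreKind.XI.value in kinds:
            assays.append((ScoreKind.XI, config.p_xi))
        if ScoreKind.MP.value in kinds:
            assays.append((ScoreKind.MP, config.p_dmr))
        if ScoreKind.PM.value in kinds:
            assays.append((ScoreKind.PM, None))  # p from the group mean
        founders = founder_table(
            ratios, assays=assays, ddof=config.ddof,
            n_min=config.n_min, n_max=config.n_max, metric=config.fit_metric,
        )
        founder_path = prefix / "founder_estimates.csv"
        write_table(founders, founder_path)
        outputs.append(founder_path)

        if config.ct_path is not None:
            cts = read_table(config.ct_path, "ct")
            folds = fold_change_table(cts)
            fold_path = prefix / "fold_changes.csv"
            write_table(folds, fold_path)
            outputs.append(fold_path)

        params = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        }
        _write_manifest(prefix, "report", params, outputs)
    except Exception:
        for path in outputs:
            path.unlink(missing_ok=True)
        (prefix / "manifest.json").unlink(missing_ok=True)
        logger.error("report failed; partial outputs removed from %s", prefix)
        raise
    return {p.stem: p for p in outputs}
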