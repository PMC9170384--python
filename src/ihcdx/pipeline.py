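"""End-to-end orchestration: generate -> score -> filter -> compare ->
sweep -> model -> calibrate, with report tables mirroring the published
analysis and full provenance (config + package version) in a manifest.

A run is deterministic for a fixed seed: identical configuration produces
byte-identical output files.  Stages are failure-tolerant — an exception in
one stage is recorded in the report's error list and later stages that do
not depend on it still run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import sweep_table, threshold_sweep
from .group_stats import group_tests, summarize
from .hscore import filter_evaluable, write_samples
from .paired import paired_table, tabulate_pairs
from .risk import adjusted_odds_ratios, auroc, calibrate_quintiles, fit_logistic, predict_prob
from .synthetic import (
    CohortConfig,
    default_cohort_config,
    default_paired_config,
    generate_cohort,
    generate_paired_cohort,
)

#: Threshold grids swept by default: H-score cut points per marker and
#: probability cut points for the two-marker model.
DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "TGFBR1": (140, 150, 160, 170, 180, 190, 200),
    "TGFBR2": (115, 120, 125, 130, 135, 140, 145),
    "probability": (0.30, 0.35, 0.37, 0.39, 0.40, 0.45),
}


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    out_dir: str | Path
    seed: int = 0
    cohort: CohortConfig | None = None  # default: combined-analysis cohort
    thresholds: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    precision: int = 2

    def __post_init__(self) -> None:
        for key, grid in self.thresholds.items():
            grid = list(grid)
            if sorted(set(grid)) != grid:
                raise ValueError(f"thresholds for {key!r} must be ascending and unique")
        if self.cohort is not None:
            for group in self.cohort.groups.values():
                if group.n < 1:
                    raise ValueError("cohort groups must have n >= 1")


@dataclass
class RunReport:
    """Outcome of a run: output manifest, in-memory tables, log, errors."""

    out_dir: Path
    manifest: dict
    tables: dict
    log: list[str]
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def run(config: RunConfig) -> RunReport:
    """Execute the full workflow and write all report files to
    ``config.out_dir``.  See the module docstring for stage semantics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    errors: list[str] = []
    tables: dict = {}
    manifest: dict = {"version": __version__, "seed": config.seed, "files": {}}

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=index)
        manifest["files"][name] = name

    cohort_cfg = config.cohort or default_cohort_config(seed=config.seed)
    cohort_cfg.to_json(out / "cohort_config.json")
    manifest["files"]["cohort_config.json"] = "cohort_config.json"

    # --- generate and score -------------------------------------------------
    samples = generate_cohort(cohort_cfg)
    write_samples(samples, out / "samples.csv")
    manifest["files"]["samples.csv"] = "samples.csv"
    log.append(f"generated {len(samples)} sample records")

    evaluable = filter_evaluable(samples)
    log.append(f"evaluability filter: {len(samples)} in, {len(evaluable)} out")

    # --- group statistics ---------------------------------------------------
    try:
        summary = summarize(evaluable)
        tests = group_tests(evaluable)
        save("summary.csv", summary)
        save("group_tests.csv", tests)
        tables["summary"] = summary
        tables["group_tests"] = tests
        log.append(f"summarized {len(summary)} groups")
    except Exception as exc:  # pragma: no cover - failure tolerance
        errors.append(f"group_stats: {exc}")

    # --- matched pairs ------------------------------------------------------
    try:
        seed_pairs = np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31)
        comparisons = {}
        for marker in ("TGFBR1", "TGFBR2"):
            paired_cfg = default_paired_config(marker, seed=int(seed_pairs))
            paired_cfg.paired_rho = cohort_cfg.paired_rho
            pairs = generate_paired_cohort(paired_cfg)
            comparisons[marker] = tabulate_pairs(pairs)
        table1 = paired_table(comparisons)
        save("table1_paired.csv", table1, index=True)
        tables["paired"] = table1
        log.append("tabulated matched HCC/TAT pairs for both markers")
    except Exception as exc:
        errors.append(f"paired_compare: {exc}")

    # --- threshold sweeps per marker ---------------------------------------
    for marker, name in (("TGFBR1", "table2_tgfbr1_sweep.csv"), ("TGFBR2", "table3_tgfbr2_sweep.csv")):
        try:
            sub = evaluable.loc[
                (evaluable["marker"] == marker)
                & evaluable["region"].isin(["HCC", "CIRRHOSIS"])
            ].dropna(subset=["h_score"])
            results = threshold_sweep(
                sub["region"].to_numpy(),
                sub["h_score"].to_numpy(),
                config.thresholds[marker],
            )
            table = sweep_table(results, digits=config.precision)
            save(name, table, index=True)
            tables[f"sweep_{marker}"] = table
            log.append(f"swept {len(results)} {marker} thresholds over {len(sub)} samples")
        except Exception as exc:
            errors.append(f"diagnostics[{marker}]: {exc}")

    # --- two-marker model ---------------------------------------------------
    try:
        wide = (
            evaluable.dropna(subset=["h_score"])
            .pivot_table(index=["patient_id", "region"], columns="marker", values="h_score")
            .dropna(subset=["TGFBR1", "TGFBR2"])
            .reset_index()
        )
        event = (wide["region"] == "CIRRHOSIS").astype(int).to_numpy()
        model = fit_logistic(wide["TGFBR1"], wide["TGFBR2"], event)
        model.to_json(out / "model.json")
        manifest["files"]["model.json"] = "model.json"
        probs = predict_prob(model, wide["TGFBR1"], wide["TGFBR2"])
        labels = wide["region"].to_numpy()

        aors = adjusted_odds_ratios(model)
        save("odds_ratios.csv", aors)
        tables["odds_ratios"] = aors

        results = threshold_sweep(labels, probs, config.thresholds["probability"], mode="probability")
        table4 = sweep_table(results, digits=config.precision)
        save("table4_probability_sweep.csv", table4, index=True)
        tables["sweep_probability"] = table4

        calibration = calibrate_quintiles(probs, labels)
        save("calibration.csv", calibration.table)
        tables["calibration"] = calibration
        model_auroc = auroc(probs, labels)
        summary_json = {
            "auroc": model_auroc,
            "calibration_slope": calibration.slope,
            "calibration_intercept": calibration.intercept,
            "calibration_r_squared": calibration.r_squared,
            "model_converged": model.converged,
            "n_model_samples": int(len(wide)),
        }
        (out / "model_summary.json").write_text(json.dumps(summary_json, indent=2))
        manifest["files"]["model_summary.json"] = "model_summary.json"
        tables["model_summary"] = summary_json
        log.append(f"fit logistic model on {len(wide)} samples (AUROC {model_auroc:.3f})")
    except Exception as exc:
        errors.append(f"risk_model: {exc}")

    if errors:
        log.extend(f"ERROR {e}" for e in errors)
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    manifest["files"]["run_log.txt"] = "run_log.txt"
    manifest["errors"] = errors
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(out_dir=out, manifest=manifest, tables=tables, log=log, errors=errors)
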