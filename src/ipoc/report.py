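"""One-shot orchestration: validate -> compute -> stats, with a manifest.

``run_all`` executes the full consumer analysis from a single serializable
:class:`RunConfig` and writes a fixed report bundle into the output
directory:

    results.csv           per-sample H-Print / iPOC / classification
    exclusions.txt        ids of samples with no measurable HBIs
    species_summary.csv   species-binned box-plot statistics
    monthly_summary.csv   month-binned box-plot statistics
    model_comparison.csv  candidate models ranked by AIC
    sensitivity.csv       omitted-variable-bias statistics for the treatment
    manifest.json         config hash, package version, output checksums

Outputs are plain CSV/JSON and bitwise reproducible for identical config
and inputs.  Any stage failure raises :class:`PipelineError`; the CLI
turns that into a nonzero exit and a manifest flagging the partial run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from ipoc import __version__
from ipoc.foodweb_stats import (
    Encoding,
    _included_frame,
    compare_models,
    fit_ols,
    monthly_summary,
    proportion_above,
    sensitivity,
    species_summary,
)
from ipoc.hprint import Calibration, run_pipeline
from ipoc.sample_io import IOConfig, read_samples, write_results

DEFAULT_MODELS: tuple[tuple[str, ...], ...] = (
    ("month",),
    ("year",),
    ("latitude",),
    ("habitat",),
    ("month", "latitude", "habitat"),
    ("month", "latitude", "habitat", "month:habitat"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest flags the partial outputs."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Fully serializable configuration of one analysis run."""

    model_config = ConfigDict(frozen=True)

    samples_path: str
    out_dir: str
    io_delimiter: str = ","
    io_columns: dict[str, str] = {}
    calibration_intercept: float = 101.08
    calibration_slope: float = -1.02
    clamp: bool = True
    models: tuple[tuple[str, ...], ...] = DEFAULT_MODELS
    treatment: str = "habitat"
    alpha: float = 0.05
    whiskers: str = "tukey"
    threshold: float = 50.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": ["|".join(str(k) for k in s.group_key) for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "median": [s.median for s in summaries],
            "q1": [s.q1 for s in summaries],
            "q3": [s.q3 for s in summaries],
            "whisker_low": [s.whisker_low for s in summaries],
            "whisker_high": [s.whisker_high for s in summaries],
            "n_outliers": [len(s.outlier_values) for s in summaries],
        }
    )


def run_all(config: RunConfig) -> dict:
    """Run the full consumer analysis; return the manifest dict.

    Raises :class:`PipelineError` on any stage failure after writing a
    manifest that flags the partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ipoc",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
        "status": "running",
        "outputs": {},
        "counts": {},
    }

    def fail(stage: str, message: str) -> PipelineError:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        return PipelineError(stage, message)

    # -- validate ----------------------------------------------------------
    io_cfg = IOConfig(delimiter=config.io_delimiter, columns=config.io_columns)
    try:
        samples, row_errors = read_samples(config.samples_path, io_cfg)
    except Exception as exc:
        raise fail("validate", str(exc))
    if not samples:
        raise fail("validate", "no valid samples in input")
    manifest["counts"]["rows_valid"] = len(samples)
    manifest["counts"]["rows_invalid"] = len(row_errors)

    # -- compute -----------------------------------------------------------
    cal = Calibration(
        intercept=config.calibration_intercept,
        slope=config.calibration_slope,
        clamp=config.clamp,
    )
    results, excluded = run_pipeline(samples, cal)
    included = [r for r in results if r.included]
    if not included:
        raise fail("compute", "every sample was excluded (no measurable HBIs)")
    write_results(results, out / "results.csv", samples=samples)
    (out / "exclusions.txt").write_text(
        "".join(f"{sid}\n" for sid in excluded), encoding="utf-8"
    )
    manifest["counts"]["samples"] = len(results)
    manifest["counts"]["included"] = len(included)
    manifest["counts"]["excluded_no_hbis"] = len(excluded)

    # -- stats -------------------------------------------------------------
    try:
        sp = species_summary(results, samples, whiskers=config.whiskers)
        mo, n_no_month = monthly_summary(results, samples, whiskers=config.whiskers)
        count_above, prop_above = proportion_above(results, config.threshold)

        df = _included_frame(results, samples)
        model_df = df.dropna(subset=["month"]).reset_index(drop=True)
        fits = [fit_ols(model_df, formula) for formula in config.models]
        ranked = compare_models(fits)
        sens = sensitivity(
            ranked[0].fit, config.treatment, alpha=config.alpha
        )
    except Exception as exc:
        raise fail("stats", str(exc))

    _summaries_frame(sp).to_csv(
        out / "species_summary.csv", index=False, float_format="%.4f"
    )
    _summaries_frame(mo).to_csv(
        out / "monthly_summary.csv", index=False, float_format="%.4f"
    )
    pd.DataFrame(
        {
            "formula": ["+".join(r.fit.formula) for r in ranked],
            "n_params": [r.fit.n_params for r in ranked],
            "aic": [r.fit.aic for r in ranked],
            "delta_aic": [r.delta_aic for r in ranked],
            "log_likelihood": [r.fit.log_likelihood for r in ranked],
        }
    ).to_csv(out / "model_comparison.csv", index=False, float_format="%.4f")
    pd.DataFrame(
        [
            {
                "treatment": sens.treatment_term,
                "t_value": sens.t_value,
                "df_residual": sens.df_residual,
                "partial_r2_outcome": sens.partial_r2_outcome,
                "robustness_value": sens.robustness_value,
                "robustness_value_alpha": sens.robustness_value_alpha,
                "alpha": sens.alpha,
                "q": sens.q,
            }
        ]
    ).to_csv(out / "sensitivity.csv", index=False, float_format="%.6f")

    manifest["counts"]["no_month"] = n_no_month
    manifest["threshold"] = {
        "value": config.threshold,
        "count_above": count_above,
        "proportion_above": round(prop_above, 6),
    }
    manifest["best_model"] = "+".join(ranked[0].fit.formula)
    manifest["status"] = "ok"
    for name in (
        "results.csv",
        "exclusions.txt",
        "species_summary.csv",
        "monthly_summary.csv",
        "model_comparison.csv",
        "sensitivity.csv",
    ):
        manifest["outputs"][name] = _sha256(out / name)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
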