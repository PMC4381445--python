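"""End-to-end calibration workflow and report generation.

Stages, in order: load or simulate inputs -> average duplicate scans ->
preprocess (SNV, Savitzky-Golay first derivative, range reduction) ->
Kennard-Stone calibration/validation split on 2 PC scores -> base PLS fit ->
normalized-error outlier screen and refit -> leave-one-out cross-validation
and factor choice -> external validation -> report tables.

Two presets bundle the model settings:

* ``composition`` — one PLS-2 model for glucan/xylan/lignin/ash (wt% dry),
  predictors weighted 1/SD per wavenumber, responses unweighted, factor cap
  9; outliers screened on the averaged glucan/xylan/lignin error (cutoff
  1.5) with a separate ash screen.
* ``reactivity`` — PLS-1 models for the summed GX.Release / GX.Yield and
  PLS-2 models for the (G, X) release and yield pairs, responses weighted
  1/SD, factor caps 9/11/8; per-constituent screening at cutoff 2.0.

Every stage is deterministic given the seed; rerunning a configuration
reproduces each artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model_eval import loo_cv, select_factors, summary_stats, validate_external, _weights_for
from .outlier_screen import screen_and_refit
from .pls_core import fit_pls
from .preprocess import PreprocessChain
from .sample_selection import kennard_stone, pca_scores
from .spectra_io import (
    ConstituentTable,
    SpectraMatrix,
    SpectraError,
    average_duplicates,
    read_constituents_csv,
    read_spectra_csv,
    save_model,
    write_constituents_csv,
    write_spectra_csv,
)
from .synthetic_data import SimConfig, simulate_dataset

__all__ = ["WorkflowConfig", "ModelSpec", "Report", "run_calibration_workflow", "build_report"]

log = logging.getLogger("nirpls.workflow")

COMPOSITION_UNITS = {"glucan": "wt%_dry", "xylan": "wt%_dry",
                     "lignin": "wt%_dry", "ash": "wt%_dry"}
REACTIVITY_UNITS = {
    "G.Release": "g_per_g", "X.Release": "g_per_g", "GX.Release": "g_per_g",
    "G.Yield": "fraction", "X.Yield": "fraction", "GX.Yield": "fraction",
}


@dataclass
class ModelSpec:
    """One calibration model: its constituents and fitting options."""

    name: str
    constituents: list[str]
    model_type: str           # "pls1" or "pls2"
    max_factors: int
    factor_policy: str = "fixed"   # "fixed" (use max_factors) or "auto"
    x_weighting: str | None = "inv_sd"
    y_weighting: str | None = None
    screen_modes: tuple[str, ...] = ("reactivity",)


@dataclass
class WorkflowConfig:
    preset: str = "composition"
    seed: int = 0
    out_dir: str = "nirpls_run"
    n_samples: int = 279
    spectra_csv: str | None = None        # load instead of simulating
    constituents_csv: str | None = None
    snv: bool = True
    sg_window: int = 21
    sg_polyorder: int = 2
    sg_deriv: int = 1
    range_lo: float = 4000.0
    range_hi: float = 8998.0
    n_select: int = 245
    n_pc: int = 2
    outlier_rounds: int = 1
    outlier_cutoff: float | None = None   # None -> mode default (1.5 / 2.0)
    factor_policy: str = "fixed"
    max_factors_override: int | None = None
    noise_sd: float | None = None         # simulator override
    write_artifacts: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "WorkflowConfig":
        flat: dict = {}
        for key, value in raw.items():
            if key == "preprocess":
                flat.update({
                    "snv": value.get("snv", True),
                    "sg_window": value.get("window", 21),
                    "sg_polyorder": value.get("polyorder", 2),
                    "sg_deriv": value.get("deriv", 1),
                })
                if "range" in value:
                    flat["range_lo"], flat["range_hi"] = value["range"]
            elif key == "split":
                flat["n_select"] = value.get("n_select", 245)
                flat["n_pc"] = value.get("n_pc", 2)
            elif key == "outlier":
                flat["outlier_rounds"] = value.get("rounds", 1)
                flat["outlier_cutoff"] = value.get("cutoff")
            elif key == "model":
                flat["factor_policy"] = value.get("factor_policy", "fixed")
                flat["max_factors_override"] = value.get("max_factors")
            elif key == "simulate":
                flat["n_samples"] = value.get("n_samples", 279)
                flat["noise_sd"] = value.get("noise_sd")
            elif key == "inputs":
                flat["spectra_csv"] = value.get("spectra")
                flat["constituents_csv"] = value.get("constituents")
            else:
                flat[key] = value
        return cls(**flat)

    def to_dict(self) -> dict:
        """Scientific configuration only: output paths and IO flags excluded,
        so identical studies hash (and serialize) identically wherever they
        are written."""
        skip = {"out_dir", "write_artifacts"}
        return {k: getattr(self, k) for k in self.__dataclass_fields__ if k not in skip}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def model_specs(self) -> list[ModelSpec]:
        cap = self.max_factors_override
        if self.preset == "composition":
            return [ModelSpec(
                name="composition",
                constituents=["glucan", "xylan", "lignin", "ash"],
                model_type="pls2",
                max_factors=cap or 9,
                factor_policy=self.factor_policy,
                y_weighting=None,
                screen_modes=("composition", "ash"),
            )]
        if self.preset == "reactivity":
            return [
                ModelSpec("gx_release", ["GX.Release"], "pls1", cap or 9,
                          self.factor_policy, y_weighting=None,
                          screen_modes=("reactivity",)),
                ModelSpec("release_pair", ["G.Release", "X.Release"], "pls2",
                          cap or 11, self.factor_policy, y_weighting="inv_sd",
                          screen_modes=("reactivity",)),
                ModelSpec("gx_yield", ["GX.Yield"], "pls1", cap or 8,
                          self.factor_policy, y_weighting=None,
                          screen_modes=("reactivity",)),
                ModelSpec("yield_pair", ["G.Yield", "X.Yield"], "pls2",
                          cap or 8, self.factor_policy, y_weighting="inv_sd",
                          screen_modes=("reactivity",)),
            ]
        raise SpectraError(f"unknown preset {self.preset!r}")

    def units_map(self) -> dict[str, str]:
        return dict(COMPOSITION_UNITS if self.preset == "composition" else REACTIVITY_UNITS)


@dataclass
class Report:
    """Calibration and validation summary tables plus run metadata."""

    calibration_rows: list[dict] = field(default_factory=list)
    validation_rows: list[dict] = field(default_factory=list)
    removed_outliers: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    cv_results: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)


CAL_COLUMNS = ("Constituent", "Samples", "Factors", "RMSEC", "RMSECV",
               "R2", "Slope", "Intercept")
VAL_COLUMNS = ("Constituent", "Samples", "Factors", "RMSEP",
               "R2", "Slope", "Intercept")


def _decimals(unit: str) -> int:
    return 2 if unit == "wt%_dry" else 3


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def build_report(report: Report, out_dir: str | Path, units: dict[str, str]) -> dict[str, Path]:
    """Write the calibration/validation summary CSVs (fixed table schemas)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_table(rows: list[dict], columns: tuple[str, ...],
                    error_col: str, path: Path) -> None:
        lines = [",".join(columns)]
        for row in rows:
            unit = units.get(row["Constituent"], "wt%_dry")
            d = _decimals(unit)
            cells = []
            for col in columns:
                v = row[col]
                if col in ("Constituent",):
                    cells.append(str(v))
                elif col in ("Samples", "Factors"):
                    cells.append(str(int(v)))
                elif col in (error_col, "Intercept"):
                    cells.append(_fmt(v, d))
                else:  # R2, Slope, RMSECV share the error precision
                    cells.append(_fmt(v, d) if col == "RMSECV" else _fmt(v, 2))
            lines.append(",".join(cells))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    cal_path = out_dir / "calibration_report.csv"
    write_table(report.calibration_rows, CAL_COLUMNS, "RMSEC", cal_path)
    paths["calibration"] = cal_path
    if report.validation_rows:
        val_path = out_dir / "validation_report.csv"
        write_table(report.validation_rows, VAL_COLUMNS, "RMSEP", val_path)
        paths["validation"] = val_path
    else:
        log.info("validation table omitted: empty validation set")
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(report.metadata, indent=1, sort_keys=True),
                         encoding="utf-8")
    paths["metadata"] = meta_path
    return paths


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _stage(name: str, **info) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_calibration_workflow(config: WorkflowConfig) -> Report:
    """Execute the full calibration study and return (and write) the report."""
    out_dir = Path(config.out_dir)
    if config.write_artifacts:
        out_dir.mkdir(parents=True, exist_ok=True)
    units = config.units_map()

    # -- inputs -------------------------------------------------------------
    if config.spectra_csv is not None:
        spectra = read_spectra_csv(config.spectra_csv)
        constituents = read_constituents_csv(config.constituents_csv, units)
        _stage("load", spectra=config.spectra_csv, n_rows=spectra.n_samples)
    else:
        sim_kwargs = dict(n_samples=config.n_samples, seed=config.seed)
        if config.noise_sd is not None:
            sim_kwargs["noise_sd"] = config.noise_sd
        sim = SimConfig(**sim_kwargs)
        spectra, composition, reactivity = simulate_dataset(sim)
        constituents = composition if config.preset == "composition" else reactivity
        if config.write_artifacts:
            inputs = out_dir / "inputs"
            inputs.mkdir(exist_ok=True)
            write_spectra_csv(spectra, inputs / "spectra.csv")
            write_constituents_csv(composition, inputs / "composition.csv")
            write_constituents_csv(reactivity, inputs / "reactivity.csv")
        _stage("simulate", n_samples=config.n_samples, seed=config.seed)

    spectra = average_duplicates(spectra)
    _stage("average_duplicates", n_samples=spectra.n_samples)

    # -- preprocessing ------------------------------------------------------
    chain = PreprocessChain(
        snv=config.snv, sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder, sg_deriv=config.sg_deriv,
        range_lo=config.range_lo, range_hi=config.range_hi,
        weight_columns=False,  # 1/SD weights are recomputed per fit/fold
    )
    pre = chain.apply_steps(spectra)
    _stage("preprocess", n_wavenumbers=pre.wavenumbers.size)

    # -- calibration / validation split -------------------------------------
    scores = pca_scores(pre.absorbance, n_pc=config.n_pc)
    split = kennard_stone(scores, config.n_select, sample_ids=pre.sample_ids)
    if config.write_artifacts:
        lines = ["sample_id,role"]
        lines += [f"{s},calibration" for s in split.calibration_ids]
        lines += [f"{s},validation" for s in split.validation_ids]
        (out_dir / "split.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    _stage("split", n_calibration=len(split.calibration_ids),
           n_validation=len(split.validation_ids))

    report = Report(metadata={
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "nirpls_version": __version__,
        "n_calibration": len(split.calibration_ids),
        "n_validation": len(split.validation_ids),
    })

    available = set(constituents.sample_ids)
    cal_ids = [s for s in split.calibration_ids if s in available]
    val_ids = [s for s in split.validation_ids if s in available]
    pre_cal = pre.select_samples(cal_ids)
    pre_val = pre.select_samples(val_ids) if val_ids else None

    assessment_lines = ["model,sample_id,constituent,y_ref,y_pred,rmsec,error,flagged"]
    for spec in config.model_specs():
        Y_cal = constituents.select_samples(cal_ids).subset(spec.constituents)
        # -- outlier screen on the base model -------------------------------
        kept_ids, _, assessments = screen_and_refit(
            pre_cal.absorbance, Y_cal.values, cal_ids, spec.constituents,
            n_factors=spec.max_factors,
            mode=spec.screen_modes, cutoff=config.outlier_cutoff,
            max_rounds=config.outlier_rounds,
            x_weighting=spec.x_weighting, y_weighting=spec.y_weighting,
        )
        removed = [s for s in cal_ids if s not in set(kept_ids)]
        report.removed_outliers.extend(f"{spec.name}:{s}" for s in removed)
        for a in assessments:
            for cname in a.normalized_errors:
                assessment_lines.append(
                    f"{spec.name},{a.sample_id},{cname},{a.y_ref[cname]:.6g},"
                    f"{a.y_pred[cname]:.6g},{a.rmsec[cname]:.6g},"
                    f"{a.normalized_errors[cname]:.6g},{a.flagged}"
                )
        _stage("outlier_screen", model=spec.name, removed=len(removed))

        X_clean = pre_cal.select_samples(kept_ids).absorbance
        Y_clean = Y_cal.select_samples(kept_ids).values

        # -- cross-validation and factor choice -----------------------------
        cv = loo_cv(
            X_clean, Y_clean, spec.max_factors,
            x_weighting=spec.x_weighting, y_weighting=spec.y_weighting,
            constituent_names=spec.constituents,
        )
        n_factors = (spec.max_factors if spec.factor_policy == "fixed"
                     else select_factors(cv))
        report.cv_results[spec.name] = cv
        _stage("crossval", model=spec.name, factors=n_factors)

        # -- final model -----------------------------------------------------
        model = fit_pls(
            X_clean, Y_clean, n_factors,
            x_weights=_weights_for(X_clean, spec.x_weighting),
            y_weights=_weights_for(Y_clean, spec.y_weighting),
            calibration_ids=list(kept_ids),
            preprocess_provenance=chain.describe(),
        )
        report.models[spec.name] = model
        if config.write_artifacts:
            save_model(model, out_dir / f"model_{spec.name}.json")

        f_idx = n_factors
        for j, cname in enumerate(spec.constituents):
            cv_stats = summary_stats(
                Y_clean[:, j], cv.loo_predictions[:, j, f_idx], n_factors=n_factors
            )
            report.calibration_rows.append({
                "Constituent": cname,
                "Samples": len(kept_ids),
                "Factors": n_factors,
                "RMSEC": float(cv.rmsec[f_idx, j]),
                "RMSECV": float(cv.rmsecv[f_idx, j]),
                "R2": cv_stats.r2,
                "Slope": cv_stats.slope,
                "Intercept": cv_stats.intercept,
            })

        # -- external validation ---------------------------------------------
        if val_ids:
            Y_val = constituents.select_samples(val_ids).subset(spec.constituents)
            val_stats = validate_external(
                model, pre_val.absorbance, Y_val.values,
                validation_ids=val_ids, constituent_names=spec.constituents,
            )
            for cname in spec.constituents:
                s = val_stats[cname]
                report.validation_rows.append({
                    "Constituent": cname,
                    "Samples": s.n_samples,
                    "Factors": n_factors,
                    "RMSEP": s.rmse,
                    "R2": s.r2,
                    "Slope": s.slope,
                    "Intercept": s.intercept,
                })
            _stage("validate", model=spec.name, n=len(val_ids))

    if config.write_artifacts:
        (out_dir / "outlier_assessments.csv").write_text(
            "\n".join(assessment_lines) + "\n", encoding="utf-8")
        paths = build_report(report, out_dir, units)
        report.metadata["artifact_hashes"] = {
            name: _file_hash(p) for name, p in sorted(paths.items()) if name != "metadata"
        }
        # rewrite metadata with the artifact hashes included
        paths["metadata"].write_text(
            json.dumps(report.metadata, indent=1, sort_keys=True), encoding="utf-8")
    return report
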