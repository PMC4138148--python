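"""End-to-end orchestration: load or simulate -> describe -> encode ->
CV-tuned group-Lasso fit -> unpenalized reference fit -> stability.

A single :class:`PipelineConfig` pins every under-specified constant
(grids, folds, seeds, sample sizes) so a run is fully reproducible; the
report records the configuration alongside the results.  The penalized and
unpenalized estimates are reported side by side.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codebook import Codebook, default_codebook
from .descriptive import (
    adjusted_area_comparison,
    bll_summary_table,
    chi_square_test,
    compare_log_bll,
    crosstab,
    mann_whitney_by_sex,
    proportion_elevated,
)
from .encode import EncodingError, encode_dummies
from .grouplasso import SeparationError, fit_logistic_mle
from .io import read_survey_csv, write_survey_csv
from .model_selection import fit_cv_tuned
from .simulate import SimulationConfig, SurveyDataset, generate_survey
from .stability import bootstrap_stability, permutation_stability


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run depends on.  Exactly one of ``input_csv`` /
    ``simulation`` must be set."""

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    codebook: Codebook = field(default_factory=default_codebook)
    bll_threshold: float = 10.0
    model_area: str | None = "exposed"  # risk-factor model restricted to this area
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001
    cv_seed: int = 0
    stability_sample_sizes: tuple = (150, 200, 250)
    stability_replicates: int = 100
    stability_seed: int = 0
    run_stability: bool = True
    run_reference_mle: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_csv / simulation")
        if not self.bll_threshold > 0:
            raise ValueError("bll_threshold must be positive")


@dataclass
class AnalysisReport:
    config_hash: str
    descriptive: dict
    cv: dict
    selected_groups: list
    penalized_coefficients: dict
    reference_mle: dict | None
    stability: list
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "descriptive": self.descriptive,
                "cv": self.cv,
                "selected_groups": self.selected_groups,
                "penalized_coefficients": self.penalized_coefficients,
                "reference_mle": self.reference_mle,
                "stability": self.stability,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Codebook):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.ndarray, tuple)):
            return list(o)
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_or_simulate(config: PipelineConfig) -> SurveyDataset:
    if config.simulation is not None:
        return generate_survey(config.simulation)
    return read_survey_csv(config.input_csv, config.codebook)


def describe(dataset: SurveyDataset, threshold: float) -> dict:
    """Characteristic-vs-stratum and area-comparison descriptive battery."""
    out: dict = {}
    out["proportions_by_area"] = proportion_elevated(
        dataset, ["area"], threshold
    ).to_dict(orient="records")
    out["bll_summary"] = bll_summary_table(dataset, threshold).to_dict(orient="records")
    tests = {}
    for entry in dataset.codebook:
        if entry.kind == "continuous":
            continue
        tab = crosstab(dataset, entry.name, threshold)
        if (tab.counts.sum(axis=1) == 0).any() or (tab.counts.sum(axis=0) == 0).any():
            continue  # empty category or single-class outcome; chi-square undefined
        tests[entry.name] = chi_square_test(tab).to_dict()
    out["stratum_chi_square"] = tests
    if dataset.data["area"].nunique() == 2:
        out["log_bll_t_test"] = compare_log_bll(dataset, "area").to_dict()
        out["ancova_area"] = adjusted_area_comparison(dataset).to_dict()
    mwu = {}
    for area in sorted(dataset.data["area"].dropna().unique()):
        mwu[area] = mann_whitney_by_sex(dataset, within_area=area).to_dict()
    out["mann_whitney_sex"] = mwu
    return out


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages; artifacts under ``config.output_dir`` if set."""
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def save_df(df: pd.DataFrame, name: str) -> None:
        if outdir is not None:
            df.to_csv(outdir / name, index=False)

    try:
        dataset = load_or_simulate(config)
    except Exception as e:
        raise PipelineError("load", str(e)) from e
    if outdir and config.simulation is not None:
        write_survey_csv(dataset, outdir / "survey.csv")

    try:
        descriptive = describe(dataset, config.bll_threshold)
    except Exception as e:
        raise PipelineError("describe", str(e)) from e

    model_data = dataset
    if config.model_area and dataset.data["area"].nunique() > 1:
        model_data = dataset.subset(dataset.data["area"] == config.model_area)

    try:
        encoded = encode_dummies(
            model_data, config.codebook, config.bll_threshold, drop_constant_columns=True
        )
        if encoded.y.min() == encoded.y.max():
            raise EncodingError("outcome has a single class at this threshold")
    except Exception as e:
        raise PipelineError("encode", str(e)) from e

    try:
        cv, fit, path = fit_cv_tuned(
            encoded,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            k=config.cv_folds,
            seed=config.cv_seed,
        )
    except Exception as e:
        raise PipelineError("fit", str(e)) from e
    save_df(cv.curve_table(), "cv_deviance.csv")
    save_df(path.group_norm_table(), "coefficient_path.csv")

    reference = None
    if config.run_reference_mle:
        try:
            mle = fit_logistic_mle(encoded)
            reference = {
                "table": mle.summary_table().to_dict(orient="records"),
                "intercept": mle.intercept,
            }
            if outdir:
                save_df(mle.summary_table(), "reference_mle.csv")
        except SeparationError as e:
            reference = {"error": str(e)}

    stability_out: list = []
    if config.run_stability:
        try:
            tables = []
            for n_s in config.stability_sample_sizes:
                for fn in (bootstrap_stability, permutation_stability):
                    res = fn(
                        model_data,
                        n_s,
                        replicates=config.stability_replicates,
                        seed=config.stability_seed,
                        k=config.cv_folds,
                    )
                    stability_out.append(res.to_dict())
                    tables.append(res.table())
            if outdir:
                save_df(pd.concat(tables, ignore_index=True), "stability_frequencies.csv")
        except Exception as e:
            raise PipelineError("stability", str(e)) from e

    coefs = dict(zip(fit.column_names, map(float, fit.coef)))
    selected = sorted(fit.active_groups)
    report = AnalysisReport(
        config_hash=_config_hash(config),
        descriptive=descriptive,
        cv={
            "selected_lambda": cv.selected_lambda,
            "selected_deviance": cv.selected_deviance,
            "n_folds": cv.n_folds,
            "seed": cv.seed,
            "n_lambda": len(cv.lambdas),
        },
        selected_groups=selected,
        penalized_coefficients={
            "intercept": fit.intercept,
            "coefficients": coefs,
            "odds_ratios": {k: float(np.exp(v)) for k, v in coefs.items()},
        },
        reference_mle=reference,
        stability=stability_out,
        provenance={
            "package_version": __version__,
            "cv_seed": config.cv_seed,
            "stability_seed": config.stability_seed,
            "simulation_seed": (
                config.simulation.seed if config.simulation is not None else None
            ),
            "n_model_records": int(encoded.n),
            "n_design_columns": int(encoded.p),
            "n_groups": int(encoded.n_groups),
        },
    )
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report
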