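"""End-to-end pipeline orchestration.

Runs rainfall indices → hormone prep → reaction-norm model → survival
models (plus the mortality model when a year table is supplied) from
either user-supplied delimited files or a synthetic-data configuration,
and writes all summary tables, a diagnostics report and a manifest
(config, seed, SHA-256 of every output) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hormones, rainfall, simulate
from .glucocorticoids import ReactionNormModel, ThreeWayGCModel
from .mcmc import McmcSettings
from .mortality import MortalityModel, aicc_compare
from .survival import BlupSurvivalModel

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """One pipeline run: input source, reference years, MCMC profile, output.

    Exactly one of ``input_dir`` (existing delimited files named
    rainfall.csv / samples.csv / females.csv and optionally
    mortality.csv) or ``synthetic`` (a :class:`simulate.SimulationConfig`
    or dict of its fields) must be given.
    """

    output_dir: str | Path = "pipeline_out"
    input_dir: str | Path | None = None
    synthetic: object | None = None
    seed: int | None = None
    index_reference_years: tuple = tuple(range(1996, 2014))
    expected_reference_years: tuple = tuple(range(1997, 2014))
    study_window: tuple = ("2008-01-01", "2013-12-31")
    mcmc_profile: str = "full"  # "full" (4×4000) or "test" (2×600)
    rain_value: float = 1.0  # expected rainfall at which BLUPs are evaluated

    def __post_init__(self):
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("specify exactly one of input_dir or synthetic")
        if self.synthetic is not None:
            if isinstance(self.synthetic, dict):
                self.synthetic = simulate.SimulationConfig(**self.synthetic)
            if self.seed is None:
                raise ValueError("synthetic runs require a seed")
            self.synthetic.seed = self.seed
        if self.mcmc_profile not in ("full", "test"):
            raise ValueError("mcmc_profile must be 'full' or 'test'")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def settings(self, offset: int = 0) -> McmcSettings:
        seed = None if self.seed is None else int(self.seed) + offset
        if self.mcmc_profile == "test":
            return McmcSettings.test_profile(seed=seed)
        return McmcSettings(seed=seed)


def make_fixtures(config: RunConfig) -> dict:
    """Write the four synthetic input tables for a synthetic run."""
    if config.synthetic is None:
        raise PipelineError("fixtures", "make_fixtures requires a synthetic config")
    outdir = Path(config.output_dir) / "inputs"
    return simulate.write_fixtures(config.synthetic, outdir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a results bundle.

    The bundle maps stage names to in-memory results (tables, fitted
    results objects) and ``paths`` to everything written.  Any stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    completed stages remain on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    timings: dict[str, float] = {}
    bundle: dict = {"paths": written}

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with _stage("inputs"):
        if config.synthetic is not None:
            paths = make_fixtures(config)
        else:
            indir = Path(config.input_dir)
            paths = {k: indir / f"{k}.csv" for k in ("rainfall", "samples", "females")}
            mort = indir / "mortality.csv"
            if mort.exists():
                paths["mortality"] = mort
            for key in ("rainfall", "samples", "females"):
                if not paths[key].exists():
                    raise FileNotFoundError(f"missing input file {paths[key]}")
        rain = rainfall.read_rainfall(paths["rainfall"])
        samples = hormones.read_samples(paths["samples"])
        females = hormones.read_females(paths["females"])

    with _stage("rainfall_indices"):
        filled = rainfall.fill_missing(rain)
        clim = rainfall.build_climatology(
            filled,
            reference_years=config.index_reference_years,
            expected_reference_years=config.expected_reference_years,
        )
        index_table = rainfall.build_index_table(filled, clim)
        rainfall.write_index_table(index_table, outdir / "drought_indices.csv")
        written["drought_indices"] = outdir / "drought_indices.csv"
        bundle["index_table"] = index_table

    with _stage("hormone_prep"):
        selected = pd.concat(
            [
                hormones.select_samples(g, study_window=config.study_window)
                for _, g in samples.groupby("female_id", sort=True)
            ],
            ignore_index=True,
        )
        retained, removal_log = hormones.remove_outliers(selected)
        frame = hormones.build_model_frame(retained, females, index_table)
        frame.to_csv(outdir / "model_frame.csv", index=False)
        removal_log.to_csv(outdir / "removal_log.csv", index=False)
        written["model_frame"] = outdir / "model_frame.csv"
        written["removal_log"] = outdir / "removal_log.csv"
        bundle["model_frame"] = frame
        bundle["removal_log"] = removal_log

    with _stage("reaction_norm_model"):
        gc_model = ReactionNormModel(frame)
        gc_fit = gc_model.fit(config.settings(offset=1))
        norms = gc_fit.reaction_norms(rain_value=config.rain_value)
        gc_fit.summary().to_csv(outdir / "gc_model_summary.csv")
        norms.to_csv(outdir / "reaction_norms.csv", index=False)
        written["gc_model_summary"] = outdir / "gc_model_summary.csv"
        written["reaction_norms"] = outdir / "reaction_norms.csv"
        bundle["gc_fit"] = gc_fit
        bundle["reaction_norms"] = norms

    with _stage("survival_models"):
        surv_model = BlupSurvivalModel(norms, females)
        surv_fit = surv_model.fit(config.settings(offset=2))
        surv_fit.summary().to_csv(outdir / "survival_model_summary.csv")
        written["survival_model_summary"] = outdir / "survival_model_summary.csv"
        bundle["survival_fit"] = surv_fit

        three_model = ThreeWayGCModel(frame)
        three_fit = three_model.fit(config.settings(offset=3))
        three_fit.summary().to_csv(outdir / "three_way_summary.csv")
        written["three_way_summary"] = outdir / "three_way_summary.csv"
        bundle["three_way_fit"] = three_fit

        grid = []
        for dd in (-1.0, 0.0, 1.0):
            for rr in (-1.0, 0.0, 1.0, 2.0):
                c = three_fit.gc_contrast(dd, rr)
                grid.append(
                    {
                        "drought_risk": dd,
                        "expected_rainfall": rr,
                        "delta_log_gc": c["delta_log_gc"],
                        "delta_lo": c["delta_ci"][0],
                        "delta_hi": c["delta_ci"][1],
                        "percent": c["percent"],
                    }
                )
        pd.DataFrame(grid).to_csv(outdir / "contrast_grid.csv", index=False)
        written["contrast_grid"] = outdir / "contrast_grid.csv"

    if "mortality" in paths:
        with _stage("mortality_model"):
            mort_model = MortalityModel.from_csv(paths["mortality"])
            mort_fit = mort_model.fit()
            null_fit = mort_model.fit_null()
            summary = mort_fit.summary()
            summary.to_csv(outdir / "mortality_summary.csv")
            mort_fit.predicted_rate_table().to_csv(
                outdir / "mortality_rates.csv", index=False
            )
            written["mortality_summary"] = outdir / "mortality_summary.csv"
            written["mortality_rates"] = outdir / "mortality_rates.csv"
            bundle["mortality_fit"] = mort_fit
            bundle["mortality_delta_aicc"] = aicc_compare(mort_fit, null_fit)

    with _stage("diagnostics"):
        rows = []
        for label in ("gc_fit", "survival_fit", "three_way_fit"):
            rep = bundle[label].diagnostics()
            rows.append(
                {
                    "model": label,
                    "overall_pass": rep.attrs["overall_pass"],
                    "max_rhat": float(rep["rhat"].max()),
                    "min_ess_bulk": float(rep["ess_bulk"].min()),
                }
            )
        diag = pd.DataFrame(rows)
        diag.to_csv(outdir / "diagnostics.csv", index=False)
        written["diagnostics"] = outdir / "diagnostics.csv"
        bundle["diagnostics"] = diag

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "mcmc_profile": config.mcmc_profile,
            "study_window": list(config.study_window),
            "index_reference_years": list(config.index_reference_years),
            "expected_reference_years": list(config.expected_reference_years),
            "synthetic_config": (
                config.synthetic.to_dict() if config.synthetic is not None else None
            ),
            "stage_timings_s": timings,
            "outputs_sha256": {k: _sha256(p) for k, p in written.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        bundle["manifest"] = manifest
    return bundle
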