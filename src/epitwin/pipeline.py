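"""Pipeline orchestration: simulate -> accelerate -> describe -> fit -> power.

A :class:`PipelineConfig` (loadable from YAML/JSON) drives the stages; every
intermediate artifact is written as flat TSV or JSON so runs are diff-able,
and a :class:`RunManifest` records the config hash, per-stage outputs, row
counts after each filter, and warnings.  Re-running with the same config and
seed reproduces byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acceleration, biometric, cohort, descriptives, power

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed for a reproducible run.

    ``source`` is either 'synthetic' (design/params drawn from the config) or
    a path to an external long-format twin table.  Sensitivity toggles mirror
    the standard robustness checks: dropping individual covariates from the
    residualization and refitting on the first measurement occasion only.
    """

    seed: int
    source: str = "synthetic"
    out_dir: str = "epitwin_run"
    clocks: tuple = ("synthetic",)
    design: dict = None
    params: dict = None
    emit_epigenetic_age: bool = True
    covariates: dict = None        # per-clock CovariateSpec overrides
    stages: tuple = ("simulate", "accelerate", "describe", "fit_univariate")
    drop_sex: bool = False
    drop_smoking: bool = False
    drop_cell_pc: bool = False
    first_occasion_only: bool = False
    mode: str = "auto"
    moderation_ages: tuple = (9.5, 12, 15.5, 18, 21.5, 24, 27.5, 30)
    power_scenarios: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def hash(self) -> str:
        # out_dir does not affect results, only where they land
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    for k in ("clocks", "stages", "moderation_ages", "power_scenarios"):
        if k in raw and isinstance(raw[k], list):
            raw[k] = tuple(raw[k])
    return PipelineConfig(**raw)


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    version: str
    completed_stages: list = dataclasses.field(default_factory=list)
    timings: dict = dataclasses.field(default_factory=dict)
    outputs: dict = dataclasses.field(default_factory=dict)
    row_counts: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)
    failed_stage: str = None
    error: str = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _covariate_spec(config: PipelineConfig, clock: str) -> acceleration.CovariateSpec:
    if config.covariates and clock in config.covariates:
        spec = acceleration.CovariateSpec(clock=clock, **config.covariates[clock])
    else:
        spec = acceleration.default_spec(clock)
    return dataclasses.replace(
        spec,
        include_sex=spec.include_sex and not config.drop_sex,
        include_smoking_beta=spec.include_smoking_beta and not config.drop_smoking,
        include_cell_pc=spec.include_cell_pc and not config.drop_cell_pc,
    )


def _fit_to_dict(fit: biometric.FitResult) -> dict:
    return {
        "label": fit.label,
        "mode": fit.spec.mode,
        "params": {k: float(v) for k, v in fit.params.items()},
        "minus2LL": fit.minus2ll,
        "n_params": fit.n_params,
        "AIC": fit.aic,
        "converged": fit.converged,
        "n_mz": fit.n_mz,
        "n_dz": fit.n_dz,
        "components": fit.components,
        "shares": fit.shares,
        "correlations": fit.correlations,
    }


def _cmp_to_dict(cmp: biometric.ComparisonResult) -> dict:
    return dataclasses.asdict(cmp)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order, persisting artifacts.

    A stage failure halts the run; the manifest records the completed stages
    and the error.  Outputs per stage:

    * simulate — ``twins.tsv`` (long-format table)
    * accelerate — ``acceleration.tsv`` (residualized scores)
    * describe — ``twin_correlations.tsv``, ``stability.tsv``
    * fit_univariate — ``univariate_<clock>.json`` (ladder + selected fit)
    * fit_bivariate — ``bivariate_<clock>.json`` (+ equality-over-time tests)
    * fit_moderation — ``moderation_<clock>.json``, components-by-age TSV
    * power — ``power.json``
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), version="0.1.0")
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    table = None
    acc_frames = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "simulate":
                design = (
                    cohort.design_from_dict(config.design)
                    if config.design
                    else cohort.TWINLIFE_DESIGN
                )
                params = cohort.params_from_dict(config.params or {})
                frames = [
                    cohort.generate_cohort(
                        design,
                        params,
                        seed=config.seed + i,
                        clock=clk,
                        emit_epigenetic_age=config.emit_epigenetic_age,
                    )
                    for i, clk in enumerate(config.clocks)
                ]
                table = pd.concat(frames, ignore_index=True)
                path = out / "twins.tsv"
                cohort.write_table(table, path)
                manifest.outputs[stage] = [str(path)]
                manifest.row_counts[stage] = len(table)

            elif stage == "load":
                table = cohort.read_table(config.source)
                manifest.outputs[stage] = [config.source]
                manifest.row_counts[stage] = len(table)

            elif stage == "accelerate":
                if table is None:
                    raise RuntimeError("no input table: run simulate/load first")
                paths = []
                for clk in config.clocks:
                    if clk not in set(table["clock"]):
                        raise ValueError(f"clock column has no rows for {clk!r}")
                    spec = _covariate_spec(config, clk)
                    acc_frames[clk] = acceleration.residualize(table, spec)
                acc = pd.concat(acc_frames.values(), ignore_index=True)
                path = out / "acceleration.tsv"
                acc.to_csv(path, sep="\t", index=False)
                paths.append(str(path))
                manifest.outputs[stage] = paths
                manifest.row_counts[stage] = len(acc)

            elif stage == "describe":
                rows, stab = [], []
                for clk, acc in acc_frames.items():
                    tc = descriptives.twin_correlation(acc)
                    tc.insert(0, "clock", clk)
                    rows.append(tc)
                    st = descriptives.rank_order_stability(acc)
                    st.insert(0, "clock", clk)
                    stab.append(st)
                corr_path = out / "twin_correlations.tsv"
                stab_path = out / "stability.tsv"
                pd.concat(rows, ignore_index=True).to_csv(
                    corr_path, sep="\t", index=False
                )
                pd.concat(stab, ignore_index=True).to_csv(
                    stab_path, sep="\t", index=False
                )
                manifest.outputs[stage] = [str(corr_path), str(stab_path)]

            elif stage == "fit_univariate":
                paths = []
                for clk, acc in acc_frames.items():
                    data = biometric.make_univariate_groups(
                        acc, first_occasion_only=config.first_occasion_only
                    )
                    comparisons, selected, fits = biometric.model_ladder_univariate(
                        data, mode=config.mode, seed=config.seed
                    )
                    payload = {
                        "clock": clk,
                        "n_units": data.n_mz + data.n_dz,
                        "comparisons": [_cmp_to_dict(c) for c in comparisons],
                        "fits": [_fit_to_dict(f) for f in fits],
                        "selected": _fit_to_dict(selected),
                    }
                    path = out / f"univariate_{clk}.json"
                    path.write_text(json.dumps(payload, indent=2))
                    paths.append(str(path))
                    manifest.row_counts[f"{stage}:{clk}"] = data.n_mz + data.n_dz
                manifest.outputs[stage] = paths

            elif stage == "fit_bivariate":
                paths = []
                for clk, acc in acc_frames.items():
                    data = biometric.make_bivariate_groups(acc)
                    mode = (
                        biometric.choose_mode(data)
                        if config.mode == "auto"
                        else config.mode
                    )
                    spec = biometric.ModelSpec(mode=mode, design="bivariate")
                    fit = biometric.fit_model(data, spec, seed=config.seed)
                    eq = biometric.test_equality_over_time(
                        data, fit, fit.spec.free, seed=config.seed
                    )
                    payload = {
                        "clock": clk,
                        "fit": _fit_to_dict(fit),
                        "equality_over_time": _cmp_to_dict(eq),
                    }
                    path = out / f"bivariate_{clk}.json"
                    path.write_text(json.dumps(payload, indent=2))
                    paths.append(str(path))
                manifest.outputs[stage] = paths

            elif stage == "fit_moderation":
                paths = []
                for clk, acc in acc_frames.items():
                    data = biometric.make_univariate_groups(
                        acc, first_occasion_only=config.first_occasion_only
                    )
                    history, fit = biometric.moderation_ladder(
                        data, mode=config.mode, seed=config.seed
                    )
                    grid = biometric.variance_components_at_age(
                        fit, list(config.moderation_ages)
                    )
                    jpath = out / f"moderation_{clk}.json"
                    tpath = out / f"moderation_{clk}_components.tsv"
                    jpath.write_text(
                        json.dumps(
                            {
                                "clock": clk,
                                "fit": _fit_to_dict(fit),
                                "pruning": [_cmp_to_dict(c) for c in history],
                            },
                            indent=2,
                        )
                    )
                    grid.to_csv(tpath, sep="\t", index=False, float_format="%.6g")
                    paths += [str(jpath), str(tpath)]
                manifest.outputs[stage] = paths

            elif stage == "power":
                results = []
                for sc in config.power_scenarios:
                    scenario = power.PowerScenario(**sc)
                    res = power.analytic_power(scenario)
                    results.append(
                        {"scenario": sc, **dataclasses.asdict(res)}
                    )
                path = out / "power.json"
                path.write_text(json.dumps(results, indent=2))
                manifest.outputs[stage] = [str(path)]

            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest.timings[stage] = round(time.perf_counter() - t0, 3)
            manifest.completed_stages.append(stage)
            log.info("stage %s done in %.2fs", stage, manifest.timings[stage])
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
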