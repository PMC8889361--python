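"""End-to-end pipeline: simulate/load -> calibrate -> CWSI -> traits -> verdicts.

``run_pipeline`` sequences the stages, writes every intermediate table as
CSV, and records a manifest (config hash, seed, package versions, outputs)
sufficient to reproduce the run bit-for-bit. Any stage failure aborts with
the stage name and cause. Logging is at stage granularity with record
counts in and out of every filter.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .baselines import MIDDAY_WINDOW, calibrate
from .cwsi_core import DEFAULT_SEASON_MONTHS, compute_cwsi_table, summarize
from .errors import CwsiError
from .relationships import DEFAULT_BAND, classify_regime, fit_relation_table
from .synthetic import ScenarioConfig, default_scenario, generate_scenario
from .tables import read_table, write_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("cwsipy.pipeline")


@dataclass
class PipelineConfig:
    """Inputs and knobs of one full run.

    Either a synthetic scenario (generated in-process) or paths to an
    observation table and a trait table on disk.
    """

    outdir: Path
    scenario: ScenarioConfig | None = None
    obs_path: Path | None = None
    traits_path: Path | None = None
    window: tuple = MIDDAY_WINDOW
    season_months: tuple = DEFAULT_SEASON_MONTHS
    band: tuple[float, float] = DEFAULT_BAND
    days_after_irrigation: int = 3
    upper_quantile: float = 0.10
    seed: int = 0
    verbosity: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        scenario = None
        if d.get("scenario"):
            scenario = ScenarioConfig.from_dict(d["scenario"])
        return cls(
            outdir=Path(d["outdir"]),
            scenario=scenario,
            obs_path=Path(d["obs_path"]) if d.get("obs_path") else None,
            traits_path=Path(d["traits_path"]) if d.get("traits_path") else None,
            band=tuple(d.get("band", DEFAULT_BAND)),
            days_after_irrigation=d.get("days_after_irrigation", 3),
            upper_quantile=d.get("upper_quantile", 0.10),
            seed=d.get("seed", 0),
            verbosity=d.get("verbosity", "INFO"),
        )

    def config_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "obs_path": str(self.obs_path) if self.obs_path else None,
            "traits_path": str(self.traits_path) if self.traits_path else None,
            "band": list(self.band),
            "days_after_irrigation": self.days_after_irrigation,
            "upper_quantile": self.upper_quantile,
            "season_months": list(self.season_months),
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """In-memory view of all pipeline outputs plus their file paths."""

    observations: pd.DataFrame
    baselines: pd.DataFrame
    cwsi_records: pd.DataFrame
    summary: pd.DataFrame
    plot_summary: pd.DataFrame
    traits: pd.DataFrame
    relations: pd.DataFrame
    verdicts: pd.DataFrame
    manifest: dict
    outdir: Path


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise CwsiError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done", name)
        return out

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under config.outdir."""
    logging.getLogger("cwsipy").setLevel(config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- inputs -----------------------------------------------------------
    if config.scenario is not None:
        data = _stage("simulate")(generate_scenario, config.scenario)
        obs, traits = data.observations, data.traits
    else:
        if config.obs_path is None:
            config = PipelineConfig(**{**config.__dict__, "scenario": default_scenario(config.seed)})
            return run_pipeline(config)
        obs = _stage("read-observations")(read_table, config.obs_path, "observations")
        traits = (
            _stage("read-traits")(read_table, config.traits_path, "traits")
            if config.traits_path
            else pd.DataFrame()
        )
    log.info("observations: %d records, %d plots", len(obs), obs["plot_id"].nunique())

    # -- calibration ------------------------------------------------------
    baselines = _stage("calibrate")(
        calibrate,
        obs,
        days_after=config.days_after_irrigation,
        window=config.window,
        upper_quantile=config.upper_quantile,
    )

    # -- CWSI and aggregation --------------------------------------------
    records = _stage("compute-cwsi")(compute_cwsi_table, obs, baselines)
    summary = _stage("aggregate")(
        summarize, records, by=("cultivar", "regime", "year"), months=config.season_months
    )
    plot_summary = _stage("aggregate-plots")(
        summarize,
        records,
        by=("plot_id", "cultivar", "regime", "year"),
        months=config.season_months,
    )

    # -- relations and verdicts ------------------------------------------
    if not traits.empty:
        joined = plot_summary.merge(
            traits.drop(columns=[c for c in ("seasonal_cwsi",) if c in traits.columns]),
            on=["plot_id", "cultivar", "regime", "year"],
            how="inner",
        )
        relations = _stage("relate")(fit_relation_table, joined)
    else:
        joined = plot_summary
        relations = pd.DataFrame()

    verdict_rows = []
    for (regime,), g in summary.groupby(["regime"]):
        v = classify_regime(g["seasonal_cwsi"].mean(), config.band)
        verdict_rows.append(("regime", "", regime, v.seasonal_cwsi, v.verdict))
    for (cultivar, regime), g in summary.groupby(["cultivar", "regime"]):
        v = classify_regime(g["seasonal_cwsi"].mean(), config.band)
        verdict_rows.append(("cultivar-regime", cultivar, regime, v.seasonal_cwsi, v.verdict))
    verdicts = pd.DataFrame(
        verdict_rows, columns=["level", "cultivar", "regime", "seasonal_cwsi", "verdict"]
    )
    verdicts["band_low"], verdicts["band_high"] = config.band

    # -- outputs ----------------------------------------------------------
    files = {}
    for name, df, schema in [
        ("observations", obs, "observations"),
        ("baselines", baselines, "baselines"),
        ("cwsi_records", records, "cwsi_records"),
        ("cwsi_summary", summary, None),
        ("plot_summary", joined, None),
        ("traits", traits, None),
        ("relations", relations, None),
        ("verdicts", verdicts, None),
    ]:
        if df is None or df.empty:
            continue
        files[name] = str(write_table(df, outdir / f"{name}.csv", schema))

    cfg = config.config_dict()
    manifest = {
        "package": "cwsipy",
        "version": __version__,
        "seed": config.seed if config.scenario is None else config.scenario.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "outputs": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        observations=obs,
        baselines=baselines,
        cwsi_records=records,
        summary=summary,
        plot_summary=joined,
        traits=traits,
        relations=relations,
        verdicts=verdicts,
        manifest=manifest,
        outdir=outdir,
    )
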