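"""End-to-end orchestration: simulate → fit-spatial → fit-trend → forecast → media.

A :class:`RunConfig` (a plain mapping, usually loaded from YAML) selects the
stages, inputs and settings; :func:`run_pipeline` executes the enabled stages
in dependency order, writes every output atomically under the run directory
and returns a manifest recording file hashes, seeds, package versions and
per-stage wall time.  Results go only to files; logging goes to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    build_intervals,
    read_adjacency,
    read_incidents,
    read_media,
    read_state_panel,
    StatePanel,
)
from .media import MediaContagionModel
from .simulate import DEFAULT_SEED, simulate_dataset
from .spatial import SpatialZIPModel
from .trend import NHPPTrendModel, compare_aic, interarrival_mle, risk_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit-spatial", "fit-trend", "forecast", "media")

#: Published configuration schema: key → (type, default).  The "paper-regime"
#: preset is exactly these defaults.
CONFIG_SCHEMA: dict[str, tuple[type, Any]] = {
    "outdir": (str, "runs/paper-regime"),
    "seed": (int, DEFAULT_SEED),
    "stages": (list, list(STAGES)),
    "force": (bool, False),
    "incidents": (str, None),
    "states": (str, None),
    "adjacency": (str, None),
    "media": (str, None),
    "n_chains": (int, 4),
    "n_iter": (int, 20000),
    "warmup": (int, None),
    "thin": (int, 10),
    "bin_width": (int, 2),
    "origin_year": (int, 1982),
    "horizons": (list, [1, 2, 3, 6, 9, 12]),
    "forecast_rates": (list, None),
    "media_from": (str, "2005-01-01"),
    "min_fatalities": (int, 4),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; see :data:`CONFIG_SCHEMA`."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(CONFIG_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {k: default for k, (_, default) in CONFIG_SCHEMA.items()}
        merged.update({k: v for k, v in self.values.items() if v is not None})
        for k, v in merged.items():
            typ, _ = CONFIG_SCHEMA[k]
            if v is not None and typ in (int, bool) and not isinstance(v, typ):
                raise ValueError(f"config key {k!r}: expected {typ.__name__}, got {v!r}")
        bad = set(merged["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.values = merged

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(doc)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, writer: Callable[[Path], None], force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; rerun with force to overwrite")
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


class StageFailure(RuntimeError):
    """A stage failed; downstream stages were not run."""

    def __init__(self, stage: str, manifest: dict, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the enabled stages in order and return the manifest.

    The manifest lists, per stage, the output files with SHA-256 content
    hashes and the wall time; plus the seed and package versions.  A failing
    stage raises :class:`StageFailure` carrying the partial manifest.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    force = bool(cfg["force"])
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "seed": seed,
        "versions": {"gvtrends": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
        "converged": True,
    }
    inputs = {k: cfg[k] for k in ("incidents", "states", "adjacency", "media")}

    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        t0 = time.time()
        files: dict[str, str] = {}
        try:
            if stage == "simulate":
                paths = simulate_dataset(outdir / "inputs", seed=seed)
                for name, p in paths.items():
                    files[name] = str(p)
                    inputs[{"incidents": "incidents", "states": "states",
                            "adjacency": "adjacency", "media": "media",
                            "truth": "truth"}.get(name, name)] = str(p)
            elif stage == "fit-spatial":
                files.update(_stage_spatial(cfg, inputs, outdir, force, manifest))
            elif stage == "fit-trend":
                files.update(_stage_trend(cfg, inputs, outdir, force))
            elif stage == "forecast":
                files.update(_stage_forecast(cfg, inputs, outdir, force))
            elif stage == "media":
                files.update(_stage_media(cfg, inputs, outdir, force))
        except Exception as exc:  # abort downstream stages, keep partial manifest
            manifest["stages"][stage] = {"error": str(exc)}
            _write_manifest(outdir, manifest, force)
            raise StageFailure(stage, manifest, exc) from exc
        manifest["stages"][stage] = {
            "files": {n: _sha256(Path(p)) for n, p in files.items()},
            "paths": files,
            "wall_time_s": round(time.time() - t0, 3),
        }
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    _write_manifest(outdir, manifest, force=True)
    return manifest


def _write_manifest(outdir: Path, manifest: dict, force: bool) -> None:
    _atomic_write(
        outdir / "manifest.json",
        lambda p: p.write_text(json.dumps(manifest, indent=2, default=str)),
        force=True,
    )


def _load_panel(inputs: dict) -> StatePanel:
    if not inputs.get("states"):
        raise ValueError("fit-spatial needs a states file (or the simulate stage)")
    adjacency = read_adjacency(inputs["adjacency"]) if inputs.get("adjacency") else None
    return read_state_panel(inputs["states"], adjacency=adjacency)


def _stage_spatial(cfg: RunConfig, inputs: dict, outdir: Path, force: bool,
                   manifest: dict) -> dict[str, str]:
    panel = _load_panel(inputs)
    fits = {}
    for kind, zi in (("zip", True), ("poisson", False)):
        fits[kind] = SpatialZIPModel(panel, zero_inflated=zi).fit(
            n_chains=cfg["n_chains"], n_iter=cfg["n_iter"],
            warmup=cfg["warmup"], thin=cfg["thin"], seed=cfg["seed"],
        )
    res = fits["zip"]
    manifest["converged"] = (manifest["converged"] and res.converged
                             and fits["poisson"].converged)
    files = {}
    p = outdir / "spatial_summary.csv"
    _atomic_write(p, lambda t: res.summary().to_csv(t), force)
    files["summary"] = str(p)
    from .spatial import kendall_permissiveness

    tau, pval = kendall_permissiveness(panel)
    diag = {
        "dic_zip": fits["zip"].dic,
        "dic_poisson": fits["poisson"].dic,
        "dic_marginal_zip": fits["zip"].dic_marginal,
        "dic_marginal_poisson": fits["poisson"].dic_marginal,
        "rhat": res.rhat,
        "converged": res.converged,
        "converged_poisson": fits["poisson"].converged,
        "n_chains": res.n_chains,
        "n_iter": res.n_iter,
        "kendall_permissiveness_tau": tau,
        "kendall_permissiveness_p": pval,
    }
    p = outdir / "spatial_diagnostics.json"
    _atomic_write(p, lambda t: t.write_text(json.dumps(diag, indent=2)), force)
    files["diagnostics"] = str(p)
    return files


def _stage_trend(cfg: RunConfig, inputs: dict, outdir: Path, force: bool) -> dict[str, str]:
    if not inputs.get("incidents"):
        raise ValueError("fit-trend needs an incidents file (or the simulate stage)")
    incidents = read_incidents(inputs["incidents"], min_fatalities=cfg["min_fatalities"])
    fit_bi = NHPPTrendModel(incidents, width_years=2, origin_year=cfg["origin_year"]).fit()
    fit_an = NHPPTrendModel(incidents, width_years=1, origin_year=cfg["origin_year"]).fit()
    fit_quad = NHPPTrendModel(incidents, width_years=2, origin_year=cfg["origin_year"]).fit(degree=2)
    preferred, delta = compare_aic(fit_an, fit_bi)
    daily, monthly = interarrival_mle(incidents)
    main = fit_bi if cfg["bin_width"] == 2 else fit_an
    out = {
        "coefficients": list(main.coefficients),
        "aic_biannual": fit_bi.aic,
        "aic_annual": fit_an.aic,
        "preferred_binning": preferred,
        "delta_aic": delta,
        "slope_p_value": main.slope_p_value,
        "quadratic_p_value": fit_quad.quadratic_p_value,
        "pearson_dispersion": main.pearson_dispersion,
        "interarrival_daily_rate": daily,
        "interarrival_monthly_rate": monthly,
        "recent_year_offset": main.most_recent_year_offset,
        "recent_monthly_rate": main.predict_monthly_rate(main.most_recent_year_offset),
    }
    files = {}
    p = outdir / "trend.json"
    _atomic_write(p, lambda t: t.write_text(json.dumps(out, indent=2)), force)
    files["trend"] = str(p)
    p = outdir / "binned_counts.csv"
    _atomic_write(p, lambda t: main.binned.to_csv(t, index=False), force)
    files["binned"] = str(p)
    return files


def _stage_forecast(cfg: RunConfig, inputs: dict, outdir: Path, force: bool) -> dict[str, str]:
    rates = cfg["forecast_rates"]
    if rates is None:
        trend_path = Path(cfg["outdir"]) / "trend.json"
        if not trend_path.exists():
            raise ValueError("forecast needs forecast_rates or a prior fit-trend stage")
        doc = json.loads(trend_path.read_text())
        rates = [doc["interarrival_monthly_rate"], doc["recent_monthly_rate"]]
    horizons = cfg["horizons"]
    cols = {"months": list(horizons)}
    for r in rates:
        t = risk_table(float(r), horizons).table
        cols[f"p_rate_{float(r):.3f}"] = list(t["probability_3dp"])
    df = pd.DataFrame(cols)
    p = Path(cfg["outdir"]) / "forecast.csv"
    _atomic_write(p, lambda t: df.to_csv(t, index=False), force)
    return {"forecast": str(p)}


def _stage_media(cfg: RunConfig, inputs: dict, outdir: Path, force: bool) -> dict[str, str]:
    if not inputs.get("incidents") or not inputs.get("media"):
        raise ValueError("media stage needs incidents and media files")
    incidents = read_incidents(inputs["incidents"], min_fatalities=cfg["min_fatalities"])
    cutoff = Date.fromisoformat(cfg["media_from"])
    recent = [r for r in incidents if r.date >= cutoff]
    media = read_media(inputs["media"])
    records = build_intervals(
        recent,
        media_counts=media["article_count"].to_list(),
        search_interest=media["search_interest"].to_list(),
        floor_same_day=True,
    )
    model = MediaContagionModel(records).with_casualties(
        [r.fatalities for r in recent[:-1]], [r.injuries for r in recent[:-1]]
    )
    res = model.fit()
    files = {}
    p = outdir / "spearman.csv"
    _atomic_write(p, lambda t: res.spearman.to_csv(t), force)
    files["spearman"] = str(p)
    p = outdir / "ridge.json"
    ridge_doc = {
        "coefficients": res.ridge.coefficients.to_dict(),
        "penalty": res.ridge.penalty,
        "p_values": res.ridge.p_values.to_dict(),
    }
    _atomic_write(p, lambda t: t.write_text(json.dumps(ridge_doc, indent=2)), force)
    files["ridge"] = str(p)
    p = outdir / "poisson.json"
    _atomic_write(
        p, lambda t: t.write_text(res.poisson.to_json(orient="index", indent=2)), force
    )
    files["poisson"] = str(p)
    # sensitivity: drop the three largest-density intervals' opening events
    top = res.model.frame.nlargest(3, "media_density")
    try:
        sens = res.sensitivity_remove(
            [model.records[i].start_event for i in top.index]
        )
        p = outdir / "sensitivity.csv"
        _atomic_write(p, lambda t: sens.to_csv(t), force)
        files["sensitivity"] = str(p)
    except ValueError:
        logger.warning("too few intervals for the sensitivity re-run; skipped")
    return files
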