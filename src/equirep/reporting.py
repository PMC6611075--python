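"""Pipeline orchestration and descriptive summaries.

A run goes synthetic generation (or ingest of prepared inputs) -> per-cell
table -> representation histograms -> equality and decadal trajectories ->
priority maps -> driver importance, writing every stage as tidy CSV plus a
manifest with seeds and checksums so a run is reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import drivers as drv
from . import equality as eq
from . import ingest as ing
from . import priority as pri
from . import representation as rep
from .grid import HUMAN_VARIABLES, PHYSICAL_VARIABLES
from .synthetic import (LandscapeSpec, PlacementScenario, generate_landscape,
                        generate_protected_network)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int
    excluded: list


def extent_equality_regression(points: pd.DataFrame, exclude=()) -> RegressionResult:
    """Descriptive OLS of mean G' on protection extent across territories.

    ``points`` needs columns ``territory``, ``extent_pct``, ``mean_gprime``;
    territories listed in ``exclude`` (and rows with undefined equality) are
    left out, mirroring how single-ecoregion and whole-extent points are
    excluded from the cross-territory fit.
    """
    excluded = [t for t in points["territory"] if t in set(exclude)]
    sub = points[~points["territory"].isin(set(exclude))].dropna(subset=["mean_gprime"])
    if len(sub) < 3:
        raise ValueError(f"need at least 3 territory points, have {len(sub)}")
    res = stats.linregress(sub["extent_pct"], sub["mean_gprime"])
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0  # constant response
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n=len(sub),
        excluded=excluded,
    )


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    scenario: PlacementScenario = field(default_factory=PlacementScenario)
    periods: tuple = ing.DEFAULT_PERIODS
    n_bins: int | str = 10  # 10 or "sturges"
    tau_threshold: float = 0.55
    basis: str = "physical"  # "physical" or "biogeographical"
    scopes: tuple = ("national", "continental")
    quantile_classes: int = 4
    rf_ntree: int = 500
    rf_bootstrap: int = 1000
    run_drivers: bool = True
    seed: int = 0
    outdir: str = "equirep_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        from .synthetic import FieldSpec
        if "landscape" in raw:
            ls = raw["landscape"]
            if "field_specs" in ls:
                ls["field_specs"] = {
                    k: FieldSpec(**v) for k, v in ls["field_specs"].items()
                }
            raw["landscape"] = LandscapeSpec(**ls)
        if "scenario" in raw:
            sc = raw["scenario"]
            if "establishment_years" in sc:
                sc["establishment_years"] = {
                    int(k): float(v) for k, v in sc["establishment_years"].items()
                }
            raw["scenario"] = PlacementScenario(**sc)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a synthetic scenario and write the artifact bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _jsonable(config.to_dict()), "artifacts": {}, "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, manifest["stages"][name])
        return out

    def _synth():
        spec = dataclasses.replace(config.landscape, seed=config.seed)
        grid = generate_landscape(spec)
        records, truth = generate_protected_network(grid, config.scenario,
                                                    seed=config.seed + 1)
        return grid, records, truth

    grid, records, truth = stage("synth", _synth)

    def _ingest():
        return ing.build_cell_table(grid, records, periods=config.periods)

    cells = stage("ingest", _ingest)
    _write(cells, outdir / "cells.csv", manifest)

    territories = sorted(cells["territory"].unique())
    current = int(cells["period"].max())

    def _represent():
        frames = []
        for terr in territories:
            for var in PHYSICAL_VARIABLES + HUMAN_VARIABLES:
                edges = rep.territory_edges(cells, terr, var, n_bins=config.n_bins)
                hist = rep.build_histogram(cells, terr, var, current, edges)
                frames.append(hist.to_frame())
        return pd.concat(frames, ignore_index=True)

    _write(stage("represent", _represent), outdir / "histograms.csv", manifest)

    def _equality():
        rows, trows = [], []
        for terr in territories:
            for pt in eq.trajectory(cells, terr, basis=config.basis,
                                    n_bins=config.n_bins,
                                    threshold=config.tau_threshold):
                trows.append(dataclasses.asdict(pt))
            res = eq.compute_equality(cells, terr, current, basis=config.basis,
                                      n_bins=config.n_bins,
                                      threshold=config.tau_threshold)
            for var, gp in res.per_variable.items():
                rows.append(
                    {
                        "territory": terr,
                        "period": current,
                        "basis": res.basis,
                        "variable": var,
                        "gprime": gp,
                        "retained": var in res.retained,
                        "mean_gprime": res.mean_gprime,
                        "extent_pct": res.extent_pct,
                    }
                )
        return pd.DataFrame(rows), pd.DataFrame(trows)

    equality_tab, trajectory_tab = stage("equality", _equality)
    _write(equality_tab, outdir / "equality.csv", manifest)
    _write(trajectory_tab, outdir / "trajectory.csv", manifest)

    def _regression():
        pts = (
            equality_tab.drop_duplicates("territory")
            [["territory", "extent_pct", "mean_gprime"]]
        )
        if len(pts.dropna(subset=["mean_gprime"])) < 3:
            return None
        return dataclasses.asdict(extent_equality_regression(pts))

    reg = stage("regression", _regression)
    if reg is not None:
        p = outdir / "regression.json"
        p.write_text(json.dumps(reg, indent=2))
        manifest["artifacts"]["regression.json"] = _sha256(p)

    def _priority():
        for scope in config.scopes:
            pm = pri.compute_priority(cells, scope=scope, period=current,
                                      n_bins=10 if config.n_bins == "sturges"
                                      else config.n_bins,
                                      threshold=config.tau_threshold)
            pm = pri.classify_quantiles(pm, config.quantile_classes)
            _write(pm.table, outdir / f"priority_{scope}.csv", manifest)

    stage("priority", _priority)

    if config.run_drivers:
        def _drivers():
            frames = []
            for terr in territories:
                res = drv.vi_bootstrap(
                    cells, terr,
                    drv.RFSettings(ntree=config.rf_ntree),
                    B=config.rf_bootstrap, seed=config.seed + 2, period=current,
                )
                frames.append(res.to_frame())
            return pd.concat(frames, ignore_index=True)

        _write(stage("drivers", _drivers), outdir / "drivers.csv", manifest)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["artifacts"][path.name] = _sha256(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
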