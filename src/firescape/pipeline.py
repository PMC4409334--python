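"""End-to-end pipeline: harmonised stack -> FR tables -> FSI -> ranking ->
unit table -> correlation screen -> matching -> ATT + balance.

The report bundle is a directory with fixed file names:
``fr_protected.csv``, ``fr_nonprotected.csv``, ``fsi.tif``,
``ranking.csv``, ``balance.csv``, ``effect.json``, ``run_log.jsonl``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from firescape import io as fio
from firescape.errors import FirescapeError
from firescape.grid import GridStack, Raster, rasterize_fires
from firescape.matching import (
    att_estimate,
    balance_report,
    build_unit_table,
    correlation_screen,
    fit_propensity,
    mahalanobis_match,
)
from firescape.susceptibility import (
    FactorScheme,
    classify_factor,
    default_factor_scheme,
    fire_density,
    fire_susceptibility_index,
    frequency_ratio_table,
    label_fr_table,
    rank_factors,
)
from firescape.synthetic import LandscapeConfig, emit_fire_csv, generate_covariates, generate_fires


@dataclass
class RunConfig:
    """Pipeline configuration with the knobs the stages expose."""

    selection_quantile: float = 0.90
    min_confidence: int = 95
    caliper_sd: float = 1.0
    forest_threshold: float = 25.0
    forest_only: bool = True
    correlation_threshold: float = 0.95
    seed: int = 0
    scheme: FactorScheme | None = None
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)


class RunLog:
    """JSON-lines run log with stage timings and cell accounting."""

    def __init__(self) -> None:
        self.records: list[dict] = []
        self._t0 = time.perf_counter()

    def add(self, stage: str, **info) -> None:
        self.records.append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - self._t0, 4), **info}
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _stage(log: RunLog, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise FirescapeError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic-mode pipeline and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    results: dict = {}

    with _stage(log, "simulate"):
        stack = generate_covariates(config.landscape, seed=config.seed)
        fire, truth = generate_fires(stack, config.landscape, seed=config.seed + 1)
        detections = emit_fire_csv(fire, stack.geometry, seed=config.seed + 2)
        log.add(
            "simulate",
            n_cells=int(np.prod(stack.geometry.shape)),
            n_fire_cells=int((fire.values == 1).sum()),
            true_att=truth.true_att,
        )

    with _stage(log, "ingest_fires"):
        fire_obs, ingest = rasterize_fires(detections, stack.geometry, config.min_confidence)
        stack.fire = fire_obs
        log.add("ingest_fires", **ingest.as_dict())

    scheme = config.scheme or default_factor_scheme(config.landscape.n_landcover_classes)

    with _stage(log, "classify"):
        class_rasters = {
            f.name: classify_factor(stack.covariates[f.name], f)
            for f in scheme
            if f.name in stack.covariates
        }
        log.add("classify", n_factors=len(class_rasters))

    with _stage(log, "frequency_ratio"):
        strata = {
            "protected": stack.protection,
            "nonprotected": Raster(
                stack.geometry,
                1 - stack.protection.values,
                kind="binary",
                nodata=255,
                name="nonprotected",
            ),
        }
        fr_tables: dict[str, pd.DataFrame] = {}
        for sname, smask in strata.items():
            parts = [
                frequency_ratio_table(fire_obs, cr, smask, factor=fname, stratum=sname)
                for fname, cr in class_rasters.items()
            ]
            tab = label_fr_table(pd.concat(parts, ignore_index=True), scheme)
            fr_tables[sname] = tab
            tab.to_csv(out / f"fr_{sname}.csv", index=False)
        log.add(
            "frequency_ratio",
            densities={s: fire_density(fire_obs, m) for s, m in strata.items()},
        )

    with _stage(log, "fsi"):
        smaps = {}
        rankings = []
        for sname, smask in strata.items():
            # stratified FSI: class rasters restricted to the stratum so the
            # stratum's FR table covers every class it is applied to
            masked = {
                fname: cr.with_values(
                    np.where(smask.values == 1, cr.values, cr.nodata)
                )
                for fname, cr in class_rasters.items()
            }
            smap = fire_susceptibility_index(fr_tables[sname], masked)
            smaps[sname] = smap
            rk = rank_factors(smap, config.selection_quantile, smask, stratum=sname)
            rankings.append(rk.to_frame())
        fio.write_raster(smaps["protected"].fsi, out / "fsi.tif")
        pd.concat(rankings, ignore_index=True).to_csv(out / "ranking.csv", index=False)
        log.add("fsi", selection_quantile=config.selection_quantile)

    with _stage(log, "units"):
        units = build_unit_table(
            stack, forest_only=config.forest_only, forest_threshold=config.forest_threshold
        )
        units.to_csv(out / "units.csv")
        log.add(
            "units",
            n_units=len(units),
            n_treated=int((units.T == 1).sum()),
            n_excluded_nodata=int(np.prod(stack.geometry.shape) - stack.valid_mask().sum()),
            n_excluded_forest=int(
                stack.valid_mask().sum() - len(units) if config.forest_only else 0
            ),
        )

    with _stage(log, "correlation_screen"):
        mat, flagged, constant = correlation_screen(units, config.correlation_threshold)
        mat.to_csv(out / "correlation.csv")
        log.add(
            "correlation_screen",
            flagged=[list(map(str, f[:2])) + [f[2]] for f in flagged],
            constant=constant,
        )

    with _stage(log, "propensity"):
        prop = fit_propensity(units)
        log.add(
            "propensity",
            converged=bool(prop.converged),
            separation=bool(prop.separation_flagged),
        )

    with _stage(log, "matching"):
        matches = mahalanobis_match(units, caliper_sd=config.caliper_sd)
        effect = att_estimate(units, matches)
        balance = balance_report(units, matches)
        balance.to_csv(out / "balance.csv", index=False)
        with open(out / "effect.json", "w") as fh:
            json.dump(effect.as_dict(), fh, indent=2, sort_keys=True)
        log.add(
            "matching",
            n_treated_matched=effect.n_treated_matched,
            n_excluded_caliper=effect.n_excluded_caliper,
            att=effect.att,
            se=effect.se,
        )

    log.write(out / "run_log.jsonl")
    results.update(
        {
            "effect": effect.as_dict(),
            "truth": truth.as_dict(),
            "units": units,
            "fr_tables": fr_tables,
            "stack": stack,
        }
    )
    return results
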