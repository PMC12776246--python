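"""End-to-end orchestration: synthesize -> prep -> SDM -> advect -> connect -> storms.

Stages communicate only through files in the run directory; the manifest
records per-stage outputs with content hashes and the particle conservation
audit, and deliberately contains no wall-clock timestamps so that two runs
of the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_prep, connectivity, hurricane_analysis, io_formats, sdm_ensemble, synthetic_data
from .io_formats import RunConfig
from .lagrangian_tracker import (
    advect,
    build_release_schedule,
    summarize_trajectories,
    trajectory_density,
)

log = logging.getLogger("mangroveshift")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Holds the in-memory artifacts of a full run (also written to disk)."""

    def __init__(self, config: RunConfig, out_dir):
        self.config = config
        self.out_dir = Path(out_dir)
        self.manifest = {"stages": [], "seed": config.seed}
        self.artifacts: dict = {}

    def _record(self, stage: str, files, extra=None):
        entry = {
            "stage": stage,
            "outputs": {f.name: _sha256(f) for f in sorted(files, key=lambda p: p.name)},
        }
        if extra:
            entry.update(extra)
        self.manifest["stages"].append(entry)


def run_all(config: RunConfig, out_dir) -> PipelineRun:
    """Run every stage; halts on failure with completed stages in the manifest."""
    run = PipelineRun(config, out_dir)
    run.out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.dump_config(config, run.out_dir / "config_resolved.yaml")
    stages = [
        ("synthesize", stage_synthesize),
        ("prep_climate", stage_prep_climate),
        ("fit_sdm", stage_fit_sdm),
        ("advect", stage_advect),
        ("connect", stage_connect),
        ("storms", stage_storms),
    ]
    try:
        for name, fn in stages:
            log.info("stage %s", name)
            fn(run)
    finally:
        with open(run.out_dir / "manifest.json", "w") as fh:
            json.dump(run.manifest, fh, indent=2, sort_keys=True)
    return run


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_synthesize(run: PipelineRun):
    cfg = run.config
    spec = cfg.domain_spec()
    truth = synthetic_data.SyntheticTruth()
    mask = synthetic_data.make_land_mask(spec, synthetic_data.default_coastline_params(spec))
    raster = synthetic_data.make_climate_raster(spec, truth, mask)
    scenario_rasters = synthetic_data.make_future_climate(
        raster, truth.scenario_emt_offsets, truth.scenario_map_factors
    )
    table = synthetic_data.make_occurrence_dataset(spec, truth, cfg.sdm.n_occurrences, cfg.seed, mask=mask)
    field = synthetic_data.make_velocity_field(
        cfg.tracker.velocity_kind, cfg.tracker.velocity_params, spec, mask=mask
    )
    storms_text = synthetic_data.make_synthetic_hurdat2(_default_storm_params(cfg), cfg.seed)

    d = run.out_dir
    io_formats.write_mask_netcdf(mask, d / "mask.nc")
    io_formats.write_velocity_netcdf(field, d / "velocity.nc")
    io_formats.write_points_csv(table, d / "occurrences.csv")
    (d / "storms.txt").write_text(storms_text)
    wb = climate_prep.WaterbodyConfig.from_mask(mask)
    wb.to_csv(d / "waterbodies.csv")

    run.artifacts.update(
        spec=spec, truth=truth, mask=mask, raster=raster, scenario_rasters=scenario_rasters,
        occurrences=table, field=field, storms_text=storms_text, waterbodies=wb,
    )
    run._record(
        "synthesize",
        [d / f for f in ("mask.nc", "velocity.nc", "occurrences.csv", "storms.txt", "waterbodies.csv")],
        extra={"n_records": len(table)},
    )


def _default_storm_params(cfg: RunConfig):
    hs = cfg.hurricanes
    params = []
    for i in range(hs.n_tracks):
        month = (8, 9, 10)[i % 3]
        params.append(
            synthetic_data.TrackParams(
                name=f"SYNTH{i + 1}",
                year=2011,
                number=i + 1,
                t0=np.datetime64(f"2011-{month:02d}-{(i % 27) + 1:02d}T00:00"),
                lon0=-80.5 + 0.2 * (i % 5),
                lat0=24.5 + 0.5 * (i % 6),
                n_fixes=10,
                heading_deg=25.0,
                heading_jitter=20.0,
                speed_kmh=22.0,
                wind_kt_range=(45, 110),
            )
        )
    return params


def stage_prep_climate(run: PipelineRun):
    a = run.artifacts
    filled = climate_prep.resolve_missing_climate(a["occurrences"], a["waterbodies"], a["raster"])
    retained, report = climate_prep.screen_predictors(filled)
    d = run.out_dir
    io_formats.write_points_csv(filled, d / "occurrences_filled.csv")
    report.to_csv(d / "correlation_report.csv", index=False)
    a.update(filled=filled, predictors=retained, correlation_report=report)
    run._record(
        "prep_climate",
        [d / "occurrences_filled.csv", d / "correlation_report.csv"],
        extra={"retained_predictors": retained,
               "n_filled": int((filled[[f"{c}_fill_source" for c in ("EMT", "MAP", "SST")]] != "").to_numpy().sum())},
    )


def stage_fit_sdm(run: PipelineRun):
    cfg, a = run.config, run.artifacts
    table, predictors, truth = a["filled"], a["predictors"], a["truth"]
    cv = sdm_ensemble.evaluate_families(
        table, predictors, train_frac=cfg.sdm.train_frac, reps=cfg.sdm.reps, seed=cfg.seed
    )
    means = cv.family_means()
    fitted = {
        fam: sdm_ensemble.fit_learner(sdm_ensemble.LearnerSpec(fam, seed=cfg.seed), table, predictors)
        for fam in sdm_ensemble.FAMILIES
    }
    mean_tss = dict(zip(means["family"], means["TSS"]))
    ensemble = sdm_ensemble.build_ensemble(fitted, mean_tss, tss_min=cfg.sdm.tss_min)
    y = table["habitat"].to_numpy(dtype=int)
    prob = ensemble.predict_prob(table)
    candidates = sdm_ensemble.optimal_thresholds(y, prob, criteria=cfg.sdm.criteria)
    threshold_report = sdm_ensemble.select_suitability_threshold(candidates, y, prob)
    thr = threshold_report.selected_threshold

    scenario_tables = {"present": table}
    for scen in synthetic_data.SCENARIOS:
        scenario_tables[scen] = synthetic_data.apply_scenario_to_points(
            table, truth.scenario_emt_offsets[scen], truth.scenario_map_factors[scen]
        )
    summary = sdm_ensemble.suitability_summary(ensemble, scenario_tables, thr, regions=cfg.regions)

    d = run.out_dir
    means.to_csv(d / "model_evaluation.csv", index=False)
    cv.report.to_csv(d / "model_evaluation_reps.csv", index=False)
    threshold_report.stats.to_csv(d / "threshold_report.csv", index=False)
    scored_all = pd.concat([s["scored"] for s in summary.values()], ignore_index=True)
    scored_all.to_csv(d / "suitability_points.csv", index=False)
    suit_rows = []
    for scen, s in summary.items():
        row = {"scenario": scen, "northernmost_suitable_lat": s["northernmost_suitable_lat"]}
        for reg, pct in s["fraction_suitable_pct"].items():
            row[f"pct_suitable_{reg}"] = pct
        suit_rows.append(row)
    pd.DataFrame(suit_rows).to_csv(d / "suitability_summary.csv", index=False)

    a.update(cv=cv, ensemble=ensemble, threshold_report=threshold_report, threshold=thr,
             suitability=summary, scenario_tables=scenario_tables)
    run._record(
        "fit_sdm",
        [d / f for f in ("model_evaluation.csv", "model_evaluation_reps.csv",
                          "threshold_report.csv", "suitability_points.csv", "suitability_summary.csv")],
        extra={"selected_threshold_summary": threshold_report.selected,
               "selected_threshold": thr,
               "ensemble_members": [m.family for m in ensemble.members]},
    )


def _source_points(table: pd.DataFrame, n: int):
    """Release sources: mangrove presences spread evenly over latitude."""
    pres = table[table["habitat"] == 1].sort_values("lat")
    if len(pres) == 0:
        raise ValueError("no presence records to derive release sources from")
    idx = np.unique(np.linspace(0, len(pres) - 1, num=min(n, len(pres))).astype(int))
    sel = pres.iloc[idx]
    return sel[["lon", "lat"]].to_numpy()


def stage_advect(run: PipelineRun):
    cfg, a = run.config, run.artifacts
    spec, mask, field = a["spec"], a["mask"], a["field"]
    start = np.datetime64(cfg.tracker.window_start)
    window = (start, start + np.timedelta64(cfg.tracker.window_hours, "h"))
    schedule = build_release_schedule(mask, _source_points(a["filled"], cfg.tracker.n_source_points), window)
    trajectories = advect(
        field, mask, schedule, cfg.tracker.max_float_months,
        min_float_range=cfg.tracker.min_float_days, seed=cfg.seed,
    )
    density = trajectory_density(trajectories, spec)
    summary = summarize_trajectories(trajectories, spec)

    d = run.out_dir
    io_formats.write_density_netcdf(density, spec, d / "density.nc")
    summary.to_csv(d / "particle_summary.csv", index=False)
    pos = pd.concat(
        [
            pd.DataFrame({"particle_id": tr.particle_id, "t": tr.times, "lon": tr.lons, "lat": tr.lats})
            for tr in trajectories
        ],
        ignore_index=True,
    )
    pos.to_csv(d / "trajectories.csv", index=False)

    a.update(schedule=schedule, trajectories=trajectories, density=density, particle_summary=summary)
    run._record(
        "advect",
        [d / "density.nc", d / "particle_summary.csv", d / "trajectories.csv"],
        extra={"n_released": len(trajectories),
               "status_counts": summary["status"].value_counts().to_dict()},
    )


def stage_connect(run: PipelineRun):
    cfg, a = run.config, run.artifacts
    scheme = connectivity.SubregionScheme(tuple(tuple(s) for s in cfg.subregions))
    matrix = connectivity.build_connectivity(a["trajectories"], scheme, a["mask"], bin_width=cfg.bin_width)
    scored = {scen: s["scored"] for scen, s in a["suitability"].items()}
    classes = connectivity.classify_destination_suitability(
        list(matrix.matrix.columns), cfg.bin_width, scored, a["threshold"], synthetic_data.SCENARIOS
    )
    audit = matrix.audit_balance()
    if audit["residual"] != 0:
        raise RuntimeError(f"conservation audit does not balance: {audit}")

    reached = {"present": connectivity.northernmost_reached_suitable(matrix, classes, None)}
    for scen in synthetic_data.SCENARIOS:
        reached[scen] = connectivity.northernmost_reached_suitable(matrix, classes, scen)

    d = run.out_dir
    matrix.matrix.to_csv(d / "connectivity.csv")
    matrix.exclusions.to_csv(d / "connectivity_exclusions.csv", index=False)
    classes.to_csv(d / "bin_classes.csv", index=False)
    pd.DataFrame(
        [{"scenario": k, "northernmost_reached_suitable_lat": v} for k, v in reached.items()]
    ).to_csv(d / "connectivity_summary.csv", index=False)

    a.update(matrix=matrix, bin_classes=classes, reached=reached, audit=audit)
    run._record(
        "connect",
        [d / f for f in ("connectivity.csv", "connectivity_exclusions.csv",
                          "bin_classes.csv", "connectivity_summary.csv")],
        extra={"audit": audit},
    )


def stage_storms(run: PipelineRun):
    cfg, a = run.config, run.artifacts
    hs = cfg.hurricanes
    tracks, errors = hurricane_analysis.parse_hurdat2(a["storms_text"])
    if errors:
        raise RuntimeError(f"synthetic storm file failed to parse: {errors[0]}")
    region = hurricane_analysis.region_polygon_from_box(hs.region_box)
    retained, segments = hurricane_analysis.filter_tracks(tracks, region, months=hs.months, years=hs.years)
    seasonal = hurricane_analysis.windrose_table(segments, n_sectors=hs.sectors)
    monthly = hurricane_analysis.monthly_windrose_tables(segments, n_sectors=hs.sectors)

    d = run.out_dir
    seasonal.to_csv(d / "windrose_seasonal.csv", index=False)
    files = [d / "windrose_seasonal.csv"]
    for month, table in monthly.items():
        f = d / f"windrose_month_{month:02d}.csv"
        table.to_csv(f, index=False)
        files.append(f)

    a.update(storm_tracks=tracks, retained_tracks=retained, segments=segments,
             windrose=seasonal, windrose_monthly=monthly)
    run._record(
        "storms", files,
        extra={"n_tracks": len(tracks), "n_retained": len(retained), "n_segments": len(segments)},
    )
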