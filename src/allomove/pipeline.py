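"""Stage orchestration: simulate -> score -> prep -> fit -> decode -> report.

Each stage reads and writes only files declared in the config's paths
section, inside the run directory.  A manifest (config copy, seed,
package version, per-stage row counts) is written at the end of every
run; reruns skip stages whose outputs already exist, so a failed run can
resume.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from allomove import __version__, datasets, health
from allomove.config import PipelineConfig
from allomove.hmm import (
    FitConfig,
    FitResult,
    HMMParameters,
    ModelStructure,
    compare_models,
    fit_hmm,
    stationary_curves,
    viterbi,
)
from allomove.hmm.params import DEFAULT_EMISSIONS
from allomove.hmm.select import _variant
from allomove.hmm.series import ObservationSeries

log = logging.getLogger(__name__)

__all__ = ["run", "run_stage"]


def _derive_seed(seed: int, stage: str) -> int:
    offsets = {"simulate": 1, "score": 2, "prep": 3, "fit": 4, "decode": 5}
    return (seed * 1000 + offsets.get(stage, 0)) % (2**31 - 1)


def _stage_simulate(cfg: PipelineConfig, counts: dict) -> None:
    from allomove.simulate import (
        SimulationConfig,
        default_truth,
        simulate_health_records,
        simulate_tracks,
    )

    seed = _derive_seed(cfg.seed, "simulate")
    s = cfg.simulate
    records = simulate_health_records(s.n_health_records, seed=seed)
    records.to_csv(cfg.resolve("health_csv"))
    counts["health_records"] = len(records)

    if s.csi_source == "cohort":
        csi = datasets.narwhal_csi()
        if s.n_individuals > len(csi):
            raise ValueError(
                f"cohort provides {len(csi)} CSI values; "
                f"requested {s.n_individuals} individuals"
            )
        csi_values = csi.iloc[: s.n_individuals].tolist()
    elif s.csi_source == "health":
        scores = _score_records(records, cfg)
        csi_values = scores["csi"].iloc[: s.n_individuals].tolist()
    else:
        raise ValueError(f"unknown csi_source {s.csi_source!r}")

    sim_cfg = SimulationConfig(
        n_individuals=s.n_individuals,
        steps_per_individual=s.steps_per_individual,
        csi_values=csi_values,
        truth=default_truth(),
        missing_dive_prob=s.missing_dive_prob,
        seed=seed,
    )
    series, truth = simulate_tracks(sim_cfg)
    ObservationSeries.list_to_csv(series, cfg.resolve("streams_csv"))
    counts["stream_rows"] = sum(len(x) for x in series)

    if s.write_telemetry:
        _write_telemetry(cfg, series, seed)


def _write_telemetry(cfg: PipelineConfig, series, seed: int) -> None:
    """Emit locations/raw fixes/depth/raster so the prep stage has inputs."""
    from allomove.simulate import locations_from_steps, make_shore_raster, simulate_depth_series

    rng = np.random.default_rng(seed + 7)
    loc_frames, fix_frames, depth_frames = [], [], []
    for ser in series:
        steps = np.where(np.isfinite(ser.step), ser.step, 100.0)
        turns = np.where(np.isfinite(ser.turn), ser.turn, 0.0)
        x, y = locations_from_steps(steps, turns)
        ts = pd.date_range(ser.timestamps[0], periods=len(x), freq="1h")
        loc_frames.append(pd.DataFrame({"id": ser.id, "timestamp": ts, "x": x, "y": y}))
        keep = rng.random(len(ts)) > 0.1  # drop some raw fixes to create gaps
        keep[0] = keep[-1] = True
        fix_frames.append(pd.DataFrame({"id": ser.id, "timestamp": ts[keep]}))
        plan = [
            (float(d), 900.0)
            for d in ser.max_depth[np.isfinite(ser.max_depth)][:50]
        ]
        if plan:
            depth, _ = simulate_depth_series(plan, seed=seed)
            df = pd.DataFrame({"time_s": depth.times_s, "depth_m": depth.depth})
            df.insert(0, "id", ser.id)
            depth_frames.append(df)
    pd.concat(loc_frames).to_csv(cfg.resolve("locations_csv"), index=False)
    pd.concat(fix_frames).to_csv(cfg.resolve("raw_fixes_csv"), index=False)
    if depth_frames:
        pd.concat(depth_frames).to_csv(cfg.resolve("depth_csv"), index=False)
    extent = (-50.0, 50.0, -50.0, 50.0)
    make_shore_raster(extent, resolution=2.0, shoreline=("vertical", -50.0)).write(
        cfg.resolve("shore_raster")
    )


def _score_records(records: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Score raw health records: BCI fit, thresholds, per-dimension scores."""
    fixed = cfg.health.fixed_thresholds
    if fixed:
        thresholds = health.HormoneThresholds(**fixed)
    else:
        thresholds = health.hormone_thresholds(
            records, method=cfg.health.quantile_method
        )
    try:
        bci = health.fit_body_condition(records)
    except ValueError:
        bci = None
    rows = {}
    for ind, r in records.iterrows():
        def _flag(v):
            return None if pd.isna(v) else bool(v)

        rec = health.HealthRecord(
            id=str(ind),
            sex=str(r["sex"]),
            standard_length=float(r["standard_length"]),
            axillary_girth=None if pd.isna(r["axillary_girth"]) else float(r["axillary_girth"]),
            healed_scars=_flag(r["healed_scars"]),
            fresh_wounds=_flag(r["fresh_wounds"]),
            ectoparasites=_flag(r["ectoparasites"]),
            predators_sighted=_flag(r["predators_sighted"]),
            calf_present=_flag(r["calf_present"]),
            cortisol=None if pd.isna(r["cortisol"]) else float(r["cortisol"]),
            dhea=None if pd.isna(r["dhea"]) else float(r["dhea"]),
            dhea_s=None if pd.isna(r["dhea_s"]) else float(r["dhea_s"]),
        )
        resid = bci.residual_for(str(ind)) if bci is not None else None
        bd = health.score_components(rec, thresholds, resid)
        rows[ind] = {
            **{c: bd.scores.get(c, np.nan) for c in datasets.SCORE_COLUMNS},
            "total_score": bd.total_score,
            "n_dims": bd.n_dimensions,
            "csi": health.composite_stress_index(bd),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("id")


def _stage_score(cfg: PipelineConfig, counts: dict) -> None:
    path = cfg.resolve("health_csv")
    records = pd.read_csv(path, index_col=0)
    if set(datasets.SCORE_COLUMNS) <= set(records.columns):
        # already a per-parameter score table (e.g. the published cohort)
        table = health.score_table(records)
    else:
        table = _score_records(records, cfg)
    table.to_csv(cfg.resolve("scores_csv"))
    counts["scored_individuals"] = len(table)


def _stage_prep(cfg: PipelineConfig, counts: dict) -> None:
    from allomove.dive import (
        DepthSeries,
        aggregate_hourly,
        detect_dives,
        zero_offset_correct,
    )
    from allomove.raster import AsciiRaster
    from allomove.track import (
        LocationSeries,
        apply_gap_mask,
        distance_to_shore,
        gap_mask,
        steps_and_turns,
    )

    locs = pd.read_csv(cfg.resolve("locations_csv"), parse_dates=["timestamp"])
    fixes_path = cfg.resolve("raw_fixes_csv")
    fixes = (
        pd.read_csv(fixes_path, parse_dates=["timestamp"])
        if fixes_path.exists()
        else None
    )
    depth_path = cfg.resolve("depth_csv")
    depth_all = pd.read_csv(depth_path) if depth_path.exists() else None
    raster_path = cfg.resolve("shore_raster")
    raster = AsciiRaster.read(raster_path) if raster_path.exists() else None
    scores = pd.read_csv(cfg.resolve("scores_csv"), index_col=0)

    out = []
    for ind, g in locs.groupby("id", sort=True):
        raw = None
        if fixes is not None:
            raw = pd.DatetimeIndex(fixes.loc[fixes["id"] == ind, "timestamp"])
        ser = LocationSeries(
            id=str(ind),
            timestamps=pd.DatetimeIndex(g["timestamp"]),
            x=g["x"].to_numpy(),
            y=g["y"].to_numpy(),
            frame=cfg.track.frame,
            raw_fix_times=raw,
        )
        step, turn = steps_and_turns(ser)
        if raw is not None:
            mask = gap_mask(
                ser.timestamps, raw, pd.Timedelta(hours=cfg.track.max_gap_hours)
            )
            step, turn = apply_gap_mask(step, turn, mask)
        T = len(ser)
        if depth_all is not None and (depth_all["id"] == ind).any():
            d = depth_all[depth_all["id"] == ind]
            ds = DepthSeries(d["time_s"].to_numpy(), d["depth_m"].to_numpy())
            corrected = zero_offset_correct(
                ds, cfg.dive.zoc_window_s, cfg.dive.zoc_quantile
            )
            dives = detect_dives(
                corrected, cfg.dive.threshold_m, cfg.dive.bottom_fraction
            )
            max_depth, wiggles = aggregate_hourly(dives, T)
        else:
            max_depth = np.full(T, np.nan)
            wiggles = np.full(T, np.nan)
        if raster is not None:
            dist = distance_to_shore(raster, ser.x, ser.y)
        else:
            dist = np.full(T, np.nan)
        csi = float(scores.loc[str(ind), "csi"]) if str(ind) in scores.index else np.nan
        out.append(
            ObservationSeries(
                id=str(ind),
                csi=csi,
                timestamps=ser.timestamps,
                step=step,
                turn=turn,
                max_depth=max_depth,
                wiggles=wiggles,
                dist_shore=dist,
            )
        )
    ObservationSeries.list_to_csv(out, cfg.resolve("prepped_streams_csv"))
    counts["prepped_rows"] = sum(len(s) for s in out)


def _fit_config(cfg: PipelineConfig, stage: str) -> FitConfig:
    return FitConfig(
        seed=_derive_seed(cfg.seed, stage),
        n_restarts=cfg.hmm.n_restarts,
        ftol=cfg.hmm.ftol,
        perturbation_sd=cfg.hmm.perturbation_sd,
        compute_hessian=cfg.hmm.compute_hessian,
    )


def _full_structure(cfg: PipelineConfig) -> ModelStructure:
    return _variant(
        ModelStructure(
            n_states=cfg.hmm.n_states,
            emissions=DEFAULT_EMISSIONS,
            transition_covariate=True,
            initial=cfg.hmm.initial,
        ),
        cfg.hmm.covariate_structure,
    )


def _stage_fit(cfg: PipelineConfig, counts: dict) -> None:
    series = ObservationSeries.list_from_csv(cfg.resolve("streams_csv"))
    structure = _full_structure(cfg)
    fit = fit_hmm(series, structure, _fit_config(cfg, "fit"))
    payload = {
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_params": fit.n_params,
        "n_restarts_used": fit.n_restarts_used,
        "convergence": fit.convergence,
        "parameters": fit.mle.to_dict(),
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
        "natural_scale": _natural_scale_summary(fit.mle),
        "seed": cfg.seed,
        "version": __version__,
    }
    with open(cfg.resolve("fit_json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    counts["fit_n_params"] = fit.n_params
    if cfg.hmm.aic_table:
        table = compare_models(
            series,
            _full_structure(cfg),
            _fit_config(cfg, "fit"),
            n_states=tuple(cfg.hmm.aic_n_states),
        )
        table.to_csv(cfg.resolve("aic_csv"), index=False)
        counts["aic_cells"] = len(table)


def _natural_scale_summary(params: HMMParameters) -> dict:
    from allomove.hmm.decode import state_names

    names = state_names(params)
    out = {}
    for k, name in enumerate(names):
        entry = {}
        for stream in params.alpha0:
            entry[stream] = {
                "mean_at_c0": params.emission_mean(stream, k, 0.0),
                "sd": params.emission_sd(stream, k),
                "log_mean_slope": float(params.alpha1[stream][k]),
            }
        if params.turn_mean is not None:
            entry["turn"] = {
                "mean_angle": float(params.turn_mean[k]),
                "concentration": params.turn_kappa(k),
            }
        out[name] = entry
    return out


def _load_fit(cfg: PipelineConfig) -> FitResult:
    with open(cfg.resolve("fit_json")) as fh:
        payload = json.load(fh)
    params = HMMParameters.from_dict(payload["parameters"])
    cov = payload.get("covariance")
    return FitResult(
        mle=params,
        loglik=payload["loglik"],
        n_params=payload["n_params"],
        covariance=None if cov is None else np.asarray(cov),
        convergence=payload.get("convergence", {}),
        n_restarts_used=payload.get("n_restarts_used", 0),
    )


def _stage_decode(cfg: PipelineConfig, counts: dict) -> None:
    series = ObservationSeries.list_from_csv(cfg.resolve("streams_csv"))
    fit = _load_fit(cfg)
    decoded_rows, budget_rows = [], []
    for ser in series:
        track = viterbi(fit.mle, ser)
        decoded_rows.append(
            pd.DataFrame(
                {
                    "id": ser.id,
                    "timestamp": ser.timestamps
                    if ser.timestamps is not None
                    else np.arange(len(ser)),
                    "state": track.states,
                    "behaviour": track.named_states,
                }
            )
        )
        budget_rows.append({"id": ser.id, "csi": ser.csi, **track.activity_budget})
    pd.concat(decoded_rows).to_csv(cfg.resolve("decoded_csv"), index=False)
    pd.DataFrame(budget_rows).to_csv(cfg.resolve("budgets_csv"), index=False)
    counts["decoded_rows"] = sum(len(d) for d in decoded_rows)

    grid = np.linspace(0.0, cfg.hmm.curve_grid_max, cfg.hmm.curve_grid_points)
    curves = stationary_curves(fit, grid)
    curves.to_csv(cfg.resolve("curves_csv"), index=False)
    counts["curve_rows"] = len(curves)


def _stage_report(cfg: PipelineConfig, counts: dict) -> None:
    from allomove.report import write_report

    missing = [
        name
        for name in ("streams_csv", "fit_json", "decoded_csv", "budgets_csv", "curves_csv")
        if not cfg.resolve(name).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"run incomplete; missing artefacts: "
            f"{[getattr(cfg.paths, m) for m in missing]}"
        )
    write_report(cfg)
    counts["report"] = 1


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "prep": _stage_prep,
    "fit": _stage_fit,
    "decode": _stage_decode,
    "report": _stage_report,
}

# Outputs that mark a stage as already done (for resuming partial runs).
_STAGE_OUTPUTS = {
    "simulate": ("health_csv", "streams_csv"),
    "score": ("scores_csv",),
    "prep": ("prepped_streams_csv",),
    "fit": ("fit_json",),
    "decode": ("decoded_csv", "budgets_csv", "curves_csv"),
    "report": ("report_md",),
}


def run_stage(cfg: PipelineConfig, stage: str, counts: dict) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    _STAGE_FUNCS[stage](cfg, counts)


def run(cfg: PipelineConfig, resume: bool = True) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    run_dir = Path(cfg.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    for stage in cfg.stages:
        outputs = [cfg.resolve(n) for n in _STAGE_OUTPUTS[stage]]
        if resume and outputs and all(p.exists() for p in outputs):
            log.info("stage %s: outputs exist, skipping (resume)", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            run_stage(cfg, stage, counts)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "stages": cfg.stages,
        "row_counts": counts,
        "config": cfg.model_dump(),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return run_dir
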