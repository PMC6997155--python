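"""Stage orchestration: synthetic/real ingest → trips → FPT/ARS → SDM →
annotation & null model → seasonal inference, with per-stage outputs in a
run directory and a machine-readable summary.

Each stage is a pure function of upstream stage outputs plus the config;
stages write their outputs under ``<outdir>/<stage>/`` so a downstream
stage can be re-run alone and reproduce its files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (idw_annotate, project_suitability, sample_background,
                       simulate_null_points, trip_mean_quality)
from .config import RunConfig
from .fpt import extract_ars, scale_profile, select_scale
from .inference import BetaGAM, fit_trait_model
from .rasters import RasterStack
from .sdm import cross_validate, permutation_importance
from .synthetic import (VARIABLES, EnvScenario, TruthParams, demo_preference,
                        generate_bird_metadata, generate_env,
                        sample_prey_presences, simulate_tracks)
from .trajectory import Trip, dedupe_fixes, rediscretize_all, segment_trips, trips_to_frame

log = logging.getLogger(__name__)

__all__ = ["run", "run_all"]


def _scenario(cfg: RunConfig) -> tuple[EnvScenario, TruthParams]:
    return (EnvScenario(years=tuple(cfg.years), days=cfg.days), TruthParams())


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate environment rasters, tracks, prey presences, metadata."""
    scenario, truth = _scenario(cfg)
    stacks = generate_env(scenario, truth, seed=cfg.seed)
    fixes = simulate_tracks(scenario, truth, stacks, cfg.n_birds,
                            demo_preference, seed=cfg.seed + 1,
                            trip_prob=cfg.trip_prob)
    presences = sample_prey_presences(stacks, truth, cfg.n_presences, seed=cfg.seed + 2)
    metadata = generate_bird_metadata(cfg.n_birds, seed=cfg.seed + 3)
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    for st in stacks.values():
        st.write(d / "rasters")
    fixes.to_csv(d / "fixes.csv", index=False)
    presences.to_csv(d / "presences.csv", index=False)
    metadata.to_csv(d / "metadata.csv", index=False)
    return {"scenario": scenario, "truth": truth, "stacks": stacks,
            "fixes": fixes, "presences": presences, "metadata": metadata}


def load_stacks(outdir: Path) -> dict[str, RasterStack]:
    d = outdir / "simulate" / "rasters"
    return {v: RasterStack.read(d, v) for v in VARIABLES}


def stage_trips(cfg: RunConfig, outdir: Path, fixes: pd.DataFrame,
                colony_xy: tuple[float, float]) -> list[Trip]:
    """Dedupe fixes, isolate complete trips, rediscretize to constant step."""
    fixes = dedupe_fixes(fixes[["bird_id", "timestamp", "x", "y"]])
    trips = segment_trips(fixes, colony_xy, cfg.colony_radius)
    trips = rediscretize_all(trips, cfg.step_length)
    d = outdir / "trips"
    d.mkdir(parents=True, exist_ok=True)
    trips_to_frame(trips).to_csv(d / "trips.csv", index=False)
    return trips


def frame_to_trips(df: pd.DataFrame) -> list[Trip]:
    trips = []
    for tid, sub in df.groupby("trip_id", sort=True):
        sub = sub.sort_values("seq")
        trips.append(Trip(
            bird_id=str(sub["bird_id"].iloc[0]), trip_id=str(tid),
            year=int(sub["year"].iloc[0]), day=int(sub["day"].iloc[0]),
            x=sub["x"].to_numpy(float), y=sub["y"].to_numpy(float),
            t=sub["t"].to_numpy(float),
            step_length=None))
    return trips


def stage_fpt(cfg: RunConfig, outdir: Path, trips: list[Trip]) -> dict:
    """FPT variance profiles, common ARS scale, foraging-point extraction."""
    radii = np.arange(cfg.radius_min, cfg.radius_max + cfg.radius_step / 2,
                      cfg.radius_step)
    profiles = scale_profile(trips, radii)
    scale = select_scale(profiles, rule=cfg.scale_rule)
    ars = extract_ars(trips, scale, cfg.fpt_percentile, cfg.fpt_reference)
    d = outdir / "fpt"
    d.mkdir(parents=True, exist_ok=True)
    pd.concat([p.to_frame() for p in profiles]).to_csv(d / "profiles.csv", index=False)
    (d / "scale.json").write_text(json.dumps({"scale_m": scale}))
    ars.to_csv(d / "ars_points.csv", index=False)
    try:
        from .plots import plot_scale_profile
        plot_scale_profile(profiles, scale, d / "scale_profile.png")
    except Exception as e:
        log.warning("profile plot failed: %s", e)
    return {"profiles": profiles, "scale": scale, "ars": ars}


def stage_sdm(cfg: RunConfig, outdir: Path, presences: pd.DataFrame,
              stacks: dict[str, RasterStack]) -> dict:
    """Annotate prey presences, sample background, fit CV maxent model."""
    pres_ann = idw_annotate(presences, stacks, cfg.idw_k, cfg.idw_power)
    background = sample_background(stacks, cfg.n_background, seed=cfg.seed + 4)
    cv = cross_validate(pres_ann, background, k=cfg.k_folds, lam=cfg.lam,
                        seed=cfg.seed + 5, variables=list(VARIABLES),
                        max_iter=cfg.maxent_max_iter, tol=cfg.maxent_tol)
    # importance on the first fold model (all folds see almost the same data)
    perm = permutation_importance(cv.folds[0], pres_ann, background, seed=cfg.seed + 6)
    contrib = cv.folds[0].percent_contribution()
    d = outdir / "sdm"
    d.mkdir(parents=True, exist_ok=True)
    pres_ann.to_csv(d / "presences_annotated.csv", index=False)
    background.to_csv(d / "background.csv", index=False)
    pd.DataFrame({"fold": range(len(cv.fold_auc)), "auc": cv.fold_auc}).to_csv(
        d / "fold_auc.csv", index=False)
    pd.DataFrame({"percent_contribution": contrib,
                  "permutation_importance": perm}).to_csv(d / "importance.csv")
    (d / "model_fold0.json").write_text(cv.folds[0].to_json())
    _write_suitability_rasters(cv, stacks, d / "suitability")
    return {"cv": cv, "background": background, "pres_ann": pres_ann,
            "contrib": contrib, "perm": perm}


def _write_suitability_rasters(cv, stacks: dict[str, RasterStack],
                               directory: Path) -> None:
    """Averaged cloglog suitability projected on the full grid, per date."""
    g = stacks["sst"].grid
    X, Y = np.meshgrid(g.xcenters, g.ycenters)
    out = RasterStack("suitability", g, {})
    for key in stacks["sst"].days:
        frame = pd.DataFrame({v: stacks[v].layers[key].ravel() for v in VARIABLES})
        out.layers[key] = cv.predict(frame).reshape(g.ny, g.nx)
    out.write(directory)


def stage_annotate(cfg: RunConfig, outdir: Path, ars: pd.DataFrame,
                   stacks: dict[str, RasterStack], cv,
                   colony_xy: tuple[float, float]) -> dict:
    """Null-point simulation, annotation, projection, trip-mean quality."""
    null = simulate_null_points(ars, colony_xy, n=cfg.n_null,
                                seed=cfg.seed + 7, bathy=stacks["bathy"],
                                joint=cfg.null_joint)
    obs_ann = idw_annotate(ars, stacks, cfg.idw_k, cfg.idw_power)
    null_ann = idw_annotate(null, stacks, cfg.idw_k, cfg.idw_power)
    obs_proj = project_suitability(obs_ann, cv)
    null_proj = project_suitability(null_ann, cv)
    sim_tq = trip_mean_quality(null_proj, "simulated")
    sim_tq["bird_id"] = pd.NA  # pseudo-trips carry no individual identity
    tq = pd.concat([trip_mean_quality(obs_proj, "observed"), sim_tq],
                   ignore_index=True)
    d = outdir / "annotate"
    d.mkdir(parents=True, exist_ok=True)
    null.to_csv(d / "null_points.csv", index=False)
    pd.concat([obs_proj.assign(source="observed"),
               null_proj.assign(source="simulated")]).to_csv(
        d / "annotated_points.csv", index=False)
    tq.to_csv(d / "trip_quality.csv", index=False)
    return {"null": null, "trip_quality": tq}


def stage_infer(cfg: RunConfig, outdir: Path, trip_quality: pd.DataFrame,
                metadata: pd.DataFrame) -> dict:
    """Trait mixed model, beta GAM, year contrasts, difference smooth."""
    d = outdir / "infer"
    d.mkdir(parents=True, exist_ok=True)
    obs_tq = trip_quality[trip_quality["group"] == "observed"]
    trait = None
    try:
        trait = fit_trait_model(obs_tq, metadata)
        (d / "trait_model.txt").write_text(str(trait.summary()))
    except Exception as e:  # singular fits on tiny demos are non-fatal
        log.warning("trait model failed: %s", e)
        (d / "trait_model.txt").write_text(f"trait model not fitted: {e}\n")
    gam = BetaGAM(trip_quality, n_knots=cfg.gam_knots)
    res = gam.fit()
    diff = res.difference_smooth()
    years = res.wald_year_contrasts() if len(gam.years) > 1 else pd.DataFrame()
    res.parametric_table().to_csv(d / "parametric_terms.csv")
    res.smooth_table().to_csv(d / "smooth_terms.csv")
    diff.to_csv(d / "difference_smooth.csv", index=False)
    if len(years):
        years.to_csv(d / "year_contrasts.csv", index=False)
    (d / "gam_summary.txt").write_text(res.summary())
    try:
        from .plots import plot_difference_smooth
        plot_difference_smooth(diff, d / "difference_smooth.png")
    except Exception as e:
        log.warning("plotting failed: %s", e)
    return {"gam": res, "diff": diff, "years": years, "trait": trait}


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the run summary; returns stage objects."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    import numpy as _np
    import pandas as _pd
    import scipy as _sp
    (outdir / "run.log").write_text(
        f"forageq {__version__} numpy {_np.__version__} scipy {_sp.__version__} "
        f"pandas {_pd.__version__}\nseed {cfg.seed} config {cfg.digest()}\n")
    if cfg.source != "synthetic":
        raise NotImplementedError(
            "prepared-input ingest expects the synthetic layout; point "
            "source at a previous run directory's simulate/ outputs")
    try:
        sim = stage_simulate(cfg, outdir)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    scenario = sim["scenario"]
    stages = [
        ("trips", lambda: stage_trips(cfg, outdir, sim["fixes"], scenario.colony_xy)),
    ]
    trips = _run_stage(*stages[0])
    fpt_out = _run_stage("fpt", lambda: stage_fpt(cfg, outdir, trips))
    sdm_out = _run_stage("sdm", lambda: stage_sdm(cfg, outdir, sim["presences"], sim["stacks"]))
    ann_out = _run_stage("annotate", lambda: stage_annotate(
        cfg, outdir, fpt_out["ars"], sim["stacks"], sdm_out["cv"], scenario.colony_xy))
    inf_out = _run_stage("infer", lambda: stage_infer(
        cfg, outdir, ann_out["trip_quality"], sim["metadata"]))

    diff = inf_out["diff"]
    sig = diff["significant"].to_numpy()
    res = inf_out["gam"]
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "n_trips": len(trips),
        "n_ars_points": int(len(fpt_out["ars"])),
        "selected_scale_m": float(fpt_out["scale"]),
        "mean_cv_auc": sdm_out["cv"].mean_auc,
        "sd_cv_auc": sdm_out["cv"].sd_auc,
        "percent_contribution": sdm_out["contrib"].round(3).to_dict(),
        "permutation_importance": sdm_out["perm"].round(3).to_dict(),
        "deviance_explained_pct": 100 * res.deviance_explained,
        "fixed_effects_share_pct": 100 * res.fixed_effects_share(),
        "group_coefficient": res.parametric_table().loc["group[observed]"].to_dict(),
        "significant_days_pct": 100.0 * float(sig.mean()),
        "significant_positive_days_pct":
            100.0 * float((sig & (diff["D"] > 0)).mean()),
        "significant_negative_days_pct":
            100.0 * float((sig & (diff["D"] < 0)).mean()),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"summary": summary, "sim": sim, "trips": trips, "fpt": fpt_out,
            "sdm": sdm_out, "annotate": ann_out, "infer": inf_out}


def _run_stage(name, fn):
    log.info("running stage %s", name)
    try:
        return fn()
    except Exception as e:
        raise RuntimeError(f"stage '{name}' failed: {e}") from e


run = run_all
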