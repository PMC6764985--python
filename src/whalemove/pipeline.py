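"""End-to-end pipeline: regularize -> features -> filter -> fit -> select ->
decode -> pool -> summarize.

Each stage failure aborts with a stage-tagged error; every run writes its
artifacts plus a manifest (package version, seed, configuration hash).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .config import PipelineConfig
from .features import regularized_to_series, steps_and_turns, filter_southern_ocean
from .hmm import HMMConfig, fit_hmm, select_model, viterbi
from .pooling import pool_fits
from .regularize import draw_realizations, fit_ssm
from .summaries import (
    load_areas,
    location_states,
    overall_summary,
    track_summary,
)

log = logging.getLogger("whalemove")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def run_pipeline(obs: pd.DataFrame, config: PipelineConfig, outdir) -> dict:
    """Run the full behavioural analysis on an Argos observation table.

    Returns a dict with the fitted models, the selected configuration, the
    pooled estimates and the summary table; writes CSV/JSON artifacts and a
    manifest under ``outdir``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    rng = np.random.default_rng(config.seed)

    try:
        areas = load_areas(config.area_file)
    except Exception as e:  # missing/invalid area file is a config error
        raise StageError("config", e)

    # --- regularize ---------------------------------------------------------
    try:
        fits_ssm, point_tracks = [], []
        for tid, g in obs.groupby("id", sort=True):
            fit = fit_ssm(
                g,
                step_hours=config.step_hours,
                error_sd_km=config.error_sd_km,
                gap_split_days=config.gap_split_days,
            )
            fits_ssm.append(fit)
            point_tracks.append(fit.track)
            log.info("regularized %s: gamma_c=%.3f sigma=%.2f km", tid, fit.gamma_c, fit.sigma_proc_km)
        path = outdir / "tracks_regularized.csv"
        wio.write_tracks_csv(point_tracks, path)
        artifacts.append(path.name)
    except StageError:
        raise
    except Exception as e:
        raise StageError("regularize", e)

    # --- features + Southern Ocean filter ----------------------------------
    try:
        series = regularized_to_series(
            point_tracks, lat_cut=config.lat_cut, step_hours=config.step_hours
        )
        if not series:
            raise ValueError("no track survives the latitude filter")
        path = outdir / "step_turn_series.csv"
        wio.write_series_csv(series, path)
        artifacts.append(path.name)
    except Exception as e:
        raise StageError("features", e)

    # --- fit the four configurations on the point estimate ------------------
    try:
        fits = {}
        for cid in config.configs:
            fits[cid] = fit_hmm(
                series,
                HMMConfig.from_id(cid),
                n_restarts=config.n_restarts,
                seed=rng,
                compute_cov=False,
            )
            log.info("config %d: loglik=%.2f aic=%.2f", cid, fits[cid].loglik, fits[cid].aic)
        best = select_model(fits.values(), criterion=config.criterion)
        import json

        path = outdir / "hmm_fits.json"
        path.write_text(
            json.dumps({str(c): wio.fit_to_json(f) for c, f in fits.items()}, indent=1)
        )
        artifacts.append(path.name)
    except Exception as e:
        raise StageError("fit", e)

    # --- multiple imputation on the best configuration ----------------------
    try:
        imput_fits = []
        for r in range(config.m_realizations):
            real_tracks = []
            for fit in fits_ssm:
                real_tracks.extend(draw_realizations(fit, 1, seed=rng))
            r_series = regularized_to_series(
                real_tracks, lat_cut=config.lat_cut, step_hours=config.step_hours
            )
            imput_fits.append(
                fit_hmm(
                    r_series,
                    best.config,
                    n_restarts=max(2, config.n_restarts // 2),
                    seed=rng,
                    compute_cov=True,
                )
            )
        pooled = pool_fits(imput_fits)
        path = outdir / "pooled_parameters.csv"
        pooled.to_frame().to_csv(path, index=False)
        artifacts.append(path.name)
    except Exception as e:
        raise StageError("pool", e)

    # --- decode + summarize -------------------------------------------------
    try:
        rows = []
        deploys = {str(tid): (g["lon"].iloc[0], g["lat"].iloc[0]) for tid, g in obs.groupby("id")}
        for track in point_tracks:
            filtered = filter_southern_ocean(track, config.lat_cut)
            if filtered is None:
                continue
            s = steps_and_turns(filtered, step_hours=config.step_hours)
            decoded = viterbi(best, s)
            loc_states = location_states(decoded.states, decoded.segment)
            rows.append(
                track_summary(
                    filtered.lonlat[:, 0],
                    filtered.lonlat[:, 1],
                    loc_states,
                    deploy_lonlat=deploys[track.id],
                    areas=areas,
                    track_id=track.id,
                    sex=track.sex,
                    segment=filtered.segment,
                    min_locs=config.min_locs,
                )
            )
        summary = pd.DataFrame(rows)
        path = outdir / "whale_summaries.csv"
        summary.to_csv(path, index=False)
        artifacts.append(path.name)
        overall = overall_summary(summary) if len(summary) >= 2 else {}
    except Exception as e:
        raise StageError("summarize", e)

    manifest = wio.write_manifest(outdir / "manifest.json", config, config.seed, artifacts)
    return {
        "ssm_fits": fits_ssm,
        "hmm_fits": fits,
        "best": best,
        "pooled": pooled,
        "summary": summary,
        "overall": overall,
        "manifest": manifest,
    }
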