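"""CSV readers/writers and run manifests.

All tables are plain CSV with ISO-8601 UTC timestamps.  Dialects:

- Argos observations: id, date, lc, lon, lat
- regularized tracks:  id, sex, realization, segment, date, lon, lat, sd_km
- step/turn series:    id, sex, realization, segment, date, speed_kmh, turn_rad
- pooled parameters:   parameter, state, sex, estimate, lo95, hi95
- catch records:       lon, lat, count, year

Floats are written at full precision so a write/read round trip is lossless
well below 1e-12.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .features import StepTurnSeries
from .params import LOC_CLASSES, SexLabel
from .regularize import RegularizedTrack

_FLOAT_FMT = "%.17g"


def read_argos_csv(path) -> pd.DataFrame:
    obs = pd.read_csv(path, dtype={"id": str, "lc": str})
    required = {"id", "date", "lc", "lon", "lat"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"Argos CSV missing columns: {sorted(missing)}")
    obs["date"] = pd.to_datetime(obs["date"], utc=True)
    bad = set(obs["lc"]) - set(LOC_CLASSES)
    if bad:
        raise ValueError(f"unknown Argos location classes: {sorted(bad)}")
    return obs.sort_values(["id", "date"]).reset_index(drop=True)


def write_argos_csv(obs: pd.DataFrame, path):
    out = obs.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_tracks_csv(tracks: list[RegularizedTrack], path):
    frames = [t.to_frame() for t in tracks]
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks_csv(path) -> list[RegularizedTrack]:
    df = pd.read_csv(path, dtype={"id": str})
    df["date"] = pd.to_datetime(df["date"], utc=True)
    tracks = []
    for (tid, realization), g in df.groupby(["id", "realization"], sort=True):
        g = g.sort_values("date")
        tracks.append(
            RegularizedTrack(
                id=str(tid),
                sex=SexLabel(g["sex"].iloc[0]),
                realization=int(realization),
                times=pd.DatetimeIndex(g["date"]),
                lonlat=g[["lon", "lat"]].to_numpy(),
                pos_sd_km=g["sd_km"].to_numpy(),
                segment=g["segment"].to_numpy(),
            )
        )
    return tracks


def write_series_csv(series_list: list[StepTurnSeries], path):
    out = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path) -> list[StepTurnSeries]:
    df = pd.read_csv(path, dtype={"id": str})
    df["date"] = pd.to_datetime(df["date"], utc=True)
    out = []
    for (tid, realization), g in df.groupby(["id", "realization"], sort=True):
        g = g.sort_values("date")
        out.append(
            StepTurnSeries(
                id=str(tid),
                sex=SexLabel(g["sex"].iloc[0]),
                realization=int(realization),
                times=pd.DatetimeIndex(g["date"]),
                speed=g["speed_kmh"].to_numpy(),
                turn=g["turn_rad"].to_numpy(),
                segment=g["segment"].to_numpy(),
            )
        )
    return out


def read_catches_csv(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    required = {"lon", "lat", "count", "year"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"catch CSV missing columns: {sorted(missing)}")
    return rec


def fit_to_json(fit) -> dict:
    """Serialize a FittedHMM as a JSON-ready dict (working and natural
    scales, likelihood, AIC, convergence)."""
    from .hmm import _natural_vector

    return {
        "config": fit.config.id,
        "names": list(fit.names),
        "working": [float(v) for v in fit.working],
        "natural": {
            k: float(v)
            for k, v in zip(fit.names, _natural_vector(fit.working, fit.config, fit.zero_mass))
        },
        "loglik": float(fit.loglik),
        "n_params": int(fit.n_params),
        "aic": float(fit.aic),
        "converged": bool(fit.converged),
        "n_obs": int(fit.n_obs),
        "n_series": int(fit.n_series),
    }


def write_manifest(path, config, seed: int, artifacts: list[str]):
    """Run manifest: package version, config hash, seed, artifact list."""
    from . import __version__

    manifest = {
        "package": "whalemove",
        "version": __version__,
        "python": platform.python_version(),
        "created_utc": datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        "seed": int(seed),
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "artifacts": sorted(artifacts),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
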