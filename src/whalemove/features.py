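"""Step-speed and turning-angle features for the behavioural HMM.

A regularized track (positions every 6 h) becomes a sequence of steps; each
step carries a speed (great-circle length / hours) and a turning angle (the
signed change between the forward azimuths of consecutive steps, wrapped to
(-pi, pi]).  The first step of every contiguous segment has no preceding
bearing, so its turn is undefined and recorded as NaN; the HMM likelihood
drops the turn term there.

The Southern Ocean filter retains only positions strictly south of the
latitude cut (default 36 deg S, i.e. lat < -36), re-segmenting any run the
filter breaks, so the behavioural model sees migration-phase movement only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .geodesy import great_circle_km, initial_bearing_rad, wrap_angle
from .params import SexLabel

__all__ = [
    "StepTurnSeries",
    "great_circle_km",
    "steps_and_turns",
    "filter_southern_ocean",
]


@dataclass
class StepTurnSeries:
    """Per-step speed/turn series for one track realization.

    All arrays are step-aligned: entry i describes the step leaving position
    i of the (possibly filtered) track.  ``turn`` is NaN on each segment's
    first step and wherever a zero-length step leaves the bearing undefined.
    """

    id: str
    sex: SexLabel
    realization: int
    times: pd.DatetimeIndex  # step start times
    speed: np.ndarray        # km/h
    turn: np.ndarray         # radians in (-pi, pi], NaN where undefined
    segment: np.ndarray      # gap-delimited run index per step

    def __post_init__(self):
        self.speed = np.asarray(self.speed, dtype=float)
        self.turn = np.asarray(self.turn, dtype=float)
        self.segment = np.asarray(self.segment, dtype=int)
        if not (len(self.times) == len(self.speed) == len(self.turn) == len(self.segment)):
            raise ValueError("step arrays must align")
        if np.any(self.speed < 0):
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.speed)

    def segments(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (speeds, turns) per contiguous segment."""
        for s in np.unique(self.segment):
            mask = self.segment == s
            yield self.speed[mask], self.turn[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "sex": self.sex.value,
                "realization": self.realization,
                "segment": self.segment,
                "date": self.times,
                "speed_kmh": self.speed,
                "turn_rad": self.turn,
            }
        )


def _positions_of(track):
    """Duck-typed access: anything with times, lonlat and optionally
    segment/realization (RegularizedTrack, TruePath)."""
    times = pd.DatetimeIndex(track.times)
    lonlat = np.asarray(track.lonlat, dtype=float)
    segment = getattr(track, "segment", None)
    if segment is None:
        segment = np.zeros(len(times), dtype=int)
    realization = int(getattr(track, "realization", 0))
    sex = getattr(track, "sex", SexLabel.unknown)
    return str(track.id), SexLabel(sex), realization, times, lonlat, np.asarray(segment, dtype=int)


def steps_and_turns(track, step_hours: float = 6.0) -> StepTurnSeries:
    """Compute the step/turn series of a regularized (or true) track.

    Speeds use the actual time delta between consecutive positions (normally
    exactly ``step_hours``); turns are differences of successive forward
    azimuths.  Steps never straddle a segment boundary.
    """
    tid, sex, realization, times, lonlat, segment = _positions_of(track)
    spd_parts, trn_parts, t_parts, seg_parts = [], [], [], []
    for s in np.unique(segment):
        idx = np.flatnonzero(segment == s)
        if idx.size < 2:
            continue
        lon = lonlat[idx, 0]
        lat = lonlat[idx, 1]
        tt = times[idx]
        dt_h = np.diff(tt.asi8) / 3.6e12
        d_km = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        speed = d_km / dt_h
        az = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
        turn = np.full(idx.size - 1, np.nan)
        if idx.size > 2:
            turn[1:] = wrap_angle(az[1:] - az[:-1])
        # zero-length steps leave bearings (hence adjacent turns) undefined
        zero = d_km == 0.0
        turn[zero] = np.nan
        if np.any(zero[:-1]):
            turn[1:][zero[:-1]] = np.nan
        spd_parts.append(speed)
        trn_parts.append(turn)
        t_parts.append(tt[:-1])
        seg_parts.append(np.full(idx.size - 1, s))
    if not spd_parts:
        raise ValueError("track has no segment with >= 2 positions")
    tcat = t_parts[0]
    for t in t_parts[1:]:
        tcat = tcat.append(t)
    return StepTurnSeries(
        id=tid,
        sex=sex,
        realization=realization,
        times=tcat,
        speed=np.concatenate(spd_parts),
        turn=np.concatenate(trn_parts),
        segment=np.concatenate(seg_parts),
    )


def filter_southern_ocean(track, lat_cut: float = -36.0):
    """Restrict a track to positions strictly south of ``lat_cut``.

    Returns a shallow track-like object with contiguous retained runs given
    fresh segment indices (a run interrupted by the filter is split), or
    ``None`` if no position survives.  The boundary itself is excluded:
    "beyond 36 deg S" is read as latitude < -36.
    """
    tid, sex, realization, times, lonlat, segment = _positions_of(track)
    keep = lonlat[:, 1] < lat_cut
    if not np.any(keep):
        return None
    idx = np.flatnonzero(keep)
    # new segment wherever the kept run is broken, or the original segment changes
    brk = np.flatnonzero((np.diff(idx) != 1) | (np.diff(segment[idx]) != 0))
    new_seg = np.zeros(idx.size, dtype=int)
    for b in brk:
        new_seg[b + 1 :] += 1

    @dataclass
    class _Filtered:
        id: str
        sex: SexLabel
        realization: int
        times: pd.DatetimeIndex
        lonlat: np.ndarray
        segment: np.ndarray

    return _Filtered(tid, sex, realization, times[idx], lonlat[idx], new_seg)


def regularized_to_series(
    tracks: Iterable, lat_cut: float | None = -36.0, step_hours: float = 6.0
) -> list[StepTurnSeries]:
    """Convenience pipeline: optional Southern Ocean filter then step/turn
    extraction for a collection of tracks; tracks filtered away entirely are
    dropped."""
    out = []
    for track in tracks:
        if lat_cut is not None:
            track = filter_southern_ocean(track, lat_cut)
            if track is None:
                continue
        try:
            out.append(steps_and_turns(track, step_hours=step_hours))
        except ValueError:
            continue
    return out
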