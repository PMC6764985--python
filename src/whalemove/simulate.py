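"""Ground-truthed synthetic track and catch-record generation.

The simulator emulates the study system end to end: a 2-state Markov chain
(transit/resident) switching on a 6-h step grid; per-state gamma step speeds
and wrapped-Cauchy turning angles advanced along great circles on the sphere;
and Argos-style degradation of the true path — irregular observation times
with exponential gaps, six location-quality classes with class-dependent
isotropic positional noise, and optional tag dropout.  Every downstream stage
(state-space regularization, feature extraction, HMM fitting, summaries) is
therefore testable against known ground truth.

Defaults reproduce the study conditions: 6-h steps, switching probabilities
Pr(resident|transit)=0.035 and Pr(transit|resident)=0.017, and per-sex
transit/resident speed means as estimated for the tracked whales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodesy import (
    KM_PER_DEGREE,
    destination_point,
    normalize_lon,
    wrap_angle,
)
from .params import (
    DEFAULT_ARGOS_ERROR_SD_KM,
    LOC_CLASSES,
    RESIDENT,
    TRANSIT,
    GammaParams,
    SexLabel,
    TransitionMatrix,
    WrappedCauchyParams,
)

#: Pooled switching probabilities estimated for the tracked population:
#: Pr(resident | transit), Pr(transit | resident).
DEFAULT_SWITCH_PROBS = (0.035, 0.017)

#: Per-sex emission parameters (transit, resident) used as the default
#: generating values; speed means are the study's pooled estimates and
#: speed SDs default to mu/2.  Turn angles: directed during transit
#: (lam=0, high concentration), reversing during residency (lam=pi, low
#: concentration).
DEFAULT_MOVEMENT_PARAMS: Mapping[SexLabel, dict] = {
    SexLabel.female: {
        "gamma": (GammaParams(5.15, 5.15 / 2), GammaParams(2.15, 2.15 / 2)),
        "wrapped_cauchy": (WrappedCauchyParams(0.0, 0.62), WrappedCauchyParams(np.pi, 0.1)),
    },
    SexLabel.male: {
        "gamma": (GammaParams(3.16, 3.16 / 2), GammaParams(0.89, 0.89 / 2)),
        "wrapped_cauchy": (WrappedCauchyParams(0.0, 0.38), WrappedCauchyParams(np.pi, 0.1)),
    },
    SexLabel.unknown: {
        "gamma": (GammaParams(4.00, 4.00 / 2), GammaParams(0.85, 0.85 / 2)),
        "wrapped_cauchy": (WrappedCauchyParams(0.0, 0.60), WrappedCauchyParams(np.pi, 0.1)),
    },
}

DEFAULT_CLASS_PROBS = {"3": 0.08, "2": 0.12, "1": 0.15, "0": 0.15, "A": 0.25, "B": 0.25}


@dataclass
class TruePath:
    """A simulated true track: regular 6-h positions plus the latent state of
    each step (interval), so ``len(states) == len(times) - 1``."""

    id: str
    sex: SexLabel
    times: pd.DatetimeIndex
    lonlat: np.ndarray  # (n, 2) decimal degrees, lon in [-180, 180)
    states: np.ndarray  # (n-1,) ints over {TRANSIT, RESIDENT}

    def __post_init__(self):
        self.lonlat = np.asarray(self.lonlat, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.times) != len(self.lonlat):
            raise ValueError("times and lonlat must have equal length")
        if len(self.states) != len(self.times) - 1:
            raise ValueError("need exactly one latent state per step (n_positions - 1)")
        if np.any(np.abs(self.lonlat[:, 1]) > 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")

    def to_frame(self) -> pd.DataFrame:
        """True path as a tidy frame; the state is attached to the step
        *leaving* each position (last row has no state)."""
        state = np.append(self.states.astype(float), np.nan)
        return pd.DataFrame(
            {
                "id": self.id,
                "sex": self.sex.value,
                "date": self.times,
                "lon": self.lonlat[:, 0],
                "lat": self.lonlat[:, 1],
                "state": state,
            }
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_wrapped_cauchy(p: WrappedCauchyParams, size, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the wrapped Cauchy distribution, in (-pi, pi]."""
    u = rng.uniform(size=size)
    # quantile of the zero-centred wrapped Cauchy; kappa=0 reduces to uniform
    ratio = (1.0 - p.kappa) / (1.0 + p.kappa)
    theta = 2.0 * np.arctan(ratio * np.tan(np.pi * (u - 0.5)))
    return wrap_angle(p.lam + theta)


def simulate_state_sequence(
    tm: TransitionMatrix,
    n_steps: int,
    initial: str | int = "stationary",
    seed=None,
) -> np.ndarray:
    """Simulate a latent behavioural state sequence.

    Parameters
    ----------
    tm : TransitionMatrix
    n_steps : int
        Number of 6-h steps; must be >= 1.
    initial : "stationary", "transit", "resident" or state index
        Start state, or draw it from the stationary distribution (default).
    seed : int, Generator or None
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = _as_rng(seed)
    p = tm.p
    if initial == "stationary":
        from .hmm import stationary_distribution

        pi = stationary_distribution(tm)
        state = int(rng.choice(2, p=pi))
    elif initial in ("transit", TRANSIT):
        state = TRANSIT
    elif initial in ("resident", RESIDENT):
        state = RESIDENT
    else:
        raise ValueError(f"unrecognized initial state {initial!r}")
    out = np.empty(n_steps, dtype=int)
    out[0] = state
    u = rng.uniform(size=n_steps - 1)
    for i in range(1, n_steps):
        # stay/switch by inverse CDF on the current row
        out[i] = (
            out[i - 1] if u[i - 1] < p[out[i - 1], out[i - 1]] else 1 - out[i - 1]
        )
    return out


def simulate_movement_path(
    states: Sequence[int],
    gamma: tuple[GammaParams, GammaParams],
    wrapped_cauchy: tuple[WrappedCauchyParams, WrappedCauchyParams],
    start_lonlat: tuple[float, float] = (112.0, -22.0),
    initial_bearing_rad: float = np.pi,  # due south
    start_time: str | pd.Timestamp = "2016-09-15T00:00:00Z",
    step_hours: float = 6.0,
    seed=None,
    track_id: str = "sim",
    sex: SexLabel = SexLabel.unknown,
) -> TruePath:
    """Advance a correlated-walk path along great circles under a given state
    sequence.

    Each step's length is a per-state gamma speed draw (km/h) times
    ``step_hours``; each step's heading is the previous heading plus a
    per-state wrapped-Cauchy turn.  The first step's heading is the supplied
    initial bearing (the turn distribution needs a reference direction).
    """
    states = np.asarray(states, dtype=int)
    if states.size < 1:
        raise ValueError("need at least one step")
    lon0, lat0 = start_lonlat
    if abs(lat0) > 89.5:
        raise ValueError("start latitude beyond +/-89.5 deg: bearings degenerate at the poles")
    rng = _as_rng(seed)
    n = states.size
    speeds = np.empty(n)
    turns = np.empty(n)
    for s in (TRANSIT, RESIDENT):
        mask = states == s
        k = int(mask.sum())
        if k:
            g = gamma[s]
            speeds[mask] = rng.gamma(shape=g.shape, scale=g.scale, size=k)
            turns[mask] = sample_wrapped_cauchy(wrapped_cauchy[s], k, rng)

    lons = np.empty(n + 1)
    lats = np.empty(n + 1)
    lons[0], lats[0] = normalize_lon(lon0), lat0
    bearing = float(initial_bearing_rad)
    for i in range(n):
        if i > 0:
            bearing = float(wrap_angle(bearing + turns[i]))
        lons[i + 1], lats[i + 1] = destination_point(
            lons[i], lats[i], bearing, speeds[i] * step_hours
        )
    start = pd.Timestamp(start_time)
    times = start + pd.to_timedelta(np.arange(n + 1) * step_hours, unit="h")
    return TruePath(
        id=track_id, sex=sex, times=pd.DatetimeIndex(times), lonlat=np.column_stack([lons, lats]), states=states
    )


def interpolate_path(path: TruePath, at_times: pd.DatetimeIndex) -> np.ndarray:
    """Positions on the true path at arbitrary times within its span,
    interpolating along the great circle of each bracketing segment."""
    t = path.times.asi8.astype(float)
    q = pd.DatetimeIndex(at_times).asi8.astype(float)
    if q.size and (q.min() < t[0] or q.max() > t[-1]):
        raise ValueError("interpolation times outside the path's time span")
    idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, len(t) - 2)
    w = (q - t[idx]) / (t[idx + 1] - t[idx])
    lon_a, lat_a = path.lonlat[idx, 0], path.lonlat[idx, 1]
    lon_b, lat_b = path.lonlat[idx + 1, 0], path.lonlat[idx + 1, 1]
    from .geodesy import great_circle_km, initial_bearing_rad as fwd_az

    d = great_circle_km(lon_a, lat_a, lon_b, lat_b)
    az = fwd_az(lon_a, lat_a, lon_b, lat_b)
    lon, lat = destination_point(lon_a, lat_a, az, w * d)
    same = d == 0.0
    lon = np.where(same, lon_a, lon)
    lat = np.where(same, lat_a, lat)
    return np.column_stack([lon, lat])


def degrade_to_argos(
    path: TruePath,
    class_probs: Mapping[str, float] | None = None,
    error_sd_km: Mapping[str, float] | None = None,
    mean_gap_hours: float = 2.0,
    dropout_time: pd.Timestamp | None = None,
    seed=None,
) -> pd.DataFrame:
    """Observe a true path the way an Argos tag would.

    Observation times are drawn with exponential gaps of the given mean
    within the path's span (truncated at ``dropout_time`` if the tag fails);
    each fix gets a location class drawn from ``class_probs`` and isotropic
    Gaussian positional error with that class's SD in km, converted to
    degrees at the local latitude.

    Returns a frame with columns id, date, lc, lon, lat, sorted by time.
    """
    if len(path.times) == 0:
        raise ValueError("cannot degrade an empty path")
    if mean_gap_hours <= 0:
        raise ValueError("mean_gap_hours must be positive")
    class_probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    error_sd_km = dict(error_sd_km or DEFAULT_ARGOS_ERROR_SD_KM)
    for lc, sd in error_sd_km.items():
        if sd < 0:
            raise ValueError(f"negative error SD for class {lc}")
    rng = _as_rng(seed)

    t0, t1 = path.times[0], path.times[-1]
    if dropout_time is not None:
        t1 = min(t1, pd.Timestamp(dropout_time))
    span_h = (t1 - t0).total_seconds() / 3600.0
    # draw enough exponential gaps to cover the span, then truncate
    n_guess = max(16, int(2 * span_h / mean_gap_hours) + 16)
    gaps = rng.exponential(scale=mean_gap_hours, size=n_guess)
    while gaps.sum() < span_h:
        gaps = np.concatenate([gaps, rng.exponential(scale=mean_gap_hours, size=n_guess)])
    offsets = np.cumsum(gaps)
    offsets = offsets[offsets <= span_h]
    times = t0 + pd.to_timedelta(offsets, unit="h")
    times = pd.DatetimeIndex([t0]).append(pd.DatetimeIndex(times))

    truth = interpolate_path(path, times)
    classes = np.array(list(class_probs.keys()))
    probs = np.array(list(class_probs.values()), dtype=float)
    probs = probs / probs.sum()
    lc = rng.choice(classes, size=len(times), p=probs)
    sd_km = np.array([error_sd_km[c] for c in lc])
    dx_km = rng.normal(size=len(times)) * sd_km
    dy_km = rng.normal(size=len(times)) * sd_km
    lat = truth[:, 1] + dy_km / KM_PER_DEGREE
    lon = truth[:, 0] + dx_km / (KM_PER_DEGREE * np.cos(np.radians(truth[:, 1])))
    return pd.DataFrame(
        {
            "id": path.id,
            "date": times,
            "lc": pd.Categorical(lc, categories=list(LOC_CLASSES)),
            "lon": normalize_lon(lon),
            "lat": lat,
        }
    )


def simulate_track(
    track_id: str,
    sex: SexLabel,
    n_steps: int = 425,
    switch_probs: tuple[float, float] = DEFAULT_SWITCH_PROBS,
    movement_params: Mapping | None = None,
    start_lonlat: tuple[float, float] = (100.0, -50.0),
    seed=None,
    **path_kwargs,
) -> TruePath:
    """Convenience wrapper: state sequence + movement path with the default
    study-condition parameters for the given sex.

    The default start sits in the Southern Ocean study domain (the
    behavioural model applies south of 36 deg S): the switching walk is
    stationary, with no net migratory drift, so tracks remain in the
    vicinity of their start."""
    rng = _as_rng(seed)
    tm = TransitionMatrix.from_switch_probs(*switch_probs)
    # the initial state is drawn from the stationary law so simulated chains
    # satisfy the stationarity assumption the HMM likelihood encodes
    states = simulate_state_sequence(tm, n_steps, initial="stationary", seed=rng)
    mp = (movement_params or DEFAULT_MOVEMENT_PARAMS)[sex]
    return simulate_movement_path(
        states,
        gamma=mp["gamma"],
        wrapped_cauchy=mp["wrapped_cauchy"],
        start_lonlat=start_lonlat,
        seed=rng,
        track_id=track_id,
        sex=sex,
        **path_kwargs,
    )


def simulate_catches(
    n_records: int,
    lon_window: tuple[float, float] = (0.0, 150.0),
    lat_window: tuple[float, float] = (-70.0, -36.0),
    year_range: tuple[int, int] = (1929, 1968),
    intensity: np.ndarray | None = None,
    seed=None,
) -> pd.DataFrame:
    """Synthetic whale-catch records for the gridding stage.

    Records fall uniformly in the half-open lon/lat windows, or follow a
    supplied relative-intensity surface over 1x1-degree cells (row = lat cell
    from the south edge, column = lon cell from the west edge).  Counts per
    record are 1-5 whales.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    lo_lon, hi_lon = lon_window
    lo_lat, hi_lat = lat_window
    if not (hi_lon > lo_lon and hi_lat > lo_lat):
        raise ValueError("degenerate lon/lat window")
    rng = _as_rng(seed)
    if intensity is None:
        lon = rng.uniform(lo_lon, hi_lon, size=n_records)
        lat = rng.uniform(lo_lat, hi_lat, size=n_records)
    else:
        intensity = np.asarray(intensity, dtype=float)
        n_lat = int(round(hi_lat - lo_lat))
        n_lon = int(round(hi_lon - lo_lon))
        if intensity.shape != (n_lat, n_lon):
            raise ValueError(
                f"intensity surface must be {(n_lat, n_lon)} for these windows"
            )
        flat = intensity.ravel()
        cells = rng.choice(flat.size, size=n_records, p=flat / flat.sum())
        ilat, ilon = np.unravel_index(cells, intensity.shape)
        lon = lo_lon + ilon + rng.uniform(size=n_records)
        lat = lo_lat + ilat + rng.uniform(size=n_records)
    return pd.DataFrame(
        {
            "lon": normalize_lon(lon),
            "lat": lat,
            "count": rng.integers(1, 6, size=n_records),
            "year": rng.integers(year_range[0], year_range[1] + 1, size=n_records),
        }
    )
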