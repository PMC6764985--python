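"""Two-state movement hidden Markov model with sex-covariate structure.

States are ``transit`` (index 0) and ``resident`` (index 1).  Per state the
emissions are a gamma distribution for step speed (parameterized by mean mu
and SD sigma, km/h) and a wrapped Cauchy distribution for turning angle
(mean angle lam, concentration kappa).  The latent chain has per-step
transition probabilities; its stationary distribution supplies the initial
state weights.

Four model configurations express how sex (female / male / unknown) enters:

1. no sex effects;
2. sex-dependent transition probabilities;
3. sex-dependent movement (emission) parameters;
4. both.

Fitting maximizes the joint likelihood over all animals (segments are
independent sequences sharing parameters) by quasi-Newton optimization on
working scales: log mu, log sigma, logit kappa, logit transition
probabilities, and an unconstrained angle for lam that is wrapped to
(-pi, pi] on output (the likelihood is periodic in lam, so the unconstrained
parameterization is smooth everywhere, including at the resident state's
near-pi mean turn, where a tangent-type link would diverge).  States are
identified after fitting by ordering mean transit speed above mean resident
speed.  Exact zero speeds, for which the gamma density is undefined, receive
an estimated per-state point mass; the corresponding parameters are only
added when the data contain zeros.

The forward and Viterbi inner recursions are numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy import optimize
from scipy.special import expit, gammaln, logit

from .features import StepTurnSeries
from .geodesy import wrap_angle
from .params import (
    RESIDENT,
    SEX_LEVELS,
    TRANSIT,
    GammaParams,
    SexLabel,
    TransitionMatrix,
    WrappedCauchyParams,
)

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# densities

def gamma_density(x, p: GammaParams):
    """Gamma pdf of step speed under the mean/SD parameterization
    (shape = mu^2/sigma^2, scale = sigma^2/mu).  Defined for x > 0."""
    return np.exp(gamma_logpdf(x, p.mu, p.sigma))


def gamma_logpdf(x, mu, sigma):
    x = np.asarray(x, dtype=float)
    k = mu * mu / (sigma * sigma)
    theta = sigma * sigma / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (k - 1.0) * np.log(x) - x / theta - k * np.log(theta) - gammaln(k)
    return out


def wrapped_cauchy_density(theta, p: WrappedCauchyParams):
    """Wrapped Cauchy pdf on (-pi, pi]:
    f(t) = (1 - kappa^2) / (2 pi (1 + kappa^2 - 2 kappa cos(t - lam)))."""
    return np.exp(wrapped_cauchy_logpdf(theta, p.lam, p.kappa))


def wrapped_cauchy_logpdf(theta, lam, kappa):
    if not (0.0 <= kappa < 1.0):
        raise ValueError(f"kappa must be in [0, 1), got {kappa}")
    theta = np.asarray(theta, dtype=float)
    return (
        np.log1p(-kappa * kappa)
        - np.log(2.0 * np.pi)
        - np.log1p(kappa * kappa - 2.0 * kappa * np.cos(theta - lam))
    )


def stationary_distribution(tm: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a 2-state chain: pi @ Gamma = pi.

    Closed form: pi_resident = p_TR / (p_TR + p_RT).  Rejects reducible
    chains (either switching probability zero)."""
    p = tm.p if isinstance(tm, TransitionMatrix) else np.asarray(tm, dtype=float)
    ptr = p[TRANSIT, RESIDENT]
    prt = p[RESIDENT, TRANSIT]
    if ptr <= 0.0 or prt <= 0.0:
        raise ValueError("chain is reducible: both switching probabilities must be > 0")
    pi_res = ptr / (ptr + prt)
    return np.array([1.0 - pi_res, pi_res])


# ---------------------------------------------------------------------------
# configuration and parameter bookkeeping

@dataclass(frozen=True)
class HMMConfig:
    """One of the four sex-covariate configurations."""

    id: int
    sex_on_transitions: bool
    sex_on_movement: bool

    _TABLE = {1: (False, False), 2: (True, False), 3: (False, True), 4: (True, True)}

    @classmethod
    def from_id(cls, cid: int) -> "HMMConfig":
        if cid not in cls._TABLE:
            raise ValueError("config id must be 1..4")
        t, m = cls._TABLE[cid]
        return cls(id=cid, sex_on_transitions=t, sex_on_movement=m)

    @property
    def n_movement_blocks(self) -> int:
        return 3 if self.sex_on_movement else 1

    @property
    def n_transition_blocks(self) -> int:
        return 3 if self.sex_on_transitions else 1

    def n_params(self, zero_mass: bool = False) -> int:
        return 8 * self.n_movement_blocks + 2 * self.n_transition_blocks + (2 if zero_mass else 0)


ALL_CONFIGS = tuple(HMMConfig.from_id(i) for i in (1, 2, 3, 4))

_STATE_TAG = ("transit", "resident")


def _param_names(config: HMMConfig, zero_mass: bool) -> list[str]:
    names = []
    mb = [s.value for s in SEX_LEVELS] if config.sex_on_movement else ["all"]
    tb = [s.value for s in SEX_LEVELS] if config.sex_on_transitions else ["all"]
    for b in mb:
        for st in _STATE_TAG:
            names += [f"mu[{st},{b}]", f"sigma[{st},{b}]"]
        for st in _STATE_TAG:
            names += [f"lambda[{st},{b}]", f"kappa[{st},{b}]"]
    for b in tb:
        names += [f"p_tr[{b}]", f"p_rt[{b}]"]
    if zero_mass:
        names += ["p_zero[transit]", "p_zero[resident]"]
    return names


@dataclass
class StateParams:
    """Natural-scale parameters applying to one animal (one sex level)."""

    gamma: tuple[GammaParams, GammaParams]
    wrapped_cauchy: tuple[WrappedCauchyParams, WrappedCauchyParams]
    tm: TransitionMatrix
    delta: np.ndarray | None = None  # None -> stationary distribution
    zero_mass: tuple[float, float] = (0.0, 0.0)

    def initial_distribution(self) -> np.ndarray:
        if self.delta is not None:
            return np.asarray(self.delta, dtype=float)
        return stationary_distribution(self.tm)


def _sex_index(sex: SexLabel) -> int:
    return SEX_LEVELS.index(SexLabel(sex))


def _unpack(working: np.ndarray, config: HMMConfig, zero_mass: bool) -> dict[SexLabel, StateParams]:
    """Working-scale vector -> natural StateParams per sex level."""
    w = np.asarray(working, dtype=float)
    nmb, ntb = config.n_movement_blocks, config.n_transition_blocks
    out = {}
    if zero_mass:
        pz = (float(expit(w[-2])), float(expit(w[-1])))
    else:
        pz = (0.0, 0.0)
    for sex in SEX_LEVELS:
        bm = _sex_index(sex) if config.sex_on_movement else 0
        bt = _sex_index(sex) if config.sex_on_transitions else 0
        o = 8 * bm
        gam = (
            GammaParams(math.exp(w[o + 0]), math.exp(w[o + 1])),
            GammaParams(math.exp(w[o + 2]), math.exp(w[o + 3])),
        )
        wc = (
            WrappedCauchyParams(wrap_angle(w[o + 4]), float(expit(w[o + 5]))),
            WrappedCauchyParams(wrap_angle(w[o + 6]), float(expit(w[o + 7]))),
        )
        ot = 8 * nmb + 2 * bt
        tm = TransitionMatrix.from_switch_probs(float(expit(w[ot])), float(expit(w[ot + 1])))
        out[sex] = StateParams(gamma=gam, wrapped_cauchy=wc, tm=tm, zero_mass=pz)
    return out


# ---------------------------------------------------------------------------
# data packing and compiled recursions

@dataclass
class _SexBlockData:
    speed: np.ndarray
    turn: np.ndarray       # NaN where undefined
    seg_start: np.ndarray
    seg_len: np.ndarray


def _pack(series_list: Sequence[StepTurnSeries]) -> dict[SexLabel, _SexBlockData]:
    by_sex: dict[SexLabel, list] = {}
    for series in series_list:
        if len(series) == 0:
            raise ValueError("empty step/turn series")
        by_sex.setdefault(SexLabel(series.sex), []).append(series)
    packed = {}
    for sex, group in by_sex.items():
        speeds, turns, starts, lens = [], [], [], []
        offset = 0
        for series in group:
            for spd, trn in series.segments():
                speeds.append(spd)
                turns.append(trn)
                starts.append(offset)
                lens.append(len(spd))
                offset += len(spd)
        packed[sex] = _SexBlockData(
            speed=np.concatenate(speeds),
            turn=np.concatenate(turns),
            seg_start=np.asarray(starts, dtype=np.int64),
            seg_len=np.asarray(lens, dtype=np.int64),
        )
    return packed


@njit(cache=True)
def _forward_nb(ld0, ld1, seg_start, seg_len, g00, g01, g10, g11, d0, d1):
    total = 0.0
    for si in range(seg_start.shape[0]):
        s0 = seg_start[si]
        L = seg_len[si]
        m = ld0[s0] if ld0[s0] > ld1[s0] else ld1[s0]
        a0 = d0 * math.exp(ld0[s0] - m)
        a1 = d1 * math.exp(ld1[s0] - m)
        c = a0 + a1
        if c < _LOG_FLOOR:
            return -np.inf
        total += math.log(c) + m
        a0 /= c
        a1 /= c
        for t in range(s0 + 1, s0 + L):
            m = ld0[t] if ld0[t] > ld1[t] else ld1[t]
            e0 = math.exp(ld0[t] - m)
            e1 = math.exp(ld1[t] - m)
            b0 = (a0 * g00 + a1 * g10) * e0
            b1 = (a0 * g01 + a1 * g11) * e1
            c = b0 + b1
            if c < _LOG_FLOOR:
                return -np.inf
            total += math.log(c) + m
            a0 = b0 / c
            a1 = b1 / c
    return total


@njit(cache=True)
def _viterbi_nb(ld0, ld1, lg00, lg01, lg10, lg11, ld_init0, ld_init1):
    """Most probable state path for one segment (log-space); ties resolved
    toward transit (state 0)."""
    L = ld0.shape[0]
    back = np.zeros((L, 2), dtype=np.int8)
    v0 = ld_init0 + ld0[0]
    v1 = ld_init1 + ld1[0]
    for t in range(1, L):
        c00 = v0 + lg00
        c10 = v1 + lg10
        if c00 >= c10:
            n0, b0 = c00, 0
        else:
            n0, b0 = c10, 1
        c01 = v0 + lg01
        c11 = v1 + lg11
        if c01 >= c11:
            n1, b1 = c01, 0
        else:
            n1, b1 = c11, 1
        v0 = n0 + ld0[t]
        v1 = n1 + ld1[t]
        back[t, 0] = b0
        back[t, 1] = b1
    path = np.empty(L, dtype=np.int8)
    path[L - 1] = 0 if v0 >= v1 else 1
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _emission_logdens(data: _SexBlockData, sp: StateParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-step log emission density for each state; missing turns contribute
    the speed term only."""
    out = []
    zero = data.speed == 0.0
    has_turn = np.isfinite(data.turn)
    for s in (TRANSIT, RESIDENT):
        g = sp.gamma[s]
        wc = sp.wrapped_cauchy[s]
        pz = sp.zero_mass[s]
        ld = np.where(
            zero,
            np.log(pz) if pz > 0 else -np.inf,
            (np.log1p(-pz) if pz > 0 else 0.0)
            + gamma_logpdf(np.where(zero, 1.0, data.speed), g.mu, g.sigma),
        )
        ld = ld + np.where(
            has_turn,
            wrapped_cauchy_logpdf(np.where(has_turn, data.turn, 0.0), wc.lam, wc.kappa),
            0.0,
        )
        out.append(ld)
    return out[0], out[1]


def forward_loglik(
    series_list: Sequence[StepTurnSeries] | StepTurnSeries,
    params: Mapping[SexLabel, StateParams] | StateParams,
) -> float:
    """Scaled-forward log-likelihood of one or more step/turn series.

    ``params`` is either a single :class:`StateParams` applied to every
    animal, or a mapping from sex level to :class:`StateParams`.  Segments
    are independent sequences; animals sum their log-likelihoods.
    """
    if isinstance(series_list, StepTurnSeries):
        series_list = [series_list]
    packed = _pack(series_list)
    total = 0.0
    for sex, data in packed.items():
        sp = params[sex] if isinstance(params, Mapping) else params
        if np.all(~np.isfinite(data.turn)) and data.speed.size == 0:
            raise ValueError("series has no usable observations")
        ld0, ld1 = _emission_logdens(data, sp)
        g = sp.tm.p
        delta = sp.initial_distribution()
        total += float(
            _forward_nb(
                ld0, ld1, data.seg_start, data.seg_len,
                g[0, 0], g[0, 1], g[1, 0], g[1, 1], delta[0], delta[1],
            )
        )
    return total


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class FittedHMM:
    """A converged maximum-likelihood fit of one configuration."""

    config: HMMConfig
    working: np.ndarray
    names: list[str]
    loglik: float
    n_params: int
    converged: bool
    zero_mass: bool
    n_obs: int
    n_series: int
    sex_levels: tuple
    cov: np.ndarray | None = field(default=None, repr=False)

    def params_for_sex(self, sex: SexLabel) -> StateParams:
        return _unpack(self.working, self.config, self.zero_mass)[SexLabel(sex)]

    def natural(self) -> dict[str, float]:
        """All parameters on their natural scales, keyed by name."""
        return dict(zip(self.names, _natural_vector(self.working, self.config, self.zero_mass)))

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik


def _natural_vector(working, config, zero_mass):
    w = np.asarray(working, dtype=float)
    out = np.empty_like(w)
    nmb = config.n_movement_blocks
    for b in range(nmb):
        o = 8 * b
        out[o : o + 4] = np.exp(w[o : o + 4])
        out[o + 4] = wrap_angle(w[o + 4])
        out[o + 5] = expit(w[o + 5])
        out[o + 6] = wrap_angle(w[o + 6])
        out[o + 7] = expit(w[o + 7])
    rest = slice(8 * nmb, None)
    out[rest] = expit(w[rest])
    return out


def aic(fit: FittedHMM) -> float:
    """Akaike information criterion: 2 k - 2 log L."""
    return fit.aic


def select_model(fits: Iterable[FittedHMM], criterion: str = "aic") -> FittedHMM:
    """Pick the best-supported configuration; ties go to fewer parameters.

    All fits must be on the same data (checked via n_obs / n_series)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    key_data = {(f.n_obs, f.n_series) for f in fits}
    if len(key_data) != 1:
        raise ValueError("model selection requires fits on identical data")
    if criterion == "aic":
        score = lambda f: f.aic
    elif criterion == "bic":
        score = lambda f: f.bic()
    else:
        raise ValueError("criterion must be 'aic' or 'bic'")
    return min(fits, key=lambda f: (score(f), f.n_params))


# ---------------------------------------------------------------------------
# fitting

def _initial_working(packed, config, zero_mass, rng, jitter: float) -> np.ndarray:
    all_speed = np.concatenate([d.speed for d in packed.values()])
    all_speed = all_speed[all_speed > 0]
    med = np.median(all_speed)
    hi = all_speed[all_speed >= med]
    lo = all_speed[all_speed < med]
    mu_t = max(hi.mean(), 1e-3)
    mu_r = max(lo.mean(), 1e-3)
    sd_t = max(hi.std(), mu_t / 4)
    sd_r = max(lo.std(), mu_r / 4)
    block = [
        math.log(mu_t), math.log(sd_t), math.log(mu_r), math.log(sd_r),
        0.0, logit(0.5), math.pi, logit(0.1),
    ]
    w = block * config.n_movement_blocks + [logit(0.05), logit(0.05)] * config.n_transition_blocks
    if zero_mass:
        w += [logit(0.01), logit(0.01)]
    w = np.asarray(w, dtype=float)
    if jitter > 0:
        w = w + rng.normal(scale=jitter, size=w.size)
    return w


def _swap_states(working: np.ndarray, config: HMMConfig, zero_mass: bool) -> np.ndarray:
    """Relabel the two states throughout the working vector."""
    w = working.copy()
    nmb = config.n_movement_blocks
    for b in range(nmb):
        o = 8 * b
        w[[o, o + 1, o + 2, o + 3]] = w[[o + 2, o + 3, o, o + 1]]
        w[[o + 4, o + 5, o + 6, o + 7]] = w[[o + 6, o + 7, o + 4, o + 5]]
    for b in range(config.n_transition_blocks):
        o = 8 * nmb + 2 * b
        w[[o, o + 1]] = w[[o + 1, o]]
    if zero_mass:
        w[[-2, -1]] = w[[-1, -2]]
    return w


def _numerical_hessian(f, x, h=1e-4):
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        for j in range(i, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


def fit_hmm(
    series_list: Sequence[StepTurnSeries],
    config: HMMConfig | int,
    n_restarts: int = 10,
    seed=None,
    compute_cov: bool = True,
    maxiter: int = 600,
) -> FittedHMM:
    """Maximum-likelihood fit of one HMM configuration to a series set.

    The pooled log-likelihood over all animals is maximized by L-BFGS-B on
    the working scale, taking the best of ``n_restarts`` jittered
    initializations (the first is unjittered, moment-based).  The initial
    state distribution is fixed at the stationary distribution of the
    (sex-appropriate) transition matrix.  After fitting, states are
    relabelled if needed so that mean transit speed exceeds mean resident
    speed.  Collapsed states (kappa -> 1 with sigma -> 0) are flagged via
    ``converged=False``.
    """
    if isinstance(config, int):
        config = HMMConfig.from_id(config)
    series_list = list(series_list)
    if len(series_list) < 2:
        raise ValueError("need at least two series to fit across individuals")
    packed = _pack(series_list)
    if (config.sex_on_movement or config.sex_on_transitions) and len(packed) < 3:
        missing = set(SEX_LEVELS) - set(packed)
        raise ValueError(
            f"config {config.id} uses sex but levels {sorted(s.value for s in missing)} are absent"
        )
    zero_mass = any(np.any(d.speed == 0.0) for d in packed.values())
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    sex_order = [s for s in SEX_LEVELS if s in packed]
    data_by_sex = [packed[s] for s in sex_order]
    emis_inputs = data_by_sex

    def nll(w):
        try:
            by_sex = _unpack(w, config, zero_mass)
        except (ValueError, OverflowError):
            return 1e12
        total = 0.0
        for sex, data in zip(sex_order, emis_inputs):
            sp = by_sex[sex]
            ld0, ld1 = _emission_logdens(data, sp)
            g = sp.tm.p
            try:
                delta = stationary_distribution(sp.tm)
            except ValueError:
                return 1e12
            ll = _forward_nb(
                ld0, ld1, data.seg_start, data.seg_len,
                g[0, 0], g[0, 1], g[1, 0], g[1, 1], delta[0], delta[1],
            )
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    best = None
    for r in range(max(1, n_restarts)):
        x0 = _initial_working(packed, config, zero_mass, rng, jitter=0.0 if r == 0 else 0.4)
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("all restarts failed to produce a finite likelihood")

    working = best.x.copy()
    params = _unpack(working, config, zero_mass)
    mu_t = np.mean([params[s].gamma[TRANSIT].mu for s in sex_order])
    mu_r = np.mean([params[s].gamma[RESIDENT].mu for s in sex_order])
    perm = None
    if mu_r > mu_t:
        working = _swap_states(working, config, zero_mass)
        d = working.size
        perm = np.arange(d)
        nmb = config.n_movement_blocks
        for b in range(nmb):
            o = 8 * b
            perm[[o, o + 1, o + 2, o + 3]] = [o + 2, o + 3, o, o + 1]
            perm[[o + 4, o + 5, o + 6, o + 7]] = [o + 6, o + 7, o + 4, o + 5]
        for b in range(config.n_transition_blocks):
            o = 8 * nmb + 2 * b
            perm[[o, o + 1]] = [o + 1, o]
        if zero_mass:
            perm[[-2, -1]] = [d - 1, d - 2]

    params = _unpack(working, config, zero_mass)
    collapsed = any(
        sp.wrapped_cauchy[s].kappa > 0.995 and sp.gamma[s].sigma < 1e-4
        for sp in params.values()
        for s in (TRANSIT, RESIDENT)
    )
    converged = bool(best.success or best.fun < 1e11) and not collapsed

    cov = None
    if compute_cov:
        H = _numerical_hessian(nll, best.x)
        try:
            cov = np.linalg.pinv(H)
            if perm is not None:
                cov = cov[np.ix_(perm, perm)]
        except np.linalg.LinAlgError:
            cov = None

    n_obs = sum(int(d.speed.size) for d in packed.values())
    return FittedHMM(
        config=config,
        working=working,
        names=_param_names(config, zero_mass),
        loglik=-float(best.fun),
        n_params=config.n_params(zero_mass),
        converged=converged,
        zero_mass=zero_mass,
        n_obs=n_obs,
        n_series=len(series_list),
        sex_levels=tuple(sex_order),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# decoding

@dataclass
class StateSequence:
    """Decoded behavioural states, step-aligned with a StepTurnSeries."""

    states: np.ndarray       # Viterbi path (ints)
    posteriors: np.ndarray   # (n, 2) forward-backward state probabilities
    segment: np.ndarray

    @property
    def pct_resident(self) -> float:
        return 100.0 * float(np.mean(self.states == RESIDENT))


def viterbi(
    fit_or_params: FittedHMM | StateParams, series: StepTurnSeries
) -> StateSequence:
    """Globally most probable state path per segment (ties -> transit),
    together with forward-backward posterior state probabilities."""
    if isinstance(fit_or_params, FittedHMM):
        sp = fit_or_params.params_for_sex(series.sex)
    else:
        sp = fit_or_params
    data = _pack([series])[SexLabel(series.sex)]
    ld0, ld1 = _emission_logdens(data, sp)
    g = sp.tm.p
    delta = sp.initial_distribution()
    with np.errstate(divide="ignore"):
        lg = np.log(g)
        ldelta = np.log(delta)
    states = np.empty(data.speed.size, dtype=int)
    post = np.empty((data.speed.size, 2))
    for s0, L in zip(data.seg_start, data.seg_len):
        sl = slice(s0, s0 + L)
        states[sl] = _viterbi_nb(
            ld0[sl], ld1[sl], lg[0, 0], lg[0, 1], lg[1, 0], lg[1, 1], ldelta[0], ldelta[1]
        )
        post[sl] = _forward_backward(ld0[sl], ld1[sl], g, delta)
    return StateSequence(states=states, posteriors=post, segment=data_segment(data))


def data_segment(data: _SexBlockData) -> np.ndarray:
    seg = np.empty(data.speed.size, dtype=int)
    for i, (s0, L) in enumerate(zip(data.seg_start, data.seg_len)):
        seg[s0 : s0 + L] = i
    return seg


def _forward_backward(ld0, ld1, g, delta):
    L = ld0.size
    dens = np.exp(
        np.column_stack([ld0, ld1]) - np.maximum(ld0, ld1)[:, None]
    )
    alpha = np.empty((L, 2))
    c = np.empty(L)
    a = delta * dens[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ g) * dens[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((L, 2))
    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        b = g @ (dens[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)
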