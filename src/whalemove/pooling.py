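"""Multiple-imputation pooling of HMM fits across track realizations.

Location uncertainty propagates into the behavioural model by refitting the
HMM to each of m imputed track realizations and pooling with Rubin's rules
on the working (link) scale: pooled estimate = mean of the m estimates;
total variance = W + (1 + 1/m) B, where W is the mean within-fit variance
(from each fit's working-scale covariance) and B the between-fit sample
variance.  95% confidence intervals use the normal quantile by default
(a t quantile with Rubin's degrees of freedom is available for small m) and
are back-transformed to the natural scale through the monotone links.

Mean-turn-angle parameters are circular: before averaging, each fit's
lambda is wrapped into the branch within pi of the first fit's value so
that fits straddling the +/-pi boundary do not inflate B.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import FittedHMM, _natural_vector


@dataclass
class PooledEstimates:
    """Pooled natural-scale estimates with 95% CIs and variance components."""

    names: list[str]
    estimate: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    working_mean: np.ndarray
    within: np.ndarray
    between: np.ndarray
    m: int
    config_id: int

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.estimate[i]), float(self.lo95[i]), float(self.hi95[i])

    def format(self, name: str, digits: int = 3) -> str:
        """Render one parameter in the conventional 'estimate [lo, hi]' style,
        e.g. '0.035 [0.025, 0.049]'."""
        e, lo, hi = self[name]
        fmt = f"{{:.{digits}f}}"
        return f"{fmt.format(e)} [{fmt.format(lo)}, {fmt.format(hi)}]"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pat = re.compile(r"^(\w+)\[(\w+)(?:,(\w+))?\]$")
        for i, name in enumerate(self.names):
            m = pat.match(name)
            parameter, state, sex = (m.group(1), m.group(2), m.group(3)) if m else (name, "", "")
            if parameter in ("p_tr", "p_rt"):
                state, sex = parameter, m.group(2)
                parameter = "transition"
            rows.append(
                {
                    "parameter": parameter,
                    "state": state,
                    "sex": sex or "all",
                    "estimate": self.estimate[i],
                    "lo95": self.lo95[i],
                    "hi95": self.hi95[i],
                }
            )
        return pd.DataFrame(rows)


def _align_angles(W: np.ndarray, names: list[str]) -> np.ndarray:
    """Wrap each fit's angular parameters into the branch centred on the
    circular mean (order-invariant)."""
    W = W.copy()
    for j, name in enumerate(names):
        if name.startswith("lambda["):
            ref = np.arctan2(np.mean(np.sin(W[:, j])), np.mean(np.cos(W[:, j])))
            W[:, j] = ref + ((W[:, j] - ref + np.pi) % (2 * np.pi) - np.pi)
    return W


def pool_fits(
    fits: list[FittedHMM],
    alpha: float = 0.05,
    quantile: str = "normal",
    method: str = "rubin",
) -> PooledEstimates:
    """Pool m fits of the same configuration across imputed realizations.

    Non-converged fits are excluded with a warning (m adjusted); mixing
    configurations is an error.  ``method='percentile'`` replaces the
    normal-theory interval by natural-scale percentiles of the m point
    estimates.
    """
    if not fits:
        raise ValueError("no fits to pool")
    cfg = {f.config.id for f in fits}
    if len(cfg) != 1:
        raise ValueError(f"cannot pool fits of different configurations: {sorted(cfg)}")
    zm = {f.zero_mass for f in fits}
    if len(zm) != 1:
        raise ValueError("cannot pool fits with differing zero-mass structure")
    kept = [f for f in fits if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        warnings.warn(f"excluding {dropped} non-converged fit(s) from pooling", stacklevel=2)
    if not kept:
        raise ValueError("no converged fits to pool")
    m = len(kept)
    names = kept[0].names
    config = kept[0].config

    Wmat = _align_angles(np.vstack([f.working for f in kept]), names)
    mean_w = Wmat.mean(axis=0)
    between = Wmat.var(axis=0, ddof=1) if m > 1 else np.zeros(Wmat.shape[1])
    variances = []
    for f in kept:
        if f.cov is None:
            raise ValueError("pooling requires fits with working-scale covariances")
        variances.append(np.clip(np.diag(f.cov), 0.0, None))
    within = np.mean(variances, axis=0)
    total = within + (1.0 + 1.0 / m) * between

    if quantile == "normal":
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        q = np.full(total.shape, q)
    elif quantile == "t":
        # Rubin's degrees of freedom; infinite when B = 0
        with np.errstate(divide="ignore"):
            r = (1.0 + 1.0 / m) * between / np.where(within > 0, within, np.inf)
            df = (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2
        q = np.where(np.isfinite(df), stats.t.ppf(1.0 - alpha / 2.0, np.maximum(df, 1.0)),
                     stats.norm.ppf(1.0 - alpha / 2.0))
    else:
        raise ValueError("quantile must be 'normal' or 't'")

    lo_w = mean_w - q * np.sqrt(total)
    hi_w = mean_w + q * np.sqrt(total)
    est = _natural_vector(mean_w, config, kept[0].zero_mass)
    if method == "rubin":
        lo = _natural_vector(lo_w, config, kept[0].zero_mass)
        hi = _natural_vector(hi_w, config, kept[0].zero_mass)
        # angular parameters are reported on the (continuous) pooled branch so
        # that lo <= estimate <= hi holds even when the branch straddles +/-pi
        for j, name in enumerate(names):
            if name.startswith("lambda["):
                est[j] = mean_w[j]
                lo[j] = lo_w[j]
                hi[j] = hi_w[j]
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    elif method == "percentile":
        nat = np.vstack([_natural_vector(w, config, kept[0].zero_mass) for w in Wmat])
        lo = np.percentile(nat, 100 * alpha / 2.0, axis=0)
        hi = np.percentile(nat, 100 * (1.0 - alpha / 2.0), axis=0)
    else:
        raise ValueError("method must be 'rubin' or 'percentile'")

    return PooledEstimates(
        names=list(names),
        estimate=est,
        lo95=lo,
        hi95=hi,
        working_mean=mean_w,
        within=within,
        between=between,
        m=m,
        config_id=config.id,
    )
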