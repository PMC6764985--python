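"""Core parameter types for the 2-state movement model.

The two behavioural states are labelled ``transit`` (fast, directed travel)
and ``resident`` (slow, tortuous movement suggestive of foraging).  Step
speeds (km/h over a 6-h interval) follow a gamma distribution per state;
turning angles follow a wrapped Cauchy distribution per state; the state
itself evolves as a 2-state Markov chain on the 6-h step grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geodesy import wrap_angle

STATE_NAMES = ("transit", "resident")
TRANSIT, RESIDENT = 0, 1

LOC_CLASSES = ("3", "2", "1", "0", "A", "B")

#: Default isotropic Argos positional error SD (km) per location class,
#: ordered best ("3") to worst ("B"); overridable in configuration.
DEFAULT_ARGOS_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0}


class SexLabel(str, Enum):
    """Sex of a tracked animal; ``unknown`` is a genuine third factor level
    (estimates are reported separately for unsexed animals, not pooled)."""

    female = "female"
    male = "male"
    unknown = "unknown"


SEX_LEVELS = (SexLabel.female, SexLabel.male, SexLabel.unknown)


@dataclass(frozen=True)
class GammaParams:
    """Gamma step-speed distribution in mean/SD form.

    Parameters
    ----------
    mu : float
        Mean step speed, km/h. Must be positive.
    sigma : float
        Step-speed standard deviation, km/h. Must be positive.
    """

    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.mu > 0 and np.isfinite(self.mu)):
            raise ValueError(f"gamma mu must be positive, got {self.mu}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"gamma sigma must be positive, got {self.sigma}")

    @property
    def shape(self) -> float:
        return self.mu**2 / self.sigma**2

    @property
    def scale(self) -> float:
        return self.sigma**2 / self.mu

    @classmethod
    def from_shape_scale(cls, shape: float, scale: float) -> "GammaParams":
        return cls(mu=shape * scale, sigma=np.sqrt(shape) * scale)


@dataclass(frozen=True)
class WrappedCauchyParams:
    """Wrapped Cauchy turning-angle distribution.

    Parameters
    ----------
    lam : float
        Mean turn angle in radians; normalized to (-pi, pi] on construction.
    kappa : float
        Concentration in [0, 1): 0 is circular-uniform, ->1 concentrates all
        mass at ``lam``.
    """

    lam: float
    kappa: float

    def __post_init__(self):
        if not (0.0 <= self.kappa < 1.0):
            raise ValueError(f"wrapped Cauchy kappa must be in [0, 1), got {self.kappa}")
        object.__setattr__(self, "lam", float(wrap_angle(self.lam)))


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-6h-step transition probabilities of the 2-state behavioural chain.

    Row/column order is fixed as (transit, resident). Rows must be proper
    probability distributions.
    """

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (2, 2):
            raise ValueError(f"transition matrix must be 2x2, got shape {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("transition matrix rows must sum to 1 within 1e-12")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_switch_probs(cls, p_transit_to_resident: float, p_resident_to_transit: float):
        """Build from the two off-diagonal switching probabilities
        Pr(resident | transit) and Pr(transit | resident)."""
        ptr, prt = p_transit_to_resident, p_resident_to_transit
        return cls(np.array([[1.0 - ptr, ptr], [prt, 1.0 - prt]]))

    @property
    def p_transit_to_resident(self) -> float:
        return float(self.p[TRANSIT, RESIDENT])

    @property
    def p_resident_to_transit(self) -> float:
        return float(self.p[RESIDENT, TRANSIT])
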