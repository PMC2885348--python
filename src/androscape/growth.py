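"""Androgen- and ROS-driven growth of the prostate epithelial population.

The effective androgen signal C_t = C_TR + w_dht * C_DR (nM of T:AR
equivalents, DHT weighted 2.4x by default) is the sole mediator.  Oxidative
stress S is an instantaneous U-shaped function of C_t: high at both low and
high androgen, with a background floor mu.  Per-capita proliferation M0 and
death N are each the average of two Hill-type signals, normalised so the
stated maxima hold exactly:

    M0 = (r/2) * [ C_t^2/(phi1^2 + C_t^2) + varphi*S*exp(1 - varphi*S) ]
    N  = delta0 + (delta/2) * [ phi2^k/(phi2^k + C_t^k) + S^q/(omega^q + S^q) ]

NOTE: the additive 1/2-normalised combination is a reconstruction chosen as
the only additive form consistent with the stated maxima (max proliferation
r; max death delta + delta0).  It is isolated in ``proliferation_signal`` and
``death_rate`` so an alternative combination is a one-line swap.

Population dynamics: dP/dt = P * (M0 - sigma*P - N); crowding (-sigma*P)
guarantees a finite equilibrium P* = max(0, (M0 - N)/sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "GrowthParams",
    "GrowthState",
    "effective_complex",
    "ros_level",
    "proliferation_signal",
    "death_rate",
    "growth_rhs",
    "growth_steady_state",
    "turnover_rate",
    "DEFAULT_GROWTH_PARAMS",
]


@dataclass(frozen=True)
class GrowthParams:
    """Shape parameters of the ROS and proliferation/death signals."""

    theta1: float = 30.0     # half-maximal C_t, low-androgen ROS (nM)
    theta2: float = 225.0    # half-maximal C_t, high-androgen ROS (nM)
    mu: float = 0.05         # background ROS level (dimensionless)
    n: float = 4.0           # Hill coefficient, low-androgen ROS
    m: float = 4.0           # Hill coefficient, high-androgen ROS
    phi1: float = 110.0      # half-maximal C_t, androgen proliferation (nM)
    phi2: float = 40.0       # half-maximal C_t, low-androgen apoptosis (nM)
    varphi: float = 4.0      # shape of ROS proliferation signal
    omega: float = 1.0       # half-maximal S, ROS-induced death
    q: float = 8.0           # Hill coefficient, ROS-induced death
    sigma: float = 1.5e-10   # crowding coefficient (cell^-1 h^-1)
    delta0: float = 0.004    # background death rate (h^-1)
    delta: float = math.log(2) / 24  # maximum androgen/ROS death rate (h^-1)
    r: float = math.log(2) / 24      # maximum proliferation rate (h^-1)
    w_dht: float = 2.4       # DHT potency relative to T in C_t
    k_apop: float = 2.0      # Hill coefficient of the low-androgen death signal

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        for name in ("n", "m", "q", "k_apop"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"Hill coefficient {name} must be >= 1")
        if self.theta2 <= self.theta1:
            raise InvalidParameterError(
                f"theta2 ({self.theta2}) must exceed theta1 ({self.theta1})"
            )


DEFAULT_GROWTH_PARAMS = GrowthParams()


@dataclass(frozen=True)
class GrowthState:
    """Epithelial cell count."""

    P: float

    def __post_init__(self):
        if self.P < 0:
            raise InvalidInputError(f"cell count must be >= 0, got {self.P}")


def effective_complex(C_TR, C_DR, w_dht: float = 2.4):
    """Effective androgen:AR signal C_t = C_TR + w_dht * C_DR (nM)."""
    if np.any(np.asarray(C_TR) < 0) or np.any(np.asarray(C_DR) < 0) or w_dht < 0:
        raise InvalidParameterError("effective_complex arguments must be >= 0")
    return C_TR + w_dht * C_DR


def ros_level(C_t, g: GrowthParams = DEFAULT_GROWTH_PARAMS):
    """Oxidative stress S(C_t): mu + low-androgen Hill + high-androgen Hill.

    Bounded in [mu, mu + 2]; equals mu + 1 both at C_t = 0 and C_t -> inf.
    """
    C_t = np.asarray(C_t, dtype=float)
    if np.any(C_t < 0):
        raise InvalidInputError("C_t must be >= 0")
    low = g.theta1 ** g.n / (g.theta1 ** g.n + C_t ** g.n)
    high = np.where(
        C_t > 0,
        C_t ** g.m / (g.theta2 ** g.m + C_t ** g.m),
        0.0,
    )
    out = g.mu + low + high
    return float(out) if out.ndim == 0 else out


def proliferation_signal(C_t, S, g: GrowthParams = DEFAULT_GROWTH_PARAMS):
    """Per-capita proliferation rate M0(C_t, S) before crowding (h^-1).

    Average of the sigmoidal androgen term and the unimodal ROS term
    varphi*S*exp(1 - varphi*S), scaled to a maximum of r.
    """
    C_t = np.asarray(C_t, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(C_t < 0) or np.any(S < 0):
        raise InvalidInputError("proliferation_signal arguments must be >= 0")
    androgen = C_t ** 2 / (g.phi1 ** 2 + C_t ** 2)
    ros = g.varphi * S * np.exp(1.0 - g.varphi * S)
    out = 0.5 * g.r * (androgen + ros)
    return float(out) if out.ndim == 0 else out


def death_rate(C_t, S, g: GrowthParams = DEFAULT_GROWTH_PARAMS):
    """Per-capita death rate N(C_t, S) (h^-1).

    Background delta0 plus the averaged low-androgen and high-ROS apoptotic
    Hill signals; bounded in [delta0, delta0 + delta].
    """
    C_t = np.asarray(C_t, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(C_t < 0) or np.any(S < 0):
        raise InvalidInputError("death_rate arguments must be >= 0")
    k = g.k_apop
    low_androgen = g.phi2 ** k / (g.phi2 ** k + C_t ** k)
    ros = np.where(S > 0, S ** g.q / (g.omega ** g.q + S ** g.q), 0.0)
    out = g.delta0 + 0.5 * g.delta * (low_androgen + ros)
    return float(out) if out.ndim == 0 else out


def growth_rhs(P: float, C_t: float, g: GrowthParams = DEFAULT_GROWTH_PARAMS) -> float:
    """dP/dt = P * (M0 - sigma*P - N) with S evaluated from C_t (cells/h)."""
    if P < 0:
        raise InvalidInputError(f"cell count must be >= 0, got {P}")
    S = ros_level(C_t, g)
    return P * (proliferation_signal(C_t, S, g) - g.sigma * P - death_rate(C_t, S, g))


def growth_steady_state(C_t, g: GrowthParams = DEFAULT_GROWTH_PARAMS):
    """Equilibrium cell count P* = max(0, (M0 - N)/sigma)."""
    if g.sigma == 0:
        raise InvalidParameterError("sigma must be > 0 for a finite equilibrium")
    S = ros_level(C_t, g)
    net = proliferation_signal(C_t, S, g) - death_rate(C_t, S, g)
    out = np.maximum(0.0, np.asarray(net) / g.sigma)
    return float(out) if out.ndim == 0 else out


def turnover_rate(C_t, g: GrowthParams = DEFAULT_GROWTH_PARAMS):
    """Per-capita cell turnover at the tissue equilibrium (h^-1).

    At steady state per-capita birth equals per-capita death, so turnover is
    the death rate N(C_t, S(C_t)).  Units per-capita per hour; only the shape
    of the curve (monotonicities) is meaningful.
    """
    return death_rate(C_t, ros_level(C_t, g), g)
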