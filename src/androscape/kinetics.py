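"""Intracellular androgen receptor (AR) binding kinetics.

Five-variable mass-action model of the intracellular prostate compartment:
free AR (R), free testosterone (T), free DHT (D), and the two ligand:receptor
complexes (C_TR, C_DR).  Testosterone enters at an empirical influx rate
U(T_S) driven by the imposed serum testosterone level T_S, is converted to
DHT by 5-alpha-reductase (Michaelis-Menten, competitively inhibitable), and
both ligands bind AR reversibly.  Free species degrade first-order; complexes
do not degrade.  AR production is homeostatic: the cell maintains a total AR
set point R_t by modulating the production rate

    lambda = beta_R_norm * max(0, R_t - C_TR - C_DR)

which, when beta_R_norm == beta_R, pins total AR (R + C_TR + C_DR) at exactly
R_t in steady state.

Units: concentrations in nM, time in hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import (
    IntegrationError,
    InvalidInputError,
    InvalidParameterError,
    SteadyStateError,
)

__all__ = [
    "InfluxParams",
    "KineticParams",
    "KineticState",
    "KineticTrajectory",
    "dissociation_constant",
    "effective_km",
    "reductase_rate",
    "influx",
    "ar_production_rate",
    "kinetics_rhs",
    "simulate_kinetics",
    "kinetics_steady_state",
    "effective_ar_turnover",
    "eta_to_inhibitor",
    "with_eta",
    "DEFAULT_KINETIC_PARAMS",
]

# Solver tolerances (see module docs): trajectories are integrated with a
# stiff-capable method at rtol=1e-8 / atol=1e-10 nM; steady-state residuals
# must fall below 1e-9 nM/h.
RTOL = 1e-8
ATOL = 1e-10
SS_RESIDUAL_TOL = 1e-9


def dissociation_constant(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant K_D = kd/ka (nM).

    Parameters
    ----------
    ka : association rate constant (nM^-1 h^-1), must be > 0.
    kd : dissociation rate constant (h^-1), must be >= 0.
    """
    if ka <= 0:
        raise InvalidParameterError(f"association rate ka must be > 0, got {ka}")
    if kd < 0:
        raise InvalidParameterError(f"dissociation rate kd must be >= 0, got {kd}")
    return kd / ka


def effective_km(K_M: float, I: float, K_I: float) -> float:
    """Effective Michaelis constant under competitive inhibition.

    Returns K_M * eta with eta = 1 + I/K_I, where I is the inhibitor
    concentration (nM) and K_I its dissociation constant (nM).
    """
    if K_M <= 0:
        raise InvalidParameterError(f"K_M must be > 0, got {K_M}")
    if K_I <= 0:
        raise InvalidParameterError(f"K_I must be > 0, got {K_I}")
    if I < 0:
        raise InvalidParameterError(f"inhibitor concentration must be >= 0, got {I}")
    return K_M * (1.0 + I / K_I)


def eta_to_inhibitor(eta: float, K_I: float) -> float:
    """Inhibitor concentration I producing the effective-K_M multiplier eta."""
    if eta < 1:
        raise InvalidParameterError(f"eta must be >= 1, got {eta}")
    return (eta - 1.0) * K_I


def reductase_rate(T_free: float, alpha: float, k_cat: float, K_M_eff: float) -> float:
    """Michaelis-Menten T -> DHT conversion rate (nM/h).

    v = alpha * k_cat * T / (K_M_eff + T).  Unit coherence:
    mg/L * nmol/(h*mg) = nmol/(L*h) = nM/h.
    """
    if min(T_free, alpha, k_cat) < 0:
        raise InvalidParameterError("reductase_rate arguments must be >= 0")
    if K_M_eff <= 0:
        raise InvalidParameterError(f"K_M_eff must be > 0, got {K_M_eff}")
    return alpha * k_cat * T_free / (K_M_eff + T_free)


@dataclass(frozen=True)
class InfluxParams:
    """Empirical testosterone influx U(T_S) into the intracellular pool.

    Two forms:

    * ``saturating`` -- U = u_max * T_S / (u_half + T_S); the default, with
      u_max/u_half calibrated once (scripts/calibrate_influx.py) so that the
      baseline steady state at T_S = 5 nM, R_t = 45 nM lands total
      intraprostatic DHT at 50 nM, the middle of the normal 40-60 nM range.
    * ``tabulated`` -- monotone linear interpolation of (T_S, U) pairs with
      flat extrapolation past the last point; U(0) = 0 is enforced.
    """

    form: str = "saturating"
    u_max: float = 2.3463312230734124  # nM/h, calibrated anchor (see docstring)
    u_half: float = 10.0  # nM
    table: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.form not in ("saturating", "tabulated"):
            raise InvalidParameterError(f"unknown influx form {self.form!r}")
        if self.form == "saturating":
            if self.u_max < 0 or self.u_half <= 0:
                raise InvalidParameterError(
                    "saturating influx needs u_max >= 0 and u_half > 0"
                )
        else:
            if len(self.table) < 1:
                raise InvalidParameterError("tabulated influx needs >= 1 point")
            ts = [p[0] for p in self.table]
            us = [p[1] for p in self.table]
            if any(t < 0 for t in ts) or any(u < 0 for u in us):
                raise InvalidParameterError("influx table entries must be >= 0")
            if sorted(ts) != ts or len(set(ts)) != len(ts):
                raise InvalidParameterError("influx table T_S must be strictly increasing")
            if any(b < a for a, b in zip(us, us[1:])):
                raise InvalidParameterError("influx table U must be non-decreasing")


def influx(T_S: float, p: InfluxParams) -> float:
    """Testosterone influx U(T_S) in nM/h; 0 at T_S = 0, non-decreasing."""
    if T_S < 0:
        raise InvalidInputError(f"serum testosterone must be >= 0, got {T_S}")
    if p.form == "saturating":
        return p.u_max * T_S / (p.u_half + T_S)
    ts = np.array([0.0] + [q[0] for q in p.table if q[0] > 0])
    us = np.array([0.0] + [q[1] for q in p.table if q[0] > 0])
    return float(np.interp(T_S, ts, us))


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the AR kinetics model (baseline values in nM, h)."""

    ka_T: float = 0.14          # T:AR association (nM^-1 h^-1)
    kd_T: float = 0.069         # T:AR dissociation (h^-1)
    ka_D: float = 0.053         # DHT:AR association (nM^-1 h^-1)
    kd_D: float = 0.018         # DHT:AR dissociation (h^-1)
    beta_R: float = math.log(2) / 3   # free AR degradation (h^-1)
    beta_T: float = math.log(2) / 3   # free T degradation (h^-1)
    beta_D: float = math.log(2) / 9   # free DHT degradation (h^-1)
    alpha: float = 5.0          # 5a-reductase concentration (mg/L)
    k_cat: float = 18.0         # turnover number (nmol h^-1 mg^-1)
    K_M: float = 75.0           # Michaelis constant (nM)
    K_I: float = 0.46           # finasteride dissociation constant (nM)
    inhibitor_I: float = 0.0    # inhibitor concentration (nM)
    R_t: float = 45.0           # homeostatic total AR set point (nM)
    beta_R_norm: float = math.log(2) / 3  # normal AR turnover rate (h^-1)
    influx: InfluxParams = field(default_factory=InfluxParams)

    def __post_init__(self):
        nonneg = {
            "kd_T": self.kd_T, "kd_D": self.kd_D, "beta_R": self.beta_R,
            "beta_T": self.beta_T, "beta_D": self.beta_D, "alpha": self.alpha,
            "k_cat": self.k_cat, "inhibitor_I": self.inhibitor_I,
            "beta_R_norm": self.beta_R_norm,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        for name, v in (("ka_T", self.ka_T), ("ka_D", self.ka_D),
                        ("K_M", self.K_M), ("K_I", self.K_I), ("R_t", self.R_t)):
            if v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")

    @property
    def K_D_T(self) -> float:
        """Equilibrium K_D for T:AR (nM)."""
        return dissociation_constant(self.ka_T, self.kd_T)

    @property
    def K_D_D(self) -> float:
        """Equilibrium K_D for DHT:AR (nM)."""
        return dissociation_constant(self.ka_D, self.kd_D)

    @property
    def K_M_eff(self) -> float:
        """Effective Michaelis constant including competitive inhibition."""
        return effective_km(self.K_M, self.inhibitor_I, self.K_I)

    @property
    def eta(self) -> float:
        """Effective-K_M multiplier 1 + I/K_I."""
        return self.K_M_eff / self.K_M


def with_eta(p: KineticParams, eta: float) -> KineticParams:
    """Copy of ``p`` with the inhibitor set so that K_M_eff = eta * K_M."""
    return replace(p, inhibitor_I=eta_to_inhibitor(eta, p.K_I))


DEFAULT_KINETIC_PARAMS = KineticParams()


@dataclass(frozen=True)
class KineticState:
    """Instantaneous concentrations (nM) of the five kinetic variables."""

    R: float
    T: float
    D: float
    C_TR: float
    C_DR: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise InvalidInputError(f"state field {name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.T, self.D, self.C_TR, self.C_DR])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "KineticState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(*map(float, y))

    @property
    def total_T(self) -> float:
        return self.T + self.C_TR

    @property
    def total_DHT(self) -> float:
        return self.D + self.C_DR

    @property
    def total_AR(self) -> float:
        return self.R + self.C_TR + self.C_DR


def ar_production_rate(R_t: float, C_TR: float, C_DR: float, beta_R_norm: float) -> float:
    """Homeostatic AR production rate lambda (nM/h), clamped at 0."""
    if min(R_t, C_TR, C_DR, beta_R_norm) < 0:
        raise InvalidParameterError("ar_production_rate arguments must be >= 0")
    return beta_R_norm * max(0.0, R_t - C_TR - C_DR)


def _rhs_array(y: np.ndarray, p: KineticParams, U: float, km_eff: float) -> np.ndarray:
    R, T, D, C_TR, C_DR = y
    v_red = p.alpha * p.k_cat * T / (km_eff + T)
    bind_T = p.ka_T * T * R - p.kd_T * C_TR
    bind_D = p.ka_D * D * R - p.kd_D * C_DR
    lam = p.beta_R_norm * max(0.0, p.R_t - C_TR - C_DR)
    return np.array([
        lam - p.beta_R * R - bind_T - bind_D,
        U - p.beta_T * T - v_red - bind_T,
        v_red - p.beta_D * D - bind_D,
        bind_T,
        bind_D,
    ])


def kinetics_rhs(s: KineticState, p: KineticParams, T_S: float) -> np.ndarray:
    """Time derivative (dR, dT, dD, dC_TR, dC_DR) in nM/h."""
    y = s.as_array()
    if np.any(y < 0):
        raise InvalidInputError("state fields must be non-negative")
    return _rhs_array(y, p, influx(T_S, p.influx), p.K_M_eff)


@dataclass(frozen=True)
class KineticTrajectory:
    """Solution of the kinetics ODE on an increasing time grid (hours)."""

    time: np.ndarray                 # (n,) hours, strictly increasing
    states: np.ndarray               # (n, 5) columns R, T, D, C_TR, C_DR

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("trajectory time grid must be strictly increasing")
        if self.states.shape != (self.time.size, 5):
            raise InvalidInputError("states must have shape (len(time), 5)")

    @property
    def R(self): return self.states[:, 0]

    @property
    def T(self): return self.states[:, 1]

    @property
    def D(self): return self.states[:, 2]

    @property
    def C_TR(self): return self.states[:, 3]

    @property
    def C_DR(self): return self.states[:, 4]

    @property
    def total_T(self): return self.T + self.C_TR

    @property
    def total_DHT(self): return self.D + self.C_DR

    @property
    def total_AR(self): return self.R + self.C_TR + self.C_DR

    def final_state(self) -> KineticState:
        return KineticState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.time,
            "R_nM": self.R, "T_nM": self.T, "D_nM": self.D,
            "CTR_nM": self.C_TR, "CDR_nM": self.C_DR,
            "totalT_nM": self.total_T, "totalDHT_nM": self.total_DHT,
            "totalAR_nM": self.total_AR,
        })


def simulate_kinetics(
    p: KineticParams,
    T_S: float,
    t_end: float,
    init: KineticState | None = None,
    n_out: int = 500,
) -> KineticTrajectory:
    """Integrate the kinetics ODE from ``init`` under constant serum T.

    Default initial condition is the androgen-naive state (R = R_t, all other
    variables 0).  Uses a stiff-capable solver; small negative excursions
    within solver tolerance are clipped to 0 on output.
    """
    if t_end <= 0:
        raise InvalidInputError(f"t_end must be > 0, got {t_end}")
    if init is None:
        init = KineticState(p.R_t, 0.0, 0.0, 0.0, 0.0)
    U = influx(T_S, p.influx)
    km_eff = p.K_M_eff
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        lambda t, y: _rhs_array(y, p, U, km_eff),
        (0.0, t_end),
        init.as_array(),
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"kinetics integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    return KineticTrajectory(time=sol.t, states=states)


def _steady_state_analytic(p: KineticParams, U: float) -> np.ndarray:
    """Closed-form steady state.

    At equilibrium both binding fluxes vanish individually, so free T solves
    the scalar balance U = beta_T*T + v_red(T)  (a quadratic), D = v_red/beta_D,
    and free AR follows from the homeostatic production law under the binding
    load b = T/K_D_T + D/K_D_D.
    """
    km = p.K_M_eff
    vmax = p.alpha * p.k_cat
    if vmax == 0:
        T = U / p.beta_T if p.beta_T > 0 else 0.0
        v = 0.0
    else:
        # beta_T*T^2 + (beta_T*km + vmax - U)*T - U*km = 0
        a, b, c = p.beta_T, p.beta_T * km + vmax - U, -U * km
        if a == 0:
            T = -c / b if b != 0 else 0.0
        else:
            disc = b * b - 4 * a * c
            T = (-b + math.sqrt(max(disc, 0.0))) / (2 * a)
        T = max(T, 0.0)
        v = vmax * T / (km + T)
    D = v / p.beta_D if p.beta_D > 0 else 0.0
    load = T / p.K_D_T + D / p.K_D_D
    denom = p.beta_R + p.beta_R_norm * load
    R = p.beta_R_norm * p.R_t / denom if denom > 0 else p.R_t
    return np.array([R, T, D, T * R / p.K_D_T, D * R / p.K_D_D])


def kinetics_steady_state(p: KineticParams, T_S: float) -> KineticState:
    """Non-negative root of the kinetics right-hand side.

    The closed-form reduction seeds a damped Newton polish on the full
    5-variable system; if the residual stays above tolerance the solver
    re-seeds from a long integration before giving up.
    """
    if T_S < 0:
        raise InvalidInputError(f"serum testosterone must be >= 0, got {T_S}")
    U = influx(T_S, p.influx)
    km_eff = p.K_M_eff
    fun = lambda y: _rhs_array(y, p, U, km_eff)

    def _residual(y):
        return float(np.max(np.abs(fun(y))))

    y0 = _steady_state_analytic(p, U)
    if _residual(y0) > SS_RESIDUAL_TOL:
        sol = root(fun, y0, method="hybr", tol=1e-12)
        y0 = sol.x
    if _residual(y0) > SS_RESIDUAL_TOL or np.any(y0 < -1e-9):
        traj = simulate_kinetics(p, T_S, 5000.0, n_out=2)
        sol = root(fun, traj.states[-1], method="hybr", tol=1e-12)
        y0 = sol.x
        if _residual(y0) > SS_RESIDUAL_TOL or np.any(y0 < -1e-9):
            raise SteadyStateError(
                f"steady-state solve did not converge (residual {_residual(y0):.3e})",
                residual=_residual(y0),
            )
    return KineticState.from_array(y0)


def effective_ar_turnover(ss: KineticState, p: KineticParams) -> float:
    """Effective turnover rate of the total AR pool at steady state (h^-1).

    Only free AR degrades, so the pool turns over at
    beta_R_norm * R_ss / R_t: the normal rate scaled by the free fraction.
    Increases nonlinearly as androgen is withdrawn.
    """
    if p.R_t <= 0:
        raise InvalidParameterError("R_t must be > 0")
    return p.beta_R_norm * ss.R / p.R_t
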