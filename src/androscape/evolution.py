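"""Mutation-selection dynamics over strains differing in AR expression.

Q strains occupy an equally spaced grid of homeostatic AR set points R_t.
Each strain sees its own steady-state androgen environment (C_t, S) computed
from the receptor-kinetics model — kinetics equilibrates in days while
selection plays out over years, and kinetics does not depend on cell counts,
so the quasi-steady-state coupling is exact at constant serum T.  Strains
grow by the tissue-growth law with crowding shared across the whole
population, and mutate to nearest-neighbour states at first-order rate gamma
(reflecting boundaries, so mutation conserves total cell count).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import growth as _growth
from .errors import IntegrationError, InvalidInputError, InvalidParameterError
from .growth import GrowthParams, effective_complex, ros_level
from .kinetics import KineticParams, kinetics_steady_state, with_eta

__all__ = [
    "StateGrid",
    "EvolutionParams",
    "StrainEnvironment",
    "EvolutionResult",
    "build_state_grid",
    "per_state_environment",
    "mutation_fluxes",
    "evolution_rhs",
    "simulate_evolution",
    "average_ar",
    "time_to_threshold",
]

HOURS_PER_YEAR = 8760.0


@dataclass(frozen=True)
class StateGrid:
    """Equally spaced grid of homeostatic AR set points (nM)."""

    Q: int
    Rt_values: np.ndarray

    def __post_init__(self):
        if self.Q < 2:
            raise InvalidParameterError(f"grid needs Q >= 2 states, got {self.Q}")
        diffs = np.diff(self.Rt_values)
        if np.any(diffs <= 0) or not np.allclose(diffs, diffs[0]):
            raise InvalidParameterError("Rt_values must be strictly increasing and equally spaced")


def build_state_grid(Q: int = 100, Rt_min: float = 15.0, step: float = 1.0) -> StateGrid:
    """State i (1-based) carries R_t = Rt_min + (i-1)*step.

    Defaults give 100 states spanning 15..114 nM (state i at 14 + i nM).
    """
    if Q < 2:
        raise InvalidParameterError(f"grid needs Q >= 2 states, got {Q}")
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    if Rt_min <= 0:
        raise InvalidParameterError(f"Rt_min must be > 0, got {Rt_min}")
    return StateGrid(Q=Q, Rt_values=Rt_min + step * np.arange(Q, dtype=float))


@dataclass(frozen=True)
class StrainEnvironment:
    """Per-strain effective androgen signal and ROS level."""

    C_t: np.ndarray
    S: np.ndarray
    T_S: float
    eta: float

    def __post_init__(self):
        if self.C_t.shape != self.S.shape:
            raise InvalidInputError("C_t and S must have equal length")
        if np.any(self.C_t < 0) or np.any(self.S < 0):
            raise InvalidInputError("environment entries must be >= 0")


def per_state_environment(
    grid: StateGrid,
    kp: KineticParams,
    T_S: float,
    eta: float = 1.0,
    g: GrowthParams = _growth.DEFAULT_GROWTH_PARAMS,
) -> StrainEnvironment:
    """Steady-state (C_t, S) for every strain on the grid.

    Each strain's kinetics is solved with its own R_t and the shared
    inhibition level eta (effective K_M multiplier).
    """
    kp_eta = with_eta(kp, eta)
    C_t = np.empty(grid.Q)
    for i, rt in enumerate(grid.Rt_values):
        try:
            ss = kinetics_steady_state(replace(kp_eta, R_t=float(rt)), T_S)
        except Exception as exc:  # tag failures with the state index
            raise type(exc)(f"state {i + 1} (R_t={rt} nM): {exc}") from exc
        C_t[i] = effective_complex(ss.C_TR, ss.C_DR, g.w_dht)
    return StrainEnvironment(C_t=C_t, S=ros_level(C_t, g), T_S=T_S, eta=eta)


def mutation_fluxes(P: np.ndarray, gamma: float) -> np.ndarray:
    """Nearest-neighbour mutation fluxes (cells/h per state).

    Interior states exchange with both neighbours at rate gamma; edge states
    with their single neighbour only (reflecting), so the fluxes sum to zero
    exactly.
    """
    if gamma < 0:
        raise InvalidParameterError(f"gamma must be >= 0, got {gamma}")
    P = np.asarray(P, dtype=float)
    out = np.zeros_like(P)
    out[:-1] += gamma * (P[1:] - P[:-1])
    out[1:] += gamma * (P[:-1] - P[1:])
    return out


def evolution_rhs(
    P: np.ndarray,
    env: StrainEnvironment,
    g: GrowthParams,
    gamma: float,
) -> np.ndarray:
    """dP_i/dt with per-strain growth, shared crowding, and mutation."""
    P = np.asarray(P, dtype=float)
    if P.shape != env.C_t.shape:
        raise InvalidInputError("population and environment lengths differ")
    M0 = _growth.proliferation_signal(env.C_t, env.S, g)
    N = _growth.death_rate(env.C_t, env.S, g)
    total = P.sum()
    return P * (M0 - g.sigma * total - N) + mutation_fluxes(P, gamma)


@dataclass(frozen=True)
class EvolutionParams:
    """Run settings for the strain-evolution simulation."""

    gamma: float = 1e-5            # mutation transition rate (h^-1)
    t_end: float = 20 * HOURS_PER_YEAR  # horizon (h)
    init_mode: str = "point"       # "point" | "uniform"
    init_state_Rt: float = 45.0    # R_t of the seeded state for "point"
    output_stride: float = 876.0   # output sampling interval (h)

    def __post_init__(self):
        if self.gamma < 0:
            raise InvalidParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.t_end <= 0:
            raise InvalidParameterError(f"t_end must be > 0, got {self.t_end}")
        if self.init_mode not in ("point", "uniform"):
            raise InvalidParameterError(f"unknown init_mode {self.init_mode!r}")
        if self.output_stride <= 0:
            raise InvalidParameterError("output_stride must be > 0")


@dataclass(frozen=True)
class EvolutionResult:
    """Population time series and the derived average AR expression."""

    time: np.ndarray        # (n,) hours
    populations: np.ndarray  # (n, Q) cells
    grid: StateGrid

    @property
    def total_cells(self) -> np.ndarray:
        return self.populations.sum(axis=1)

    @property
    def avg_Rt(self) -> np.ndarray:
        tot = self.total_cells
        return (self.populations @ self.grid.Rt_values) / tot

    def to_frame(self, wide: bool = True):
        import pandas as pd

        base = pd.DataFrame({
            "time_h": self.time,
            "avg_Rt_nM": self.avg_Rt,
            "total_cells": self.total_cells,
        })
        if wide:
            cols = {f"P_state_{i + 1:03d}": self.populations[:, i] for i in range(self.grid.Q)}
            return pd.concat([base, pd.DataFrame(cols)], axis=1)
        return base


def default_initial_population(
    grid: StateGrid,
    env: StrainEnvironment,
    g: GrowthParams,
    ep: EvolutionParams,
) -> np.ndarray:
    """Initial population per EvolutionParams.init_mode.

    "point": all cells in the state nearest init_state_Rt, at that strain's
    solo growth equilibrium.  "uniform": the total equilibrium of the nearest
    state spread evenly over all states.
    """
    idx = int(np.argmin(np.abs(grid.Rt_values - ep.init_state_Rt)))
    P0_total = _growth.growth_steady_state(float(env.C_t[idx]), g)
    if P0_total <= 0:
        P0_total = 1.0  # seed a nominal cell if the chosen state is non-viable
    P = np.zeros(grid.Q)
    if ep.init_mode == "point":
        P[idx] = P0_total
    else:
        P[:] = P0_total / grid.Q
    return P


def simulate_evolution(
    grid: StateGrid,
    env: StrainEnvironment,
    g: GrowthParams,
    ep: EvolutionParams,
    init: np.ndarray | None = None,
) -> EvolutionResult:
    """Integrate the Q-state mutation-selection ODE system."""
    if init is None:
        init = default_initial_population(grid, env, g, ep)
    init = np.asarray(init, dtype=float)
    if init.shape != (grid.Q,):
        raise InvalidInputError(f"init must have shape ({grid.Q},)")
    if np.any(init < 0) or init.sum() == 0:
        raise InvalidInputError("init must be non-negative and not all zero")

    M0 = _growth.proliferation_signal(env.C_t, env.S, g)
    N = _growth.death_rate(env.C_t, env.S, g)
    F = M0 - N
    gamma, sigma, Q = ep.gamma, g.sigma, grid.Q

    # Growth terms see max(P, 0): tiny negative solver excursions in
    # near-empty states otherwise destabilise the quadratic crowding term;
    # mutation coupling pulls such excursions back to zero.
    def rhs(t, P):
        Pp = np.maximum(P, 0.0)
        out = Pp * (F - sigma * Pp.sum())
        out[:-1] += gamma * (P[1:] - P[:-1])
        out[1:] += gamma * (P[:-1] - P[1:])
        return out

    lap = np.zeros((Q, Q))
    idx = np.arange(Q)
    lap[idx[:-1], idx[:-1] + 1] += gamma
    lap[idx[1:], idx[1:] - 1] += gamma
    lap[idx[:-1], idx[:-1]] -= gamma
    lap[idx[1:], idx[1:]] -= gamma

    def jac(t, P):
        Pp = np.maximum(P, 0.0)
        act = (P > 0).astype(float)
        J = lap - sigma * np.outer(Pp, act)
        J[idx, idx] += act * (F - sigma * Pp.sum())
        return J

    n_out = max(2, int(np.floor(ep.t_end / ep.output_stride)) + 1)
    t_eval = np.linspace(0.0, ep.t_end, n_out)
    sol = solve_ivp(
        rhs, (0.0, ep.t_end), init, method="BDF", jac=jac,
        rtol=1e-8, atol=1e-6, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"evolution integration failed: {sol.message}")
    pops = np.clip(sol.y.T, 0.0, None)
    return EvolutionResult(time=sol.t, populations=pops, grid=grid)


def average_ar(P: np.ndarray, grid: StateGrid) -> float:
    """Population-weighted average AR set point (nM)."""
    P = np.asarray(P, dtype=float)
    total = P.sum()
    if total <= 0:
        raise InvalidInputError("average AR is undefined for an all-zero population")
    return float(P @ grid.Rt_values / total)


def time_to_threshold(time: np.ndarray, avg_Rt: np.ndarray, threshold: float) -> float | None:
    """First time the average-R_t series reaches ``threshold`` (linear interp).

    Returns None if the threshold is never reached.
    """
    time = np.asarray(time, dtype=float)
    avg_Rt = np.asarray(avg_Rt, dtype=float)
    if time.size == 0 or time.size != avg_Rt.size:
        raise InvalidInputError("series must be non-empty and equal-length")
    if np.any(np.diff(time) <= 0):
        raise InvalidInputError("time series must be strictly increasing")
    hits = np.nonzero(avg_Rt >= threshold)[0]
    if hits.size == 0:
        return None
    j = int(hits[0])
    if j == 0:
        return float(time[0])
    t0, t1 = time[j - 1], time[j]
    v0, v1 = avg_Rt[j - 1], avg_Rt[j]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))
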