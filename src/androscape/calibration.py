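"""Steady-state parameter inference and synthetic tissue datasets.

Workflow mirrors how the kinetics model is parametrised from steady-state
measurements of intraprostatic total T and total DHT versus serum T, taken
with and without 5-alpha-reductase inhibition:

1. Under full inhibition (alpha treated as 0) and an imposed total AR pool,
   complexes neither degrade nor net-bind at steady state, so the influx
   balances free-T degradation: U = beta_T * T_free, with T_free recovered
   from total T by inverting the single-ligand binding equilibrium.
2. The (T_S, U) table is fit with the saturating form u_max*T_S/(u_half+T_S).
3. With U fixed, (alpha, beta_D) are estimated by least squares against the
   uninhibited arm's steady-state totals.

Real measurements are not shipped; ``generate_synthetic_dataset`` produces
equivalent fixtures from known parameters for parameter-recovery validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit, least_squares

from .errors import DataError, FitError, InvalidParameterError
from .kinetics import InfluxParams, KineticParams, kinetics_steady_state

__all__ = [
    "TissueDataset",
    "FitResult",
    "fmol_per_mg_to_nM",
    "free_from_total_T",
    "infer_influx_table",
    "fit_influx_function",
    "fit_reductase",
    "generate_synthetic_dataset",
    "calibrate_default_influx",
]


def fmol_per_mg_to_nM(content: float, protein_conc: float) -> float:
    """Convert an AR content in fmol per mg cytosol protein to nM.

    content (fmol/mg) x protein_conc (g/L) x 10^3 (mg/g) = 10^3*content*pc
    fmol/L; 1 nM = 10^6 fmol/L, so the result is content*protein_conc*1e-3 nM.
    E.g. 1 fmol/mg at 200 g/L protein = 0.2 nM.
    """
    if content < 0 or protein_conc < 0:
        raise InvalidParameterError("conversion inputs must be >= 0")
    return content * protein_conc * 1e-3


def free_from_total_T(total_T: float, R_t: float, K_D: float) -> float:
    """Free ligand concentration given total ligand and an imposed AR pool.

    Inverts total = T_f + R_t*T_f/(K_D + T_f); the unique non-negative root
    of the quadratic T_f^2 + (K_D + R_t - total)*T_f - K_D*total = 0.
    """
    if total_T < 0 or R_t < 0:
        raise InvalidParameterError("concentrations must be >= 0")
    if K_D <= 0:
        raise InvalidParameterError(f"K_D must be > 0, got {K_D}")
    b = K_D + R_t - total_T
    disc = b * b + 4.0 * K_D * total_T
    return max(0.0, (-b + math.sqrt(disc)) / 2.0)


@dataclass(frozen=True)
class TissueDataset:
    """Steady-state serum/prostate androgen measurements.

    Columns: serum_T_nM, total_T_nM, total_DHT_nM, finasteride (0/1).
    """

    frame: pd.DataFrame

    COLUMNS = ("serum_T_nM", "total_T_nM", "total_DHT_nM", "finasteride")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise DataError(f"dataset missing columns: {sorted(missing)}")
        f = self.frame
        if (f[["serum_T_nM", "total_T_nM", "total_DHT_nM"]] < 0).any().any():
            raise DataError("concentrations must be >= 0")
        for flag, sub in f.groupby("finasteride"):
            if sub["serum_T_nM"].duplicated().any():
                raise DataError(f"duplicate serum_T_nM in finasteride={flag} arm")

    def arm(self, finasteride: bool) -> pd.DataFrame:
        sub = self.frame[self.frame["finasteride"] == int(finasteride)]
        return sub.sort_values("serum_T_nM").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TissueDataset":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares calibration step."""

    params: dict
    rss: float
    converged: bool
    n_obs: int
    message: str = ""

    def __post_init__(self):
        if not math.isfinite(self.rss):
            raise FitError(f"non-finite residual sum of squares: {self.rss}")

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params, "rss": self.rss,
            "converged": self.converged, "n_obs": self.n_obs,
            "message": self.message,
        }, indent=2)


def generate_synthetic_dataset(
    true_params: KineticParams,
    T_S_grid,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> TissueDataset:
    """Two-arm synthetic steady-state dataset from known kinetics parameters.

    For each serum T level, computes model steady-state totals in the
    uninhibited arm (alpha as given) and a fully inhibited arm (alpha = 0),
    then applies multiplicative log-normal noise with coefficient of
    variation ``noise_cv`` (mean-one; noise_cv = 0 is exact).  Deterministic
    for a given seed.
    """
    T_S_grid = np.asarray(T_S_grid, dtype=float)
    if T_S_grid.size == 0:
        raise DataError("T_S grid must be non-empty")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for fin, params in ((0, true_params), (1, replace(true_params, alpha=0.0))):
        for ts in T_S_grid:
            ss = kinetics_steady_state(params, float(ts))
            rows.append({
                "serum_T_nM": float(ts),
                "total_T_nM": ss.total_T,
                "total_DHT_nM": ss.total_DHT,
                "finasteride": fin,
            })
    frame = pd.DataFrame(rows)
    if noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + noise_cv ** 2))
        for col in ("total_T_nM", "total_DHT_nM"):
            factors = rng.lognormal(mean=-sig ** 2 / 2.0, sigma=sig, size=len(frame))
            frame[col] = frame[col] * factors
    return TissueDataset(frame)


def infer_influx_table(data: TissueDataset, kp: KineticParams) -> pd.DataFrame:
    """Influx U(T_S) from the inhibited arm's total-T measurements.

    With conversion blocked and the AR pool imposed at kp.R_t, steady state
    requires U = beta_T * T_free; T_free comes from the binding-equilibrium
    inversion.  Returns a DataFrame with columns T_S_nM, U_nM_per_h.
    """
    arm = data.arm(finasteride=True)
    if len(arm) < 2:
        raise DataError("need >= 2 finasteride rows to infer the influx table")
    K_D = kp.K_D_T
    U = [
        kp.beta_T * free_from_total_T(tot, kp.R_t, K_D)
        for tot in arm["total_T_nM"]
    ]
    return pd.DataFrame({"T_S_nM": arm["serum_T_nM"].to_numpy(), "U_nM_per_h": U})


def fit_influx_function(table: pd.DataFrame, form: str = "saturating") -> tuple[InfluxParams, FitResult]:
    """Least-squares fit of the saturating influx form through the origin."""
    if form != "saturating":
        raise InvalidParameterError(f"unsupported influx form {form!r}")
    if len(table) < 2:
        raise DataError("need >= 2 table points to fit the influx function")
    ts = table["T_S_nM"].to_numpy(dtype=float)
    us = table["U_nM_per_h"].to_numpy(dtype=float)

    def f(t, u_max, u_half):
        return u_max * t / (u_half + t)

    u0 = max(us.max(), 1e-6)
    h0 = max(np.median(ts), 1e-6)
    half_floor = 1e-6 * max(ts.max(), 1.0)
    try:
        popt, _ = curve_fit(
            f, ts, us, p0=[u0, h0],
            bounds=([0.0, half_floor], [np.inf, np.inf]), maxfev=20000,
        )
    except Exception as exc:
        raise FitError(f"influx fit failed: {exc}") from exc
    u_max, u_half = map(float, popt)
    resid = us - f(ts, u_max, u_half)
    rss = float(resid @ resid)
    # A u_half collapsing to its floor means the curve degenerated to a flat
    # line: the data carry no saturation information.
    degenerate = u_half <= 2 * half_floor or np.ptp(us) < 1e-12 * max(us.max(), 1.0)
    result = FitResult(
        params={"u_max": u_max, "u_half": u_half},
        rss=rss,
        converged=not degenerate,
        n_obs=len(table),
        message="degenerate (flat) influx table" if degenerate else "",
    )
    return InfluxParams(form="saturating", u_max=u_max, u_half=u_half), result


def fit_reductase(
    data: TissueDataset,
    influx_params: InfluxParams,
    kp: KineticParams,
) -> FitResult:
    """Estimate (alpha, beta_D) from the uninhibited arm's totals.

    Minimises ordinary least squares on total T and total DHT (nM, equally
    weighted) over model steady states, holding all other parameters and the
    supplied influx function fixed.
    """
    arm = data.arm(finasteride=False)
    if len(arm) < 2:
        raise DataError("need >= 2 non-finasteride rows to fit (alpha, beta_D)")
    ts = arm["serum_T_nM"].to_numpy(dtype=float)
    obs = np.concatenate([
        arm["total_T_nM"].to_numpy(dtype=float),
        arm["total_DHT_nM"].to_numpy(dtype=float),
    ])
    base = replace(kp, influx=influx_params)

    def residuals(x):
        a, bd = x
        p = replace(base, alpha=float(a), beta_D=float(max(bd, 1e-12)))
        tot_T, tot_D = [], []
        for t in ts:
            ss = kinetics_steady_state(p, float(t))
            tot_T.append(ss.total_T)
            tot_D.append(ss.total_DHT)
        return np.concatenate([tot_T, tot_D]) - obs

    x0 = np.array([max(kp.alpha, 0.5), max(kp.beta_D, 0.01)])
    try:
        sol = least_squares(
            residuals, x0, bounds=([0.0, 1e-6], [np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except Exception as exc:
        raise FitError(f"reductase fit failed: {exc}") from exc
    alpha_hat, beta_D_hat = map(float, sol.x)
    # If alpha ~ 0 no DHT is produced and beta_D has no leverage on the loss.
    jac_bd = np.linalg.norm(sol.jac[:, 1]) if sol.jac is not None else 0.0
    identifiable = alpha_hat > 1e-6 and jac_bd > 1e-8
    return FitResult(
        params={"alpha": alpha_hat, "beta_D": beta_D_hat,
                "beta_D_identifiable": bool(identifiable)},
        rss=float(sol.fun @ sol.fun),
        converged=bool(sol.success),
        n_obs=len(arm),
        message="" if identifiable else "beta_D unidentifiable (alpha ~ 0)",
    )


def calibrate_default_influx(
    kp: KineticParams | None = None,
    u_half: float = 10.0,
    anchor_T_S: float = 5.0,
    anchor_total_DHT: float = 50.0,
) -> InfluxParams:
    """Solve u_max so baseline steady-state total DHT hits the anchor.

    With u_half fixed, finds the u_max for which the steady state at
    ``anchor_T_S`` (R_t from ``kp``, default 45 nM) gives total intraprostatic
    DHT equal to ``anchor_total_DHT`` (default 50 nM, the middle of the normal
    40-60 nM range).  This is how the shipped influx defaults were frozen.
    """
    kp = kp or KineticParams()

    def total_dht(u_max):
        p = replace(kp, influx=InfluxParams(form="saturating", u_max=u_max, u_half=u_half))
        return kinetics_steady_state(p, anchor_T_S).total_DHT - anchor_total_DHT

    u_max = brentq(total_dht, 1e-6, 1e3, xtol=1e-12, rtol=1e-14)
    return InfluxParams(form="saturating", u_max=float(u_max), u_half=u_half)
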