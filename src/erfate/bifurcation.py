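"""Deterministic threshold, bistability and irreversibility analysis.

The stochastic dose-response window is underpinned by a deterministic
bifurcation structure: below a critical stress level S* the autophagic
(survival) steady state is reachable from rest; above it the apoptotic state
is the only attractor reached within the treatment horizon.  Hysteresis is
probed by quasi-static up/down scans of S with a fixed dwell per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import THETA_APO, CellState, _rhs_vec, classify, integrate, resting_state
from .params import ModelParameters
from .protocols import constant_stress

__all__ = ["apoptosis_threshold", "hysteresis_scan", "threshold_vs_kaau", "HysteresisResult"]


def _apoptotic_after(params: ModelParameters, S: float, t_end: float, state0: CellState, theta_apo: float) -> bool:
    traj = integrate(params, constant_stress(S, t_end), state0=state0, dt_out=t_end / 48)
    return classify(traj.final_state(), params, theta_apo=theta_apo) == "apoptotic"


def apoptosis_threshold(
    params: ModelParameters,
    S_range: tuple[float, float] = (0.0, 10.0),
    resolution: float = 0.01,
    t_end: float = 240.0,
    theta_apo: float = THETA_APO,
) -> float:
    """Smallest stress level S* whose constant application for ``t_end`` min
    drives the deterministic model from rest into the apoptotic state.

    Located by bisection to ``resolution``.  Returns ``inf`` when even the
    upper end of ``S_range`` does not trigger apoptosis within the horizon.
    """
    lo, hi = float(S_range[0]), float(S_range[1])
    rest = resting_state(params)
    if _apoptotic_after(params, lo, t_end, rest, theta_apo):
        return lo
    if not _apoptotic_after(params, hi, t_end, rest, theta_apo):
        return float("inf")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _apoptotic_after(params, mid, t_end, rest, theta_apo):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class HysteresisResult:
    """Outcome of a quasi-static up/down stress scan."""

    S_on: float       # activation level on the upward scan (inf if none)
    S_off: float      # deactivation level on the downward scan
    bistable: bool    # S_off < S_on
    irreversible: bool  # apoptotic state persists through the S = 0 dwell
    S_up: np.ndarray
    apo_up: np.ndarray   # equilibrated APO_act along the upward scan
    S_down: np.ndarray
    apo_down: np.ndarray


def _equilibrate(params: ModelParameters, S: float, y: np.ndarray, dwell: float, tol: float) -> np.ndarray:
    """Relax at constant S for up to ``dwell`` minutes (early exit below tol)."""
    t, chunk = 0.0, min(dwell, 100.0)
    while t < dwell:
        sol = solve_ivp(
            lambda tt, yy: _rhs_vec(yy, S, params),
            (0.0, chunk),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(_rhs_vec(y, S, params))) < tol:
            break
    return y


def hysteresis_scan(
    params: ModelParameters,
    S_up_grid: Sequence[float] | None = None,
    S_down_grid: Sequence[float] | None = None,
    dwell: float = 500.0,
    tol: float = 1e-8,
    theta_apo: float = THETA_APO,
) -> HysteresisResult:
    """Quasi-static hysteresis scan of the stress level.

    Upward: starting from rest, S is stepped up the grid, re-equilibrating at
    each level (dwell 500 min or convergence below ``tol``); ``S_on`` is the
    first level whose equilibrated state is apoptotic.  Downward: from the
    state at the top of the grid, S is stepped down; ``S_off`` is the first
    level where the state is no longer apoptotic.  ``irreversible`` means the
    apoptotic state survives the dwell at S = 0 — the model's point-of-no-
    return criterion.  (With the stressor removed the active chain is no
    longer replenished, so persistence is judged over the dwell horizon, the
    same finite-time convention as the washout experiments.)
    """
    if S_up_grid is None:
        S_up_grid = np.linspace(0.0, 10.0, 41)
    if S_down_grid is None:
        S_down_grid = np.asarray(S_up_grid)[::-1]
    S_up = np.asarray(S_up_grid, dtype=float)
    S_down = np.asarray(S_down_grid, dtype=float)

    y = resting_state(params).as_vector()
    apo_up = np.empty(len(S_up))
    S_on = float("inf")
    for i, S in enumerate(S_up):
        y = _equilibrate(params, S, y, dwell, tol)
        apo_up[i] = y[-1]
        if np.isinf(S_on) and y[-1] / params.APO_T > theta_apo:
            S_on = float(S)

    apo_down = np.empty(len(S_down))
    S_off = float("inf")
    for i, S in enumerate(S_down):
        y = _equilibrate(params, S, y, dwell, tol)
        apo_down[i] = y[-1]
        if np.isinf(S_off) and y[-1] / params.APO_T <= theta_apo:
            S_off = float(S)

    irreversible = np.isinf(S_off)
    if irreversible:
        S_off = float(S_down[-1])  # persisted through the bottom of the grid
    # in a graded (monostable) system the down-scan deactivates within one
    # grid step of S_on; require a wider gap before calling it bistable
    step = float(np.max(np.diff(S_up))) if len(S_up) > 1 else 0.0
    bistable = np.isfinite(S_on) and S_off < S_on - 1.5 * step
    return HysteresisResult(
        S_on=S_on,
        S_off=S_off,
        bistable=bool(bistable),
        irreversible=bool(irreversible),
        S_up=S_up,
        apo_up=apo_up,
        S_down=S_down,
        apo_down=apo_down,
    )


def threshold_vs_kaau(
    params: ModelParameters,
    kaau_p_grid: Sequence[float] = (0.2, 0.45, 0.7),
    **kwargs,
) -> np.ndarray:
    """Deterministic apoptosis threshold S* as a function of the autophagy
    activation strength kaau_p (autophagy modulation curve)."""
    return np.array(
        [apoptosis_threshold(params.replace(kaau_p=float(k)), **kwargs) for k in kaau_p_grid]
    )
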