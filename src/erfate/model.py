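"""Deterministic ODE core of the autophagy-apoptosis crosstalk network.

State variables (all concentrations, fractions of unit pools):

* ``ERSS`` — active ER stress sensor, driven by the stressor level S,
* ``AUT``  — active autophagy inducer, activated by ERSS through a
  zero-order-ultrasensitive (Goldbeter-Koshland type) cycle,
* ``APO_chain`` — ``n_steps`` sequentially modified forms of the apoptosis
  inducer; the last entry is the fully active form ``APO_act``.

Rate laws::

    dERSS/dt = ka_e*S*(ERSS_T - ERSS) - ki_e*ERSS
    dAUT/dt  = (kaau + kaau_p*ERSS) * (AUT_T - AUT)/(J_aa + AUT_T - AUT)
             - (kiau + kiau_p*APO_act) * AUT/(J_ia + AUT)
    chain:     forward per step  kaap*ERSS  (mass action on each form)
               backward per step kiap/(1 + k_fb*APO_act) + kiap_p*AUT

The unmodified apoptosis pool is implicit (``APO_T - sum(APO_chain)``), so the
chain conserves total APO exactly.  Mutual antagonism (AUT slows the chain's
forward progress via kiap_p; APO_act deactivates AUT via kiau_p) plus the
multistep chain and the positive feedback ``k_fb`` make apoptosis activation a
bistable, effectively irreversible switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParameters
from .protocols import StressProtocol

__all__ = [
    "CellState",
    "CellTrajectory",
    "rhs",
    "integrate",
    "resting_state",
    "classify",
    "IntegrationError",
]

#: default fate-classification thresholds (active fraction of the pool)
THETA_AUT = 0.5
THETA_APO = 0.5

FateLabel = Literal["apoptotic", "autophagic", "neither"]


class IntegrationError(RuntimeError):
    """Integration failed; carries the last valid time in ``t_last``."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time t = {t_last:g} min)")
        self.t_last = t_last


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of one cell."""

    t: float
    ERSS: float
    AUT: float
    APO_chain: np.ndarray  # length n_steps; last entry = APO_act

    def __post_init__(self) -> None:
        object.__setattr__(self, "APO_chain", np.asarray(self.APO_chain, dtype=float))

    @property
    def APO_act(self) -> float:
        return float(self.APO_chain[-1])

    def validate(self, params: ModelParameters, tol: float = 1e-9) -> None:
        """Raise ValueError naming the offending field if invariants fail."""
        if not -tol <= self.ERSS <= params.ERSS_T + tol:
            raise ValueError(f"ERSS = {self.ERSS} outside [0, {params.ERSS_T}]")
        if not -tol <= self.AUT <= params.AUT_T + tol:
            raise ValueError(f"AUT = {self.AUT} outside [0, {params.AUT_T}]")
        if len(self.APO_chain) != params.n_steps:
            raise ValueError(
                f"APO_chain has length {len(self.APO_chain)}, expected {params.n_steps}"
            )
        if np.any(self.APO_chain < -tol):
            raise ValueError(f"APO_chain has negative entries: {self.APO_chain}")
        if self.APO_chain.sum() > params.APO_T + tol:
            raise ValueError(
                f"sum(APO_chain) = {self.APO_chain.sum()} exceeds APO_T = {params.APO_T}"
            )

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.ERSS, self.AUT], self.APO_chain))

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray) -> "CellState":
        return cls(t=float(t), ERSS=float(y[0]), AUT=float(y[1]), APO_chain=y[2:].copy())


def zeros_state(params: ModelParameters, t: float = 0.0) -> CellState:
    """All-inactive state (zero activities)."""
    return CellState(t=t, ERSS=0.0, AUT=0.0, APO_chain=np.zeros(params.n_steps))


# -- right-hand side ---------------------------------------------------------


def _rhs_vec(y: np.ndarray, S: float, p: ModelParameters) -> np.ndarray:
    """ODE right-hand side on the flat state vector [ERSS, AUT, APO_1..n]."""
    erss, aut = y[0], y[1]
    chain = y[2:]
    apo_act = chain[-1]
    dy = np.empty_like(y)

    dy[0] = p.ka_e * S * (p.ERSS_T - erss) - p.ki_e * erss
    dy[1] = (p.kaau + p.kaau_p * erss) * (p.AUT_T - aut) / (p.J_aa + p.AUT_T - aut) - (
        p.kiau + p.kiau_p * apo_act
    ) * aut / (p.J_ia + aut)

    kf = p.kaap * erss
    kb = p.kiap / (1.0 + p.k_fb * apo_act) + p.kiap_p * aut
    pool = p.APO_T - chain.sum()  # unmodified form
    below = np.concatenate(([pool], chain[:-1]))
    above = np.concatenate((chain[1:], [0.0]))
    # d(chain_i)/dt = inflow from below + backflow from above - outflow
    dy[2:] = kf * below + kb * above - (kb * chain)
    dy[2:-1] -= kf * chain[:-1]
    return dy


def rhs(state: CellState, S: float, params: ModelParameters) -> np.ndarray:
    """Time derivatives [dERSS, dAUT, dAPO_1 .. dAPO_n] at ``state``.

    Raises a domain error naming the offending field for negative S or a
    malformed state.
    """
    if S < 0:
        raise ValueError(f"stressor level S = {S} must be >= 0")
    state.validate(params)
    return _rhs_vec(state.as_vector(), float(S), params)


# -- trajectories ------------------------------------------------------------


@dataclass(frozen=True)
class CellTrajectory:
    """Time course of one cell on a uniform output grid.

    ``y`` has shape (n_times, 2 + n_steps) with columns
    ``ERSS, AUT, APO_1 .. APO_n``.
    """

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    protocol: StressProtocol
    stochastic: bool = False
    seed: int | None = None

    @property
    def ERSS(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def AUT(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def APO_chain(self) -> np.ndarray:
        return self.y[:, 2:]

    @property
    def APO_act(self) -> np.ndarray:
        return self.y[:, -1]

    def state_at(self, t: float) -> CellState:
        """State at the output grid point nearest to ``t``."""
        i = int(np.argmin(np.abs(self.t - t)))
        return CellState.from_vector(self.t[i], self.y[i])

    def final_state(self) -> CellState:
        return CellState.from_vector(self.t[-1], self.y[-1])

    def fate(self, theta_aut: float = THETA_AUT, theta_apo: float = THETA_APO) -> FateLabel:
        """Fate label of the final state."""
        return classify(self.final_state(), self.params, theta_aut, theta_apo)

    def activation_time(self, theta_apo: float = THETA_APO) -> float | None:
        """First grid time at which APO_act crosses theta_apo*APO_T, or None."""
        above = self.APO_act > theta_apo * self.params.APO_T
        idx = np.flatnonzero(above)
        return float(self.t[idx[0]]) if idx.size else None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.t, "ERSS": self.ERSS, "AUT": self.AUT}
        for i in range(self.params.n_steps):
            cols[f"APO_{i + 1}"] = self.y[:, 2 + i]
        df = pd.DataFrame(cols)
        df["fate"] = self.fate()
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate(
    params: ModelParameters,
    protocol: StressProtocol,
    state0: CellState | None = None,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CellTrajectory:
    """Integrate the ODEs under a stress protocol.

    Uses LSODA with relative/absolute local error control (``rtol``/``atol``);
    each piecewise-constant protocol segment is integrated separately so the
    stressor discontinuities fall exactly on integration restarts.  Output is
    sampled on a uniform grid of spacing ``dt_out``.  State invariants
    (bounds, chain conservation) are checked at every output point and a
    breach beyond 100x the error tolerance raises rather than being clipped.
    """
    if state0 is None:
        state0 = resting_state(params)
    if not dt_out > 0:
        raise ValueError("dt_out must be > 0")
    state0.validate(params)

    t_grid = np.arange(0.0, protocol.t_end + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= protocol.t_end + 1e-12]
    out = np.empty((len(t_grid), 2 + params.n_steps))
    y = state0.as_vector().copy()
    out[0] = y
    filled = 1  # t = 0 is the initial state

    edges = protocol.boundaries()
    for (t0, S), t1 in zip(protocol.segments, edges[1:]):
        # grid points inside (t0, t1]; the segment end is always evaluated so
        # the next segment restarts from the exact boundary state
        mask = (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = np.append(t_grid[mask], t1) if not mask.any() or t_grid[mask][-1] < t1 - 1e-12 else t_grid[mask]
        sol = solve_ivp(
            lambda t, yy: _rhs_vec(yy, S, params),
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed: {sol.message}", sol.t[-1] if sol.t.size else t0
            )
        n = int(mask.sum())
        if n:
            out[filled : filled + n] = sol.y[:, :n].T
            filled += n
        y = sol.y[:, -1].copy()

    _check_invariants(t_grid, out, params, tol=100 * max(rtol, atol))
    return CellTrajectory(t=t_grid, y=out, params=params, protocol=protocol)


def _check_invariants(t: np.ndarray, y: np.ndarray, params: ModelParameters, tol: float) -> None:
    """Bounds and conservation at every output point; breach raises."""
    bad = np.flatnonzero(
        (y[:, 0] < -tol)
        | (y[:, 0] > params.ERSS_T + tol)
        | (y[:, 1] < -tol)
        | (y[:, 1] > params.AUT_T + tol)
        | (y[:, 2:].min(axis=1) < -tol)
        | (y[:, 2:].sum(axis=1) > params.APO_T + tol)
    )
    if bad.size:
        i = bad[0]
        raise IntegrationError(
            f"state invariant breached beyond tolerance {tol:g} at t = {t[i]:g}", float(t[i])
        )


# -- resting state and fate classification -----------------------------------


def resting_state(
    params: ModelParameters,
    tol: float = 1e-9,
    horizon: float = 20000.0,
    chunk: float = 500.0,
) -> CellState:
    """Steady state at S = 0, reached by relaxation from zero activities.

    Integrates in chunks until the max absolute derivative falls below
    ``tol`` (1/min); raises on non-convergence within ``horizon`` minutes.
    """
    y = zeros_state(params).as_vector()
    t = 0.0
    while t < horizon:
        sol = solve_ivp(
            lambda tt, yy: _rhs_vec(yy, 0.0, params),
            (0.0, chunk),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise IntegrationError(f"resting-state relaxation failed: {sol.message}", t)
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(_rhs_vec(y, 0.0, params))) < tol:
            return CellState.from_vector(0.0, np.maximum(y, 0.0))
    raise IntegrationError(
        f"resting state did not converge to |dy/dt| < {tol:g} within {horizon:g} min", t
    )


def classify(
    state: CellState,
    params: ModelParameters,
    theta_aut: float = THETA_AUT,
    theta_apo: float = THETA_APO,
) -> FateLabel:
    """Fate label of a cell state.

    "apoptotic" if the active apoptosis fraction exceeds ``theta_apo``,
    else "autophagic" if the active autophagy fraction exceeds ``theta_aut``,
    else "neither".  Apoptosis takes precedence: the two programs are treated
    as mutually exclusive with death dominant.
    """
    if not 0 < theta_aut < 1 or not 0 < theta_apo < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    if state.APO_act / params.APO_T > theta_apo:
        return "apoptotic"
    if state.AUT / params.AUT_T > theta_aut:
        return "autophagic"
    return "neither"
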