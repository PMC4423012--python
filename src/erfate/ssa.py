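"""Exact stochastic (Gillespie) single-cell engine.

Every additive rate term of the deterministic model becomes one reaction
channel whose propensity is ``Omega * term(counts / Omega)``, so that
``sum(stoichiometry * propensity) / Omega`` recovers the ODE right-hand side
exactly at any state.  Molecule counts are integers; the conserved pools
(inactive sensor, inactive autophagy inducer, unmodified apoptosis inducer)
are carried implicitly as complements, which keeps conservation exact in
integer arithmetic.

The piecewise-constant stressor is handled exactly: within a protocol segment
all propensities are time-independent, and a next-reaction time that would
overshoot a segment boundary is truncated there (the event is discarded and
propensities are re-evaluated under the new stressor level) — the standard
exact treatment for rates with jump discontinuities.

Per-cell seeds are spawned from the master seed via
``numpy.random.SeedSequence(master_seed).generate_state(n_cells) % 2**31``,
a documented, platform-stable scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .model import THETA_APO, THETA_AUT, CellTrajectory, classify
from .params import ModelParameters
from .protocols import StressProtocol

__all__ = ["ReactionSet", "EnsembleResult", "to_reactions", "simulate_cell", "simulate_ensemble"]


# -- reaction-network view ----------------------------------------------------


@dataclass(frozen=True)
class ReactionSet:
    """The model as a list of (stoichiometry, propensity) reaction channels.

    Species order: ``[ERSS, AUT, APO_1, ..., APO_n]`` (active forms; the
    complements are implicit).  Propensities are functions
    ``(counts: int array, S: float) -> float`` of molecule counts.
    """

    species: tuple[str, ...]
    stoichiometry: np.ndarray  # (n_reactions, n_species) integer changes
    propensities: tuple[Callable[[np.ndarray, float], float], ...]
    params: ModelParameters

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[0]

    def propensity_vector(self, counts: np.ndarray, S: float) -> np.ndarray:
        return np.array([a(counts, S) for a in self.propensities])

    def drift(self, counts: np.ndarray, S: float) -> np.ndarray:
        """sum(stoich * propensity) / Omega — equals the ODE rhs at counts/Omega."""
        a = self.propensity_vector(counts, S)
        return (self.stoichiometry.T @ a) / self.params.Omega


def to_reactions(params: ModelParameters) -> ReactionSet:
    """Map the ODE terms onto reaction channels (one per additive term)."""
    if params.Omega < 10:
        warnings.warn(
            f"Omega = {params.Omega} < 10 is a deep-noise regime outside the "
            "calibrated behavior of the model.",
            stacklevel=2,
        )
    p = params
    W = float(p.Omega)
    e_tot, a_tot, p_tot = p.pool_counts()
    n = p.n_steps
    species = ("ERSS", "AUT") + tuple(f"APO_{i + 1}" for i in range(n))
    n_sp = 2 + n

    stoich: list[np.ndarray] = []
    props: list[Callable[[np.ndarray, float], float]] = []

    def add(changes: dict[int, int], prop: Callable[[np.ndarray, float], float]) -> None:
        v = np.zeros(n_sp, dtype=np.int64)
        for i, c in changes.items():
            v[i] = c
        stoich.append(v)
        props.append(prop)

    # ER stress sensor
    add({0: +1}, lambda c, S: p.ka_e * S * (e_tot - c[0]))
    add({0: -1}, lambda c, S: p.ki_e * c[0])
    # autophagy inducer (zero-order ultrasensitive cycle)
    add(
        {1: +1},
        lambda c, S: (p.kaau + p.kaau_p * c[0] / W) * (a_tot - c[1]) / (p.J_aa + (a_tot - c[1]) / W),
    )
    add(
        {1: -1},
        lambda c, S: (p.kiau + p.kiau_p * c[-1] / W) * c[1] / (p.J_ia + c[1] / W),
    )
    # apoptosis chain: forward steps (kaap * ERSS per step, mass action)
    for i in range(n):
        if i == 0:
            # unmodified pool -> APO_1
            add({2: +1}, lambda c, S: p.kaap * (c[0] / W) * (p_tot - c[2:].sum()))
        else:
            j = i  # APO_i -> APO_{i+1}
            add(
                {2 + j - 1: -1, 2 + j: +1},
                lambda c, S, j=j: p.kaap * (c[0] / W) * c[2 + j - 1],
            )
    # apoptosis chain: backward steps (feedback-suppressed basal + AUT-driven)
    def kb(c: np.ndarray) -> float:
        return p.kiap / (1.0 + p.k_fb * c[-1] / W) + p.kiap_p * c[1] / W

    for i in range(n):
        if i == 0:
            add({2: -1}, lambda c, S: kb(c) * c[2])
        else:
            j = i
            add({2 + j: -1, 2 + j - 1: +1}, lambda c, S, j=j: kb(c) * c[2 + j])

    return ReactionSet(
        species=species,
        stoichiometry=np.array(stoich),
        propensities=tuple(props),
        params=params,
    )


# -- fast kernel --------------------------------------------------------------


@njit(cache=True)
def _ssa_run(pvec, n_steps, e_tot, a_tot, p_tot, c0, seg_starts, seg_levels, t_end, t_grid, seed):
    """Direct-method SSA over the piecewise-constant protocol.

    Returns (grid_states, final_counts, status); status 1 flags a non-finite
    propensity.  Propensities mirror ``to_reactions`` exactly (asserted in the
    test suite).
    """
    ka_e, ki_e = pvec[0], pvec[1]
    kaau, kaau_p, J_aa, J_ia, kiau, kiau_p = pvec[2], pvec[3], pvec[4], pvec[5], pvec[6], pvec[7]
    kaap, kiap, kiap_p, k_fb = pvec[8], pvec[9], pvec[10], pvec[11]
    W = pvec[12]

    np.random.seed(seed)
    n_sp = 2 + n_steps
    n_rx = 4 + 2 * n_steps
    c = c0.copy()
    a = np.zeros(n_rx)
    n_grid = t_grid.shape[0]
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    g = 0
    t = 0.0
    n_seg = seg_starts.shape[0]

    for si in range(n_seg):
        S = seg_levels[si]
        seg_end = t_end if si == n_seg - 1 else seg_starts[si + 1]
        while t < seg_end:
            # propensities at current counts
            e, au = c[0], c[1]
            pn = c[n_sp - 1]
            chain_sum = 0
            for k in range(n_steps):
                chain_sum += c[2 + k]
            p0 = p_tot - chain_sum
            a[0] = ka_e * S * (e_tot - e)
            a[1] = ki_e * e
            a[2] = (kaau + kaau_p * e / W) * (a_tot - au) / (J_aa + (a_tot - au) / W)
            a[3] = (kiau + kiau_p * pn / W) * au / (J_ia + au / W)
            kfw = kaap * (e / W)
            kbw = kiap / (1.0 + k_fb * pn / W) + kiap_p * au / W
            a[4] = kfw * p0
            for k in range(1, n_steps):
                a[4 + k] = kfw * c[2 + k - 1]
            for k in range(n_steps):
                a[4 + n_steps + k] = kbw * c[2 + k]

            a0 = 0.0
            for k in range(n_rx):
                a0 += a[k]
            if not np.isfinite(a0):
                return out, c, 1
            if a0 <= 0.0:
                t_next = seg_end
                rx = -1
            else:
                dt = np.random.exponential(1.0) / a0
                if t + dt >= seg_end:
                    t_next = seg_end
                    rx = -1  # truncated at the boundary: no reaction fires
                else:
                    t_next = t + dt
                    r = np.random.random() * a0
                    acc = 0.0
                    rx = n_rx - 1
                    for k in range(n_rx):
                        acc += a[k]
                        if r < acc:
                            rx = k
                            break

            # sample the grid with the pre-event state
            while g < n_grid and t_grid[g] < t_next:
                for k in range(n_sp):
                    out[g, k] = c[k]
                g += 1

            if rx >= 0:
                if rx == 0:
                    c[0] += 1
                elif rx == 1:
                    c[0] -= 1
                elif rx == 2:
                    c[1] += 1
                elif rx == 3:
                    c[1] -= 1
                elif rx < 4 + n_steps:
                    k = rx - 4  # forward step k: APO_k -> APO_{k+1} (k=0: pool -> APO_1)
                    if k > 0:
                        c[2 + k - 1] -= 1
                    c[2 + k] += 1
                else:
                    k = rx - 4 - n_steps  # backward step k: APO_{k+1} -> APO_k
                    c[2 + k] -= 1
                    if k > 0:
                        c[2 + k - 1] += 1
            t = t_next

    while g < n_grid:
        for k in range(n_sp):
            out[g, k] = c[k]
        g += 1
    return out, c, 0


def _param_vector(p: ModelParameters) -> np.ndarray:
    return np.array(
        [p.ka_e, p.ki_e, p.kaau, p.kaau_p, p.J_aa, p.J_ia, p.kiau, p.kiau_p,
         p.kaap, p.kiap, p.kiap_p, p.k_fb, float(p.Omega)]
    )


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-cell seeds from a master seed (SeedSequence stream, mod 2**31)."""
    return (np.random.SeedSequence(master_seed).generate_state(n) % (2**31)).astype(np.int64)


# -- public simulation API ----------------------------------------------------


class PropensityError(RuntimeError):
    """Non-finite propensity; carries a snapshot of the molecule counts."""

    def __init__(self, counts: np.ndarray):
        super().__init__(f"non-finite propensity at counts {counts.tolist()}")
        self.counts = counts


def _initial_counts(params: ModelParameters, state0) -> np.ndarray:
    from .model import resting_state

    if state0 is None:
        state0 = resting_state(params)
    c = np.rint(state0.as_vector() * params.Omega).astype(np.int64)
    return c


def simulate_cell(
    params: ModelParameters,
    protocol: StressProtocol,
    seed: int,
    dt_out: float = 1.0,
    state0=None,
) -> CellTrajectory:
    """One exact stochastic trajectory, sampled on a uniform output grid.

    The initial condition defaults to the deterministic resting state rounded
    to molecule counts.  Identical inputs and seed give a bit-identical
    trajectory.
    """
    if not dt_out > 0:
        raise ValueError("dt_out must be > 0")
    e_tot, a_tot, p_tot = params.pool_counts()
    c0 = _initial_counts(params, state0)
    t_grid = np.arange(0.0, protocol.t_end + 0.5 * dt_out, dt_out)
    t_grid = t_grid[t_grid <= protocol.t_end + 1e-12]
    seg_starts = np.array([t for t, _ in protocol.segments])
    seg_levels = np.array([s for _, s in protocol.segments])
    counts, final, status = _ssa_run(
        _param_vector(params),
        params.n_steps,
        e_tot,
        a_tot,
        p_tot,
        c0,
        seg_starts,
        seg_levels,
        float(protocol.t_end),
        t_grid,
        int(seed) % (2**31),
    )
    if status != 0:
        raise PropensityError(final)
    y = counts.astype(float) / params.Omega
    return CellTrajectory(
        t=t_grid, y=y, params=params, protocol=protocol, stochastic=True, seed=int(seed)
    )


@dataclass(frozen=True)
class EnsembleResult:
    """A seeded collection of stochastic single-cell trajectories."""

    trajectories: tuple[CellTrajectory, ...]
    seeds: np.ndarray
    master_seed: int
    params: ModelParameters
    protocol: StressProtocol
    theta_aut: float = THETA_AUT
    theta_apo: float = THETA_APO

    @property
    def n_cells(self) -> int:
        return len(self.trajectories)

    @property
    def t(self) -> np.ndarray:
        return self.trajectories[0].t

    def fates(self, t_eval: float | None = None) -> list[str]:
        """Per-cell fate labels at ``t_eval`` (default: end of the horizon)."""
        if t_eval is None:
            t_eval = float(self.t[-1])
        return [
            classify(tr.state_at(t_eval), self.params, self.theta_aut, self.theta_apo)
            for tr in self.trajectories
        ]

    def activation_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, censored): first crossing of theta_apo; censored cells carry
        the horizon time with censored flag True."""
        horizon = float(self.t[-1])
        times = np.empty(self.n_cells)
        censored = np.zeros(self.n_cells, dtype=bool)
        for i, tr in enumerate(self.trajectories):
            at = tr.activation_time(self.theta_apo)
            if at is None:
                times[i] = horizon
                censored[i] = True
            else:
                times[i] = at
        return times, censored

    def mean_y(self) -> np.ndarray:
        return np.mean([tr.y for tr in self.trajectories], axis=0)


def simulate_ensemble(
    params: ModelParameters,
    protocol: StressProtocol,
    n_cells: int = 50,
    master_seed: int = 0,
    dt_out: float = 1.0,
    extrinsic_sigma: float = 0.0,
    theta_aut: float = THETA_AUT,
    theta_apo: float = THETA_APO,
) -> EnsembleResult:
    """Independent stochastic cells with reproducibly spawned seeds.

    ``extrinsic_sigma > 0`` adds cell-to-cell variability of the stressor
    strength: each cell sees the protocol levels multiplied by a lognormal
    factor ``exp(sigma * z)`` (intrinsic molecular noise only by default).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seeds = spawn_seeds(master_seed, n_cells)
    if extrinsic_sigma > 0:
        factors = np.exp(
            extrinsic_sigma * np.random.default_rng(np.random.SeedSequence(master_seed)).standard_normal(n_cells)
        )
    else:
        factors = np.ones(n_cells)
    from .model import resting_state

    state0 = resting_state(params)
    trajs = []
    for i in range(n_cells):
        proto_i = (
            protocol
            if factors[i] == 1.0
            else StressProtocol(
                tuple((t, s * factors[i]) for t, s in protocol.segments), protocol.t_end
            )
        )
        trajs.append(simulate_cell(params, proto_i, int(seeds[i]), dt_out=dt_out, state0=state0))
    return EnsembleResult(
        trajectories=tuple(trajs),
        seeds=seeds,
        master_seed=int(master_seed),
        params=params,
        protocol=protocol,
        theta_aut=theta_aut,
        theta_apo=theta_apo,
    )
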