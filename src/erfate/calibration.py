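"""Calibration of the free rate constants against printed simulation anchors.

The model's full kinetic parameter set is not available in closed form, so
the package fixes it by calibration: a seeded coarse random search plus local
refinement that minimizes deviations from a set of behavioral anchors — the
deterministic threshold window (3 < S* < 5), the stochastic dose-response
window (autophagy-majority below S = 3, apoptosis-majority from S = 5), the
washout commitment curve (low commitment at early washout, ~95% apoptotic at
105 min), and the transient autophagy peak preceding apoptosis at S0 = 5.

Stochastic anchors are evaluated with fixed sub-seeds (common random numbers
across candidates) so the search surface is deterministic for a given master
seed.  Anchors with ``weight = inf`` are hard constraints: candidates are
ranked first by total hard violation, then by the weighted soft residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bifurcation import apoptosis_threshold
from .model import integrate, resting_state
from .params import ModelParameters
from .population import dose_response_scan, washout_commitment_curve
from .protocols import constant_stress

__all__ = ["Anchor", "AnchorSet", "default_anchors", "evaluate_anchors", "calibrate"]


@dataclass(frozen=True)
class Anchor:
    """One behavioral target: a named statistic constrained to [lo, hi].

    ``weight = inf`` marks a hard anchor (constraint); finite weights scale
    the soft residual.  ``source`` records where the printed target comes
    from.  The residual of value v is its distance outside [lo, hi], scaled
    by ``scale``.
    """

    id: str
    statistic: str
    args: Mapping[str, float]
    lo: float
    hi: float
    weight: float = 1.0
    scale: float = 1.0
    source: str = ""

    def residual(self, value: float) -> float:
        if self.lo <= value <= self.hi:
            return 0.0
        d = (self.lo - value) if value < self.lo else (value - self.hi)
        return d / self.scale


@dataclass(frozen=True)
class AnchorSet:
    """A collection of anchors evaluated with shared simulations."""

    anchors: tuple[Anchor, ...]
    n_cells: int = 50
    t_end: float = 240.0

    def __post_init__(self) -> None:
        if any(a.scale <= 0 for a in self.anchors):
            raise ValueError("anchor scales must be > 0")
        if any(a.hi < a.lo for a in self.anchors):
            raise ValueError("anchor interval must have lo <= hi")

    def ids(self) -> list[str]:
        return [a.id for a in self.anchors]


def default_anchors(n_cells: int = 50) -> AnchorSet:
    """The calibration targets shipped with the package.

    a1  deterministic threshold window; a2* stochastic dose-response window;
    a3* washout commitment curve; a4 autophagy transient precedes apoptosis.
    """
    H = math.inf
    a = [
        Anchor("a1", "S_star", {}, 3.05, 4.95, H, 1.0,
               "threshold window 3 < S* < 5"),
        # dose-response at 240 min
        Anchor("a2_S1_apo", "f_apo", {"S0": 1}, 0.0, 0.1, H, 0.1,
               "S0=1: apoptotic fraction stays low"),
        Anchor("a2_S1_aut", "f_aut", {"S0": 1}, 0.55, 1.0, H, 0.1,
               "S0=1: autophagy-majority"),
        Anchor("a2_S2_apo", "f_apo", {"S0": 2}, 0.0, 0.25, H, 0.1,
               "S0=2: apoptotic fraction below one half"),
        Anchor("a2_S2_aut", "f_aut", {"S0": 2}, 0.55, 1.0, H, 0.1,
               "S0=2: autophagy-majority"),
        Anchor("a2_S3_aut", "f_aut", {"S0": 3}, 0.0, 0.5, 1.0, 0.1,
               "S0=3: autophagy loses its outright majority (window edge)"),
        Anchor("a2_S3_apo", "f_apo", {"S0": 3}, 0.15, 0.5, 1.0, 0.1,
               "S0=3: apoptosis present but not the majority (coexistence)"),
        Anchor("a2_S4_apo", "f_apo", {"S0": 4}, 0.2, 0.5, 1.0, 0.1,
               "S0=4: coexistence of both fates"),
        Anchor("a2_S4_aut", "f_aut", {"S0": 4}, 0.2, 0.8, 1.0, 0.1,
               "S0=4: coexistence of both fates"),
        Anchor("a2_S5_apo", "f_apo", {"S0": 5}, 0.55, 1.0, H, 0.1,
               "S0=5: apoptosis-majority"),
        Anchor("a2_S6_apo", "f_apo", {"S0": 6}, 0.6, 1.0, H, 0.1,
               "S0=6: apoptosis-majority"),
        Anchor("a2_S10_apo", "f_apo", {"S0": 10}, 0.9, 1.0, H, 0.1,
               "S0=10: essentially all cells apoptotic"),
        # washout commitment (S0=10, evaluate 120 min post washout)
        Anchor("a3_w15", "f_apo_washout", {"t_washout": 15}, 0.0, 0.15, H, 0.1,
               "washout at 15 min: commitment still low"),
        Anchor("a3_w30", "f_apo_washout", {"t_washout": 30}, 0.0, 0.35, 1.0, 0.1,
               "washout at 30 min: rise is only beginning"),
        Anchor("a3_w60", "f_apo_washout", {"t_washout": 60}, 0.25, 0.85, 1.0, 0.1,
               "washout at 60 min: mid-rise"),
        Anchor("a3_w90", "f_apo_washout", {"t_washout": 90}, 0.7, 1.0, 1.0, 0.1,
               "washout at 90 min: rise essentially complete"),
        Anchor("a3_w105", "f_apo_washout", {"t_washout": 105}, 0.85, 1.0, H, 0.1,
               "washout at 105 min: ~95% of the population apoptotic"),
        Anchor("a4", "aut_peak_before_apo", {"S0": 5}, 1.0, 1.0, H, 1.0,
               "S0=5: transient autophagy peak precedes apoptosis activation"),
    ]
    return AnchorSet(tuple(a), n_cells=n_cells)


# -- anchor evaluation --------------------------------------------------------


def _evaluate_all(params: ModelParameters, anchors: AnchorSet, master_seed: int) -> dict[str, float]:
    """Compute every anchor statistic, sharing ensembles across anchors."""
    values: dict[str, float] = {}
    need_dose = sorted(
        {a.args["S0"] for a in anchors.anchors if a.statistic in ("f_apo", "f_aut")}
    )
    need_wash = sorted(
        {a.args["t_washout"] for a in anchors.anchors if a.statistic == "f_apo_washout"}
    )
    dose: dict[float, tuple[float, float]] = {}
    if need_dose:
        curve = dose_response_scan(
            params,
            S_grid=need_dose,
            n_cells=anchors.n_cells,
            t_end=anchors.t_end,
            t_eval=anchors.t_end,
            master_seed=master_seed,
        )
        dose = {
            s: (fa, fp)
            for s, fa, fp in zip(curve.values, curve.frac_autophagic, curve.frac_apoptotic)
        }
    wash: dict[float, float] = {}
    if need_wash:
        curve = washout_commitment_curve(
            params,
            washout_grid=need_wash,
            n_cells=anchors.n_cells,
            master_seed=master_seed + 1,
        )
        wash = {t: fp for t, fp in zip(curve.values, curve.frac_apoptotic)}

    for a in anchors.anchors:
        if a.statistic == "S_star":
            kaau_p = a.args.get("kaau_p")
            p = params if kaau_p is None else params.replace(kaau_p=kaau_p)
            values[a.id] = apoptosis_threshold(p, resolution=0.05)
        elif a.statistic == "f_apo":
            values[a.id] = dose[a.args["S0"]][1]
        elif a.statistic == "f_aut":
            values[a.id] = dose[a.args["S0"]][0]
        elif a.statistic == "f_apo_washout":
            values[a.id] = wash[a.args["t_washout"]]
        elif a.statistic == "aut_peak_before_apo":
            traj = integrate(params, constant_stress(a.args["S0"], anchors.t_end), dt_out=1.0)
            t_apo = traj.activation_time()
            t_peak = float(traj.t[int(np.argmax(traj.AUT))])
            peak_high = traj.AUT.max() > 0.5 * params.AUT_T
            values[a.id] = float(peak_high and t_apo is not None and t_peak < t_apo)
        else:
            raise ValueError(f"unknown anchor statistic {a.statistic!r}")
    return values


def evaluate_anchors(
    params: ModelParameters, anchors: AnchorSet, master_seed: int
) -> dict[str, dict[str, float]]:
    """Per-anchor report: value, residual, and whether a hard anchor is violated."""
    values = _evaluate_all(params, anchors, master_seed)
    report = {}
    for a in anchors.anchors:
        r = a.residual(values[a.id])
        report[a.id] = {
            "value": values[a.id],
            "residual": r,
            "hard": math.isinf(a.weight),
            "violated": r > 0,
        }
    return report


def _score(anchors: AnchorSet, values: Mapping[str, float]) -> tuple[float, float]:
    """(hard violation magnitude, weighted soft residual)."""
    hard = soft = 0.0
    for a in anchors.anchors:
        r = a.residual(values[a.id])
        if math.isinf(a.weight):
            hard += r
        else:
            soft += a.weight * r
    return hard, soft


# -- search -------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "kaap": (0.1, 0.3),
    "kiap": (0.01, 0.05),
    "kiap_p": (0.08, 0.3),
    "kiau_p": (0.8, 2.5),
    "k_fb": (100.0, 400.0),
    "ka_e": (0.05, 0.25),
    "ki_e": (1.0, 3.0),
    "kaau_p": (0.45, 0.68),
}


def calibrate(
    search_space: Mapping[str, tuple[float, float]] | None = None,
    anchors: AnchorSet | None = None,
    master_seed: int = 0,
    budget: int = 60,
    start: ModelParameters | None = None,
) -> tuple[ModelParameters, dict]:
    """Seeded random search + coordinate refinement over the free parameters.

    ``budget`` counts model evaluations (each evaluation runs every anchor
    with common random numbers).  Returns the best parameter set and a report
    with per-anchor residuals; if hard anchors remain violated the report's
    ``"converged"`` flag is False and ``"violated"`` lists them.
    """
    if search_space is None:
        search_space = DEFAULT_SEARCH_SPACE
    if anchors is None:
        anchors = default_anchors()
    base = start if start is not None else ModelParameters()
    rng = np.random.default_rng(master_seed)
    names = list(search_space)

    def make(vals: Sequence[float]) -> ModelParameters:
        return base.replace(**dict(zip(names, vals)))

    def evaluate(vals: Sequence[float]) -> tuple[tuple[float, float], dict[str, float]]:
        values = _evaluate_all(make(vals), anchors, master_seed)
        return _score(anchors, values), values

    # start point: the base parameters (clipped into the box), then random draws
    x0 = np.array([min(max(getattr(base, n), search_space[n][0]), search_space[n][1]) for n in names])
    best_x, (best_score, best_vals) = x0, evaluate(x0)
    n_eval = 1
    n_random = max(0, min(budget // 3, budget - n_eval))
    lo = np.array([search_space[n][0] for n in names])
    hi = np.array([search_space[n][1] for n in names])
    for _ in range(n_random):
        x = lo * (hi / lo) ** rng.random(len(names))  # log-uniform draw
        score, vals = evaluate(x)
        n_eval += 1
        if score < best_score:
            best_x, best_score, best_vals = x, score, vals

    # coordinate-wise multiplicative refinement around the incumbent
    step = 0.3
    while n_eval < budget and step > 0.02:
        improved = False
        for i in rng.permutation(len(names)):
            for sgn in (+1, -1):
                if n_eval >= budget:
                    break
                x = best_x.copy()
                x[i] = float(np.clip(x[i] * (1 + sgn * step), lo[i], hi[i]))
                if x[i] == best_x[i]:
                    continue
                score, vals = evaluate(x)
                n_eval += 1
                if score < best_score:
                    best_x, best_score, best_vals = x, score, vals
                    improved = True
        if not improved:
            step /= 2

    params = make(best_x)
    report = {
        "anchors": {
            a.id: {
                "value": best_vals[a.id],
                "residual": a.residual(best_vals[a.id]),
                "target": [a.lo, a.hi],
                "hard": math.isinf(a.weight),
                "source": a.source,
            }
            for a in anchors.anchors
        },
        "hard_violation": best_score[0],
        "soft_residual": best_score[1],
        "converged": best_score[0] == 0.0,
        "violated": [
            a.id
            for a in anchors.anchors
            if math.isinf(a.weight) and a.residual(best_vals[a.id]) > 0
        ],
        "n_evaluations": n_eval,
        "master_seed": master_seed,
        "search_space": {n: list(search_space[n]) for n in names},
        "best": {n: float(v) for n, v in zip(names, best_x)},
    }
    return params, report
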