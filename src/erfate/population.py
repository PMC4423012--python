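"""Population-level readouts: fate fractions, dose-response and washout scans.

These reproduce the study's in-silico population experiments: 50 independent
stochastic cells per condition, classified as autophagic / apoptotic / neither
at a fixed evaluation time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import THETA_APO, THETA_AUT, CellTrajectory, classify
from .params import ModelParameters
from .protocols import StressProtocol, constant_stress, washout
from .ssa import EnsembleResult, simulate_ensemble, spawn_seeds

#: calibrated cell-to-cell variability of the stressor strength used by the
#: dose-response scan (lognormal sigma on S0); the washout experiment's
#: commitment spread is intrinsic and uses no extrinsic factor
DEFAULT_DOSE_EXTRINSIC_SIGMA = 0.2

__all__ = [
    "FateCurve",
    "DEFAULT_DOSE_EXTRINSIC_SIGMA",
    "fate_fractions",
    "dose_response_scan",
    "activation_time_distribution",
    "washout_commitment_curve",
    "ensemble_mean",
]


@dataclass(frozen=True)
class FateCurve:
    """Fate fractions as a function of a swept variable (S0 or washout time)."""

    sweep_name: str
    values: np.ndarray
    frac_autophagic: np.ndarray
    frac_apoptotic: np.ndarray
    frac_neither: np.ndarray
    n_cells: int
    master_seed: int
    t_eval: np.ndarray  # evaluation time per grid point (min)
    params: ModelParameters

    def __post_init__(self) -> None:
        s = self.frac_autophagic + self.frac_apoptotic + self.frac_neither
        if not np.allclose(s, 1.0):
            raise ValueError("fate fractions must sum to 1 at every grid point")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep_value": self.values,
                "frac_autophagic": self.frac_autophagic,
                "frac_apoptotic": self.frac_apoptotic,
                "frac_neither": self.frac_neither,
                "n_cells": self.n_cells,
                "seed": self.master_seed,
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the curve as CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "sweep_name": self.sweep_name,
                "n_cells": self.n_cells,
                "master_seed": self.master_seed,
                "t_eval": self.t_eval.tolist(),
                "params": self.params.to_dict(),
                "params_sha256": params_hash(self.params),
            }
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def params_hash(params: ModelParameters) -> str:
    """Stable hash of a parameter set, for provenance records."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def fate_fractions(
    ensemble: EnsembleResult,
    t_eval: float | None = None,
    theta_aut: float = THETA_AUT,
    theta_apo: float = THETA_APO,
) -> tuple[float, float, float]:
    """(autophagic, apoptotic, neither) fractions at ``t_eval``.

    Each cell is classified by its state at the output grid point nearest to
    ``t_eval`` (default: end of the simulated horizon).
    """
    if t_eval is None:
        t_eval = float(ensemble.t[-1])
    if not ensemble.t[0] <= t_eval <= ensemble.t[-1] + 1e-9:
        raise ValueError(f"t_eval = {t_eval} outside the ensemble horizon")
    labels = [
        classify(tr.state_at(t_eval), ensemble.params, theta_aut, theta_apo)
        for tr in ensemble.trajectories
    ]
    n = len(labels)
    f_apo = sum(1 for x in labels if x == "apoptotic") / n
    f_aut = sum(1 for x in labels if x == "autophagic") / n
    return f_aut, f_apo, 1.0 - f_aut - f_apo


def dose_response_scan(
    params: ModelParameters,
    S_grid: Sequence[float] | None = None,
    n_cells: int = 50,
    t_end: float = 240.0,
    t_eval: float = 240.0,
    master_seed: int = 0,
    theta_aut: float = THETA_AUT,
    theta_apo: float = THETA_APO,
    extrinsic_sigma: float = DEFAULT_DOSE_EXTRINSIC_SIGMA,
) -> FateCurve:
    """Fate fractions over a stressor-level grid (default S0 = 1..10).

    One independent 50-cell ensemble per grid point, with per-point sub-seeds
    spawned from ``master_seed``.  ``extrinsic_sigma`` adds per-cell
    lognormal variability of the stressor strength (see simulate_ensemble).
    """
    if S_grid is None:
        S_grid = np.arange(1, 11)
    S_grid = np.asarray(S_grid, dtype=float)
    sub_seeds = spawn_seeds(master_seed, len(S_grid))
    f_aut = np.empty(len(S_grid))
    f_apo = np.empty(len(S_grid))
    for i, S0 in enumerate(S_grid):
        ens = simulate_ensemble(
            params,
            constant_stress(S0, t_end),
            n_cells=n_cells,
            master_seed=int(sub_seeds[i]),
            theta_aut=theta_aut,
            theta_apo=theta_apo,
            extrinsic_sigma=extrinsic_sigma,
        )
        f_aut[i], f_apo[i], _ = fate_fractions(ens, t_eval, theta_aut, theta_apo)
    return FateCurve(
        sweep_name="S0",
        values=S_grid,
        frac_autophagic=f_aut,
        frac_apoptotic=f_apo,
        frac_neither=1.0 - f_aut - f_apo,
        n_cells=n_cells,
        master_seed=int(master_seed),
        t_eval=np.full(len(S_grid), float(t_eval)),
        params=params,
    )


def activation_time_distribution(ensemble: EnsembleResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell first-crossing times of the apoptotic threshold.

    Returns ``(times_min, censored)``; cells that never cross within the
    horizon carry the horizon time with ``censored = True``.
    """
    return ensemble.activation_times()


def washout_commitment_curve(
    params: ModelParameters,
    S0: float = 10.0,
    washout_grid: Sequence[float] | None = None,
    t_post: float = 120.0,
    n_cells: int = 50,
    master_seed: int = 0,
    theta_aut: float = THETA_AUT,
    theta_apo: float = THETA_APO,
    extrinsic_sigma: float = 0.0,
) -> FateCurve:
    """Fate fractions vs washout time (stressor removed, evaluated t_post later).

    Defaults follow the in-silico washout experiment: S0 = 10, washout times
    15..105 min in 15-min steps, evaluation 120 min after each washout.
    """
    if washout_grid is None:
        washout_grid = np.arange(15.0, 106.0, 15.0)
    washout_grid = np.asarray(washout_grid, dtype=float)
    sub_seeds = spawn_seeds(master_seed, len(washout_grid))
    f_aut = np.empty(len(washout_grid))
    f_apo = np.empty(len(washout_grid))
    t_eval = washout_grid + t_post
    for i, tw in enumerate(washout_grid):
        ens = simulate_ensemble(
            params,
            washout(S0, tw, t_post),
            n_cells=n_cells,
            master_seed=int(sub_seeds[i]),
            theta_aut=theta_aut,
            theta_apo=theta_apo,
            extrinsic_sigma=extrinsic_sigma,
        )
        f_aut[i], f_apo[i], _ = fate_fractions(ens, t_eval[i], theta_aut, theta_apo)
    return FateCurve(
        sweep_name="t_washout",
        values=washout_grid,
        frac_autophagic=f_aut,
        frac_apoptotic=f_apo,
        frac_neither=1.0 - f_aut - f_apo,
        n_cells=n_cells,
        master_seed=int(master_seed),
        t_eval=t_eval,
        params=params,
    )


def ensemble_mean(ensemble: EnsembleResult) -> CellTrajectory:
    """Arithmetic mean trajectory over the cells of an ensemble."""
    return CellTrajectory(
        t=ensemble.t.copy(),
        y=ensemble.mean_y(),
        params=ensemble.params,
        protocol=ensemble.protocol,
        stochastic=True,
        seed=ensemble.master_seed,
    )
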