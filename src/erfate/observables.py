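"""Synthetic experimental observables: blot-like marker time courses and an
Annexin-style apoptotic index.

Maps model trajectories onto the readouts used to follow autophagy and
apoptosis in cells — LC3II and p62 immunoblot densitometry for autophagic
activity, procaspase-3 and cleaved PARP for the apoptotic machinery, and a
counted apoptotic-index percentage — so analysis code can be exercised
against data with known ground truth.

Observation model (all constants configurable, defaults 1):

* LC3II ∝ active autophagy inducer (lipidated LC3 tracks autophagosome mass),
* p62 ∝ exp(-c * integral of AUT dt): p62 is consumed by autophagic flux, so
  its band decays with cumulative autophagic activity rather than tracking
  the instantaneous level,
* procaspase-3 ∝ (APO_T - APO_act): the zymogen pool depleted by activation,
* cleaved PARP ∝ APO_act,
* multiplicative lognormal noise with a configurable coefficient of
  variation emulates densitometry variability; a loading-control channel is
  reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import CellTrajectory
from .ssa import EnsembleResult
from .population import fate_fractions

__all__ = ["MarkerTimecourse", "markers_from_trajectory", "apoptotic_index"]


@dataclass(frozen=True)
class MarkerTimecourse:
    """Normalized band intensities over time (arbitrary densitometry units)."""

    t: np.ndarray
    LC3II: np.ndarray
    p62: np.ndarray
    procaspase3: np.ndarray
    cleavedPARP: np.ndarray
    loading_control: float
    seed: int | None

    def __post_init__(self) -> None:
        for name in ("LC3II", "p62", "procaspase3", "cleavedPARP"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} intensities must be >= 0")


def markers_from_trajectory(
    traj: CellTrajectory,
    noise_cv: float = 0.0,
    seed: int | None = None,
    a: float = 1.0,
    b: float = 1.0,
    c: float = 1.0,
    d: float = 1.0,
    e: float = 1.0,
    loading_control: float = 1.0,
) -> MarkerTimecourse:
    """Marker time courses for one trajectory (or an ensemble mean).

    ``noise_cv`` is the coefficient of variation of multiplicative lognormal
    noise applied independently per band and time point; 0 gives noise-free
    markers that are deterministic functions of the trajectory.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    p = traj.params
    aut_integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (traj.AUT[1:] + traj.AUT[:-1]) * np.diff(traj.t)))
    )
    # p62 decays with cumulative autophagic flux; time is rescaled so the
    # integral is comparable across horizons (per-hour units)
    markers = {
        "LC3II": a * traj.AUT,
        "p62": b * np.exp(-c * aut_integral / 60.0),
        "procaspase3": d * (p.APO_T - traj.APO_act),
        "cleavedPARP": e * traj.APO_act,
    }
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal with CV = noise_cv
        for k in markers:
            markers[k] = markers[k] * rng.lognormal(
                -0.5 * sigma**2, sigma, size=len(traj.t)
            )
    return MarkerTimecourse(
        t=traj.t.copy(),
        loading_control=loading_control,
        seed=seed,
        **markers,
    )


def apoptotic_index(
    ensemble: EnsembleResult,
    t_grid: Sequence[float],
    n_counted: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Percentage of cells scored apoptotic at each time, with counting noise.

    Emulates scoring ``n_counted`` stained cells per time point: the count is
    binomial around the ensemble's true apoptotic fraction.
    """
    if n_counted < 1:
        raise ValueError("n_counted must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        _, f_apo, _ = fate_fractions(ensemble, t_eval=float(t))
        out[i] = 100.0 * rng.binomial(n_counted, f_apo) / n_counted
    return out
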