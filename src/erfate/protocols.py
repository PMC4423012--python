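"""Stress protocols: piecewise-constant stressor level S(t) over minutes.

Three experiment classes are covered: constant treatment, washout (stressor
removed at a fixed time), and autophagy-strength modulation (a parameter
change standing in for pretreatment with an autophagy inhibitor/activator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .params import ModelParameters

__all__ = ["StressProtocol", "constant_stress", "washout", "modulate_autophagy"]


@dataclass(frozen=True)
class StressProtocol:
    """Piecewise-constant stressor level.

    ``segments`` is an ordered list of ``(start_time_min, level)`` pairs, the
    first starting at t = 0; each level holds until the next start time (the
    protocol is right-continuous: ``S(t)`` at a boundary is the new level).
    """

    segments: tuple[tuple[float, float], ...]
    t_end: float

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(s)) for t, s in self.segments)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "t_end", float(self.t_end))
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(s < 0 for _, s in segs):
            raise ValueError("stressor levels must be >= 0")
        if not self.t_end > starts[-1]:
            raise ValueError("t_end must exceed the last segment start")

    def level_at(self, t: float) -> float:
        """S(t), right-continuous."""
        level = self.segments[0][1]
        for start, s in self.segments:
            if t >= start:
                level = s
            else:
                break
        return level

    def boundaries(self) -> np.ndarray:
        """Segment edges including t_end: [t0, t1, ..., t_end]."""
        return np.array([t for t, _ in self.segments] + [self.t_end])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {"segments": [list(seg) for seg in self.segments], "t_end": self.t_end}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StressProtocol":
        return cls(tuple(tuple(seg) for seg in d["segments"]), d["t_end"])


def constant_stress(S0: float, t_end: float) -> StressProtocol:
    """Constant stressor level S0 over [0, t_end]."""
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    return StressProtocol(((0.0, float(S0)),), t_end)


def washout(S0: float, t_washout: float, t_post: float) -> StressProtocol:
    """Stressor at S0 until t_washout, then instantaneously removed.

    Models drug-removal experiments: S drops to 0 at ``t_washout`` and the
    cells are followed for another ``t_post`` minutes.
    """
    if not t_washout > 0:
        raise ValueError("t_washout must be > 0")
    if not t_post > 0:
        raise ValueError("t_post must be > 0")
    return StressProtocol(
        ((0.0, float(S0)), (float(t_washout), 0.0)), float(t_washout) + float(t_post)
    )


def modulate_autophagy(params: ModelParameters, kaau_p_new: float) -> ModelParameters:
    """Copy of ``params`` with the ERSS-driven autophagy activation rate replaced.

    ``kaau_p_new = 0.2`` emulates pretreatment with an autophagy inhibitor
    (3-methyladenine); ``0.7`` emulates an activator (metyrapone).  The
    modulation applies from t = 0, mirroring how the simulated pretreatment
    experiments were run.
    """
    if kaau_p_new < 0:
        raise ValueError("kaau_p_new must be >= 0")
    return params.replace(kaau_p=float(kaau_p_new))
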