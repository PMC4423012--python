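"""Model parameters for the autophagy-apoptosis crosstalk network.

The model lumps the ER stress response into three tiers: an ER stress sensor
(ERSS) driven by the stressor level S, a pro-survival autophagy inducer (AUT)
activated by the sensor, and a pro-death apoptosis inducer (APO) activated by
the sensor through a chain of ``n_steps`` sequential modifications.  The two
inducers inhibit each other (double-negative feedback), and the active
apoptosis inducer additionally suppresses its own deactivation (positive
feedback of strength ``k_fb``).

All concentrations are dimensionless fractions of the respective total pools
(``ERSS_T``, ``AUT_T``, ``APO_T``, default 1.0); time is measured in minutes;
first-order rate constants are in 1/min.  ``Omega`` is the system size used by
the stochastic engine to convert concentrations into molecule counts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParameters", "default_parameters"]

_RATE_FIELDS = (
    "ka_e", "ki_e",
    "kaau", "kaau_p", "J_aa", "J_ia", "kiau", "kiau_p",
    "kaap", "kiap", "kiap_p", "k_fb",
)
_TOTAL_FIELDS = ("ERSS_T", "AUT_T", "APO_T")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, pool totals and system size of the crosstalk model.

    The defaults are the package's calibrated parameter set: they place the
    deterministic apoptosis threshold inside the stress window 3 < S < 5 and
    reproduce the washout commitment window (see ``erfate.calibration``).
    The same values ship as ``erfate/data/default_params.yaml``.
    """

    # pool totals (dimensionless concentration units)
    ERSS_T: float = 1.0
    AUT_T: float = 1.0
    APO_T: float = 1.0
    # ER stress sensor: activation by stressor S, basal inactivation
    ka_e: float = 0.1222  # 1/(stress unit * min)
    ki_e: float = 1.79    # 1/min
    # autophagy inducer: zero-order ultrasensitive (de)activation
    kaau: float = 0.02    # 1/min, basal activation
    kaau_p: float = 0.65  # 1/min, ERSS-driven activation (the modulated term)
    J_aa: float = 0.05    # Michaelis constant of activation
    J_ia: float = 0.2194  # Michaelis constant of inactivation
    kiau: float = 0.0322  # 1/min, basal inactivation
    kiau_p: float = 1.8   # 1/(conc*min), inactivation by active APO
    # apoptosis inducer chain: n_steps distributive modifications
    kaap: float = 0.23    # 1/(conc*min), ERSS-driven per-step activation
    kiap: float = 0.02    # 1/min, basal per-step deactivation
    kiap_p: float = 0.1983  # 1/(conc*min), deactivation by active AUT
    k_fb: float = 350.0   # dimensionless positive-feedback strength
    n_steps: int = 2
    # stochastic engine system size (molecules per concentration unit)
    Omega: int = 100

    def __post_init__(self) -> None:
        for name in _TOTAL_FIELDS:
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v!r}")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError(f"n_steps must be an integer >= 1, got {self.n_steps!r}")
        object.__setattr__(self, "n_steps", int(self.n_steps))
        if self.n_steps < 2:
            warnings.warn(
                "n_steps < 2 removes the multistep source of ultrasensitivity; "
                "the apoptosis response is graded in this regime.",
                stacklevel=3,
            )
        if int(self.Omega) != self.Omega or self.Omega <= 0:
            raise ValueError(f"Omega must be a positive integer, got {self.Omega!r}")
        object.__setattr__(self, "Omega", int(self.Omega))
        for name in _TOTAL_FIELDS:
            # molecule totals are round(Omega * total); warn if that rounds away
            # more than numerical dust so count-based conservation stays exact
            v = getattr(self, name) * self.Omega
            if abs(v - round(v)) > 1e-9:
                warnings.warn(
                    f"Omega*{name} = {v} is not an integer; the stochastic engine "
                    f"uses round({v}) = {round(v)} molecules.",
                    stacklevel=3,
                )

    # -- derived quantities -------------------------------------------------

    def pool_counts(self) -> tuple[int, int, int]:
        """Molecule totals (ERSS, AUT, APO) at system size Omega."""
        return (
            round(self.ERSS_T * self.Omega),
            round(self.AUT_T * self.Omega),
            round(self.APO_T * self.Omega),
        )

    # -- plumbing -----------------------------------------------------------

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load from a flat key-value YAML or JSON file (keys = field names)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path} does not contain a key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True))


def default_parameters() -> ModelParameters:
    """The calibrated default parameter set."""
    return ModelParameters()
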