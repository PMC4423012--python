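"""Configuration loading and result serialization helpers."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import ModelParameters
from .population import params_hash
from .protocols import StressProtocol

log = logging.getLogger("erfate")

__all__ = ["load_config", "resolve_parameters", "write_sidecar", "params_hash"]


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path} does not contain a key-value mapping")
    return dict(data)


def resolve_parameters(config: Mapping[str, Any]) -> ModelParameters:
    """Build ModelParameters from a config dict.

    Recognized keys: ``params_file`` (path to a flat key-value file),
    ``params`` (inline mapping of field overrides), or neither (calibrated
    defaults).  An XPPAUT model can be supplied via ``ode_file``; it must
    match the canonical parameter names.
    """
    if "ode_file" in config:
        from .xpp import import_ode_file

        params, report = import_ode_file(config["ode_file"])
        if params is None:
            raise ValueError(
                f"{config['ode_file']} does not match the canonical parameter set; "
                f"states found: {list(report.odes)}"
            )
        return params
    base = (
        ModelParameters.from_file(config["params_file"])
        if "params_file" in config
        else ModelParameters()
    )
    if "params" in config:
        base = base.replace(**dict(config["params"]))
    return base


def write_sidecar(path: str | Path, params: ModelParameters, seed: int, **extra: Any) -> None:
    """JSON provenance sidecar next to a result file."""
    from . import __version__

    meta = {
        "package": "erfate",
        "version": __version__,
        "master_seed": seed,
        "params": params.to_dict(),
        "params_sha256": params_hash(params),
        **extra,
    }
    p = Path(path)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(meta, indent=2))
    log.info("wrote %s (params %s, seed %d)", path, params_hash(params), seed)
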