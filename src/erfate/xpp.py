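"""XPPAUT ``.ode`` model import/export.

The reference implementation of this model family was distributed as XPPAUT
code, so the package can round-trip its canonical equations through the
``.ode`` dialect and import an external file either as a parameter override
(when the parameter names match the canonical model) or as a generic
right-hand side interpreted with sympy.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParameters

__all__ = ["OdeFile", "export_ode", "parse_ode_file", "import_ode_file"]

_CANONICAL_FIELDS = [f.name for f in dataclasses.fields(ModelParameters)]


@dataclass
class OdeFile:
    """Parsed content of an XPPAUT ``.ode`` file."""

    parameters: dict[str, float] = field(default_factory=dict)
    odes: dict[str, str] = field(default_factory=dict)  # variable -> RHS expression
    inits: dict[str, float] = field(default_factory=dict)
    aux: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    def rhs_function(self):
        """Compile the ODEs into ``f(t, y, **params) -> dy`` via sympy.

        State order follows the order of ODE declarations.  Any symbol that is
        neither a state variable nor a declared parameter is treated as an
        extra keyword argument (e.g. a stressor level ``S``).
        """
        import sympy

        states = list(self.odes)
        syms = {name: sympy.Symbol(name) for name in states}
        syms.update({k: sympy.Symbol(k) for k in self.parameters})
        exprs = [sympy.sympify(self.odes[v], locals=syms) for v in states]
        free = sorted(
            {s.name for e in exprs for s in e.free_symbols}
            - set(states)
            - set(self.parameters),
        )
        args = (
            [sympy.Symbol(v) for v in states]
            + [sympy.Symbol(k) for k in self.parameters]
            + [sympy.Symbol(k) for k in free]
        )
        f = sympy.lambdify(args, exprs, modules="numpy")
        pvals = list(self.parameters.values())

        def rhs(t, y, **extra):
            extras = [extra[k] for k in free]
            return np.asarray(f(*y, *pvals, *extras), dtype=float)

        rhs.state_names = states  # type: ignore[attr-defined]
        rhs.extra_names = free  # type: ignore[attr-defined]
        return rhs


def export_ode(params: ModelParameters, path: str | Path | None = None) -> str:
    """Write the canonical model as an XPPAUT ``.ode`` file; returns the text."""
    p = params
    lines = ["# autophagy-apoptosis crosstalk under ER stress (canonical form)"]
    for name in _CANONICAL_FIELDS:
        lines.append(f"par {name}={getattr(p, name)!r}")
    lines.append("par S=0.0")
    lines.append("dERSS/dt=ka_e*S*(ERSS_T-ERSS)-ki_e*ERSS")
    lines.append(
        "dAUT/dt=(kaau+kaau_p*ERSS)*(AUT_T-AUT)/(J_aa+AUT_T-AUT)"
        "-(kiau+kiau_p*APO_%d)*AUT/(J_ia+AUT)" % p.n_steps
    )
    chain = [f"APO_{i + 1}" for i in range(p.n_steps)]
    pool = "(APO_T-" + "-".join(chain) + ")"
    kb = f"(kiap/(1+k_fb*APO_{p.n_steps})+kiap_p*AUT)"
    for i, var in enumerate(chain):
        below = pool if i == 0 else chain[i - 1]
        terms = [f"kaap*ERSS*{below}", f"-{kb}*{var}"]
        if i < p.n_steps - 1:
            terms += [f"-kaap*ERSS*{var}", f"+{kb}*{chain[i + 1]}"]
        lines.append(f"d{var}/dt=" + "".join(terms))
    for v in ["ERSS", "AUT"] + chain:
        lines.append(f"init {v}=0.0")
    lines.append("done")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


_PAR_RE = re.compile(r"^(?:par|p)\s+(.*)$", re.IGNORECASE)
_INIT_RE = re.compile(r"^init\s+(.*)$", re.IGNORECASE)
_DDT_RE = re.compile(r"^d([A-Za-z_]\w*)/dt\s*=\s*(.*)$")
_PRIME_RE = re.compile(r"^([A-Za-z_]\w*)'\s*=\s*(.*)$")
_INIT2_RE = re.compile(r"^([A-Za-z_]\w*)\(0\)\s*=\s*(.*)$")
_AUX_RE = re.compile(r"^aux\s+([A-Za-z_]\w*)\s*=\s*(.*)$", re.IGNORECASE)


def parse_ode_file(path: str | Path) -> OdeFile:
    """Parse an XPPAUT ``.ode`` file (parameter, ODE, init and aux lines).

    Unrecognized non-comment constructs are collected in ``unmatched`` and
    reported as a warning, not an error; an empty model raises ValueError.
    """
    text = Path(path).read_text()
    out = OdeFile()
    for raw in text.splitlines():
        line = raw.split("#")[0].strip()
        if not line or line.lower() == "done":
            continue
        if m := _PAR_RE.match(line):
            for item in re.split(r"[,\s]+", m.group(1)):
                if "=" in item:
                    k, v = item.split("=", 1)
                    out.parameters[k.strip()] = float(v)
            continue
        if m := _INIT_RE.match(line):
            for item in re.split(r"[,\s]+", m.group(1)):
                if "=" in item:
                    k, v = item.split("=", 1)
                    out.inits[k.strip()] = float(v)
            continue
        if m := _DDT_RE.match(line) or _PRIME_RE.match(line):
            out.odes[m.group(1)] = m.group(2)
            continue
        if m := _INIT2_RE.match(line):
            out.inits[m.group(1)] = float(m.group(2))
            continue
        if m := _AUX_RE.match(line):
            out.aux[m.group(1)] = m.group(2)
            continue
        if line.startswith("@"):
            out.unmatched.append(line)  # numerics directives: irrelevant here
            continue
        out.unmatched.append(line)
    if out.unmatched:
        warnings.warn(
            f"{len(out.unmatched)} unrecognized construct(s) in {path}: "
            + "; ".join(out.unmatched[:5]),
            stacklevel=2,
        )
    if not out.parameters and not out.odes:
        raise ValueError(f"{path} contains no parameters or equations")
    return out


def import_ode_file(path: str | Path) -> tuple[ModelParameters | None, OdeFile]:
    """Import a model file: ``(parameters, parse report)``.

    When every canonical parameter name is present the file is interpreted as
    a parameter override of the canonical equations and a ``ModelParameters``
    is returned; otherwise the first element is None and the caller can use
    ``report.rhs_function()`` as a generic interpreted model.
    """
    report = parse_ode_file(path)
    lower = {k.lower(): v for k, v in report.parameters.items()}
    if all(name.lower() in lower for name in _CANONICAL_FIELDS):
        params = ModelParameters.from_dict(
            {name: lower[name.lower()] for name in _CANONICAL_FIELDS}
        )
        return params, report
    return None, report
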