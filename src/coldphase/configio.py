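"""Plain-text key-value configuration for parameter sets and transitions.

The format is one ``key = value`` pair per line, ``#`` comments allowed.
Values are decimal numbers or simple arithmetic expressions over ``pi``
(e.g. ``3*pi/200``, ``-pi/150``) so the frequency constants can be
stored exactly as printed.
"""

from __future__ import annotations

import ast
import math
import operator
from pathlib import Path

from coldphase.model import LinearParameterSet, TanhParameterSet
from coldphase.temperature import TransitionSpec, WidthFit, make_transition

__all__ = [
    "parse_value",
    "read_config",
    "write_config",
    "load_parameter_set",
    "dump_parameter_set",
    "load_transition",
]

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}
_UNARYOPS = {ast.UAdd: operator.pos, ast.USub: operator.neg}


def _eval_node(node):
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.Name) and node.id == "pi":
        return math.pi
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](_eval_node(node.left), _eval_node(node.right))
    if isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
        return _UNARYOPS[type(node.op)](_eval_node(node.operand))
    raise ValueError(f"unsupported expression element: {ast.dump(node)}")


def parse_value(text: str) -> float:
    """Parse a decimal number or a +-*/ expression over ``pi``."""
    try:
        return _eval_node(ast.parse(text.strip(), mode="eval").body)
    except (SyntaxError, ValueError) as exc:
        raise ValueError(f"cannot parse config value {text!r}") from exc


def read_config(path) -> dict:
    """Read a ``key = value`` file into a dict of floats."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = parse_value(value)
    return out


def write_config(path, items: dict, header: str | None = None) -> None:
    """Write a dict as a ``key = value`` file (floats with full precision)."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for key, value in items.items():
        lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


_TANH_KEYS = ("b0", "b1", "A0", "A1", "Omega0", "Omega1", "C", "Tbar")
_LINEAR_KEYS = ("b0", "b1", "A0", "A1", "Omega0", "Omega1")


def load_parameter_set(path):
    """Load a parameter set; the presence of ``C``/``Tbar`` selects tanh."""
    cfg = read_config(path)
    if "C" in cfg or "Tbar" in cfg:
        missing = [k for k in _TANH_KEYS if k not in cfg]
        if missing:
            raise ValueError(f"missing tanh parameter keys: {missing}")
        return TanhParameterSet(**{k: cfg[k] for k in _TANH_KEYS})
    missing = [k for k in _LINEAR_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"missing linear parameter keys: {missing}")
    return LinearParameterSet(**{k: cfg[k] for k in _LINEAR_KEYS})


def dump_parameter_set(path, pset, header: str | None = None) -> None:
    keys = _TANH_KEYS if isinstance(pset, TanhParameterSet) else _LINEAR_KEYS
    write_config(path, {k: getattr(pset, k) for k in keys}, header=header)


def load_transition(cfg: dict) -> TransitionSpec:
    """Build a transition from config keys ``Ti_eff``, ``Tf_eff`` (+ ``D``)."""
    for key in ("Ti_eff", "Tf_eff"):
        if key not in cfg:
            raise ValueError(f"missing transition key {key!r}")
    return make_transition(cfg["Ti_eff"], cfg["Tf_eff"], D=cfg.get("D"))


def load_width_fit(cfg: dict) -> WidthFit:
    return WidthFit(a0=cfg["a0"], alpha=cfg["alpha"])
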