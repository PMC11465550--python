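"""Symbolic state-space ODE models and time-course datasets.

Models are declared in the standard state-space form

    dx/dt = f(x(t), u(t), p),   y(t, p) = g(x(t), p),   x(t0) = x0,

with ``x`` the state vector (dimension n), ``p`` the unknown parameters,
``u`` known inputs (constants or piecewise-constant tables) and ``y`` the
measured outputs (dimension m).  All symbolic work is done with sympy;
expressions are parsed from infix strings (``^`` and ``**`` both accepted
for powers) and validated against the declared symbol roles.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import pandas as pd
import sympy as sp
import yaml
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

__all__ = [
    "OdeModel",
    "Dataset",
    "ModelError",
    "parse_model",
    "load_model",
    "serialize_model",
    "fix_parameters",
    "parameter_point",
    "TIME",
]

#: Reserved time symbol; autonomous systems need not mention it.
TIME = sp.Symbol("t", real=True)

# Functions allowed inside model expressions.  Kept deliberately small:
# every other bare name in an expression is treated as a (possibly
# undeclared) symbol rather than silently resolving to a sympy builtin.
_ALLOWED_FUNCS = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "Abs": sp.Abs,
    "Piecewise": sp.Piecewise,
    "Min": sp.Min,
    "Max": sp.Max,
    "pi": sp.pi,
    "E": sp.E,
}

_TRANSFORMATIONS = standard_transformations + (convert_xor,)


class ModelError(ValueError):
    """Raised for invalid model declarations (with the offending symbol)."""


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, real=True)


def parse_expression(text: str, declared: Mapping[str, sp.Symbol]) -> sp.Expr:
    """Parse an infix expression string against a set of declared symbols.

    Both ``^`` and ``**`` are accepted for powers.  Symbols not in
    ``declared`` still parse (validation reports them later with context).
    """
    global_dict = dict(_ALLOWED_FUNCS)
    # names parse_expr's auto-symbol transformation relies on
    global_dict.update(
        {"Symbol": _sym, "Integer": sp.Integer, "Float": sp.Float, "Rational": sp.Rational}
    )
    local = dict(declared)
    local.setdefault("t", TIME)
    try:
        expr = parse_expr(
            str(text),
            local_dict=local,
            global_dict=global_dict,
            transformations=_TRANSFORMATIONS,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises a zoo of error types here
        raise ModelError(f"unparsable expression {text!r}: {exc}") from exc
    if not isinstance(expr, (sp.Expr, sp.MatrixBase)):
        raise ModelError(f"expression {text!r} did not parse to a scalar")
    return expr


def to_exact(value) -> sp.Rational:
    """Exact rational representation of a decimal constant (2.5 -> 5/2)."""
    if isinstance(value, sp.Expr):
        return sp.nsimplify(value, rational=True)
    return sp.Rational(str(value))


@dataclass(frozen=True, eq=False)
class OdeModel:
    """A validated parametrised ODE model in state-space form.

    Attributes
    ----------
    states : ordered state symbols x (dimension n)
    params : ordered unknown parameter symbols p
    constants : known symbols -> numeric value (covers constant inputs)
    inputs : named piecewise-constant input tables, name -> (times, values)
    rhs : one expression per state (f)
    outputs : observable id -> expression (g); non-empty
    init : state -> numeric value, or a symbol for a declared-unknown IC
    units : optional per-symbol unit strings (metadata only, never checked)
    """

    name: str
    states: tuple
    params: tuple
    rhs: tuple
    outputs: Mapping[str, sp.Expr]
    init: Mapping[sp.Symbol, Union[float, sp.Symbol]]
    constants: Mapping[sp.Symbol, float] = field(default_factory=dict)
    inputs: Mapping[str, tuple] = field(default_factory=dict)
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._validate()

    # -- dimensions ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def output_names(self) -> tuple:
        return tuple(self.outputs)

    @property
    def unknown_init(self) -> tuple:
        """Symbols standing for declared-unknown initial conditions."""
        return tuple(
            v for v in self.init.values() if isinstance(v, sp.Symbol)
        )

    @property
    def unknowns(self) -> tuple:
        """All unknown quantities: parameters plus unknown ICs."""
        return tuple(self.params) + self.unknown_init

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        if len(self.rhs) != len(self.states):
            raise ModelError(
                f"{len(self.rhs)} ODE right-hand sides for {len(self.states)} states"
            )
        if not self.outputs:
            raise ModelError("model declares no outputs")
        roles: dict[sp.Symbol, str] = {}
        for role, syms in (
            ("state", self.states),
            ("parameter", self.params),
            ("constant", tuple(self.constants)),
        ):
            for s in syms:
                if s == TIME:
                    raise ModelError("symbol 't' is reserved for time")
                if s in roles:
                    raise ModelError(
                        f"symbol '{s}' declared both as {roles[s]} and {role}"
                    )
                roles[s] = role
        declared = set(roles) | {TIME}
        ic_syms = set(self.unknown_init)
        for x in self.states:
            if x not in self.init:
                raise ModelError(f"state '{x}' has no initial condition")
        for x, v in self.init.items():
            if x not in self.states:
                raise ModelError(f"initial condition for undeclared state '{x}'")
            if isinstance(v, sp.Symbol):
                if v in roles:
                    raise ModelError(
                        f"unknown-IC symbol '{v}' already declared as {roles[v]}"
                    )
            else:
                if not sp.Float(v).is_finite:
                    raise ModelError(f"non-finite initial condition for '{x}'")
        for label, expr in self._all_expressions():
            extra = expr.free_symbols - declared - ic_syms
            if extra:
                bad = ", ".join(sorted(str(s) for s in extra))
                raise ModelError(f"undeclared symbol(s) {bad} in {label}")

    def _all_expressions(self):
        for x, f in zip(self.states, self.rhs):
            yield f"d({x})/dt", f
        for name, g in self.outputs.items():
            yield f"output '{name}'", g

    # -- transforms ---------------------------------------------------
    def with_outputs(self, names: Sequence[str]) -> "OdeModel":
        """Restrict the observation set to the named outputs."""
        missing = [n for n in names if n not in self.outputs]
        if missing:
            raise ModelError(f"unknown output(s): {missing}")
        return OdeModel(
            name=self.name,
            states=self.states,
            params=self.params,
            rhs=self.rhs,
            outputs={n: self.outputs[n] for n in names},
            init=dict(self.init),
            constants=dict(self.constants),
            inputs=dict(self.inputs),
            units=dict(self.units),
        )

    def substituted_constants(self, exact: bool = True) -> dict:
        """Constant substitution map, exact rationals by default."""
        conv = to_exact if exact else float
        subs = {s: conv(v) for s, v in self.constants.items()}
        for iname, (times, values) in self.inputs.items():
            subs[sp.Symbol(iname, real=True)] = _piecewise_constant(times, values)
        return subs

    def config_hash(self) -> str:
        return hashlib.sha256(serialize_model(self).encode()).hexdigest()[:16]


def _piecewise_constant(times, values) -> sp.Expr:
    pieces = [(sp.Float(v), TIME < sp.Float(tv)) for tv, v in zip(times[1:], values[:-1])]
    pieces.append((sp.Float(values[-1]), True))
    return sp.Piecewise(*pieces)


# ---------------------------------------------------------------------------
# config parsing / serialization
# ---------------------------------------------------------------------------

def parse_model(config_text: str) -> OdeModel:
    """Parse a keyed-text (YAML) model config into a validated :class:`OdeModel`.

    Sections: ``states``, ``parameters``, ``constants``, ``odes``,
    ``outputs``, ``init``; optional ``name``, ``inputs``, ``units``.
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ModelError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ModelError("config must be a mapping of sections")
    for section in ("states", "parameters", "odes", "outputs", "init"):
        if section not in raw:
            raise ModelError(f"config missing required section '{section}'")

    state_names = [str(s) for s in raw["states"]]
    param_names = [str(s) for s in raw["parameters"]]
    constants_raw = raw.get("constants") or {}
    declared = {n: _sym(n) for n in state_names + param_names + list(map(str, constants_raw))}

    init_raw = raw["init"]
    init: dict = {}
    for sname in state_names:
        if sname not in init_raw:
            raise ModelError(f"state '{sname}' has no initial condition")
        v = init_raw[sname]
        if isinstance(v, str) and not _is_number(v):
            init[declared[sname]] = _sym(v)  # declared-unknown IC
        else:
            init[declared[sname]] = float(v)
    for v in init.values():
        if isinstance(v, sp.Symbol):
            declared.setdefault(str(v), v)

    odes_raw = raw["odes"]
    rhs = []
    for sname in state_names:
        if sname not in odes_raw:
            raise ModelError(f"no ODE given for state '{sname}'")
        rhs.append(parse_expression(odes_raw[sname], declared))

    outputs_raw = raw["outputs"]
    if isinstance(outputs_raw, Mapping):
        outputs = {str(k): parse_expression(v, declared) for k, v in outputs_raw.items()}
    else:  # plain list: each entry names a state / expression observed directly
        outputs = {str(v): parse_expression(v, declared) for v in outputs_raw}

    inputs_raw = raw.get("inputs") or {}
    inputs = {
        str(k): (list(map(float, v["times"])), list(map(float, v["values"])))
        for k, v in inputs_raw.items()
    }

    return OdeModel(
        name=str(raw.get("name", "model")),
        states=tuple(declared[n] for n in state_names),
        params=tuple(declared[n] for n in param_names),
        rhs=tuple(rhs),
        outputs=outputs,
        init=init,
        constants={declared[str(k)]: float(v) for k, v in constants_raw.items()},
        inputs=inputs,
        units={str(k): str(v) for k, v in (raw.get("units") or {}).items()},
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_model(path) -> OdeModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def serialize_model(model: OdeModel) -> str:
    """Serialize to the config dialect; round-trips through :func:`parse_model`."""
    doc = {
        "name": model.name,
        "states": [str(s) for s in model.states],
        "parameters": [str(p) for p in model.params],
        "constants": {str(k): float(v) for k, v in model.constants.items()},
        "odes": {str(x): sp.sstr(f) for x, f in zip(model.states, model.rhs)},
        "outputs": {k: sp.sstr(g) for k, g in model.outputs.items()},
        "init": {
            str(x): (str(v) if isinstance(v, sp.Symbol) else float(v))
            for x, v in model.init.items()
        },
    }
    if model.inputs:
        doc["inputs"] = {
            k: {"times": list(ts), "values": list(vs)}
            for k, (ts, vs) in model.inputs.items()
        }
    if model.units:
        doc["units"] = dict(model.units)
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# parameter points
# ---------------------------------------------------------------------------

def parameter_point(model: OdeModel, values: Mapping) -> dict:
    """Normalise a parameter mapping to {Symbol: float} covering all unknowns.

    Keys may be symbols or strings; must cover exactly the model's unknown
    parameters (and any declared-unknown initial conditions); all finite.
    """
    by_name = {str(s): s for s in model.unknowns}
    point: dict = {}
    for k, v in values.items():
        name = str(k)
        if name not in by_name:
            raise ModelError(f"'{name}' is not an unknown parameter of {model.name}")
        v = float(v)
        if not sp.Float(v).is_finite:
            raise ModelError(f"non-finite value for parameter '{name}'")
        point[by_name[name]] = v
    missing = [n for n in by_name if by_name[n] not in point]
    if missing:
        raise ModelError(f"missing value(s) for parameter(s): {missing}")
    return point


def fix_parameters(model: OdeModel, known: Mapping) -> OdeModel:
    """Move the given unknown parameters into the known constants.

    The returned model has those symbols in ``constants`` with the supplied
    numeric values; rhs and outputs are untouched.  An empty map returns an
    equivalent model.
    """
    by_name = {str(p): p for p in model.params}
    fixed: dict = {}
    for k, v in known.items():
        name = str(k)
        if name not in by_name:
            raise ModelError(f"'{name}' is not an unknown parameter of {model.name}")
        v = float(v)
        if not sp.Float(v).is_finite:
            raise ModelError(f"non-finite value for fixed parameter '{name}'")
        fixed[by_name[name]] = v
    constants = dict(model.constants)
    constants.update(fixed)
    return OdeModel(
        name=model.name,
        states=model.states,
        params=tuple(p for p in model.params if p not in fixed),
        rhs=model.rhs,
        outputs=dict(model.outputs),
        init=dict(model.init),
        constants=constants,
        inputs=dict(model.inputs),
        units=dict(model.units),
    )


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Time-course observations: records of (time, observable, value[, sigma])."""

    frame: pd.DataFrame

    REQUIRED = ("time", "observable", "value")

    def __post_init__(self):
        df = pd.DataFrame(self.frame)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ModelError(f"dataset missing column '{col}'")
        if "sigma" not in df.columns:
            df["sigma"] = pd.NA
        df = df[["time", "observable", "value", "sigma"]].copy()
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        df["sigma"] = pd.to_numeric(df["sigma"], errors="coerce")
        if not df["time"].apply(lambda v: v == v and abs(v) != float("inf")).all():
            raise ModelError("dataset contains non-finite times")
        bad_sigma = df["sigma"].notna() & (df["sigma"] <= 0)
        if bad_sigma.any():
            raise ModelError("dataset contains non-positive sigma values")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def observables(self) -> tuple:
        return tuple(pd.unique(self.frame["observable"]))

    @property
    def has_sigma(self) -> bool:
        return bool(self.frame["sigma"].notna().all())

    def validate_against(self, model: OdeModel) -> None:
        unknown = set(self.observables) - set(model.output_names)
        if unknown:
            raise ModelError(
                f"dataset observables {sorted(unknown)} not among model outputs "
                f"{list(model.output_names)}"
            )
        if len(self.frame) == 0:
            raise ModelError("dataset is empty")

    @classmethod
    def from_csv(cls, path_or_buffer) -> "Dataset":
        return cls(pd.read_csv(path_or_buffer))

    def to_csv(self, path=None):
        df = self.frame.copy()
        if df["sigma"].isna().all():
            df = df.drop(columns="sigma")
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)
        return None
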