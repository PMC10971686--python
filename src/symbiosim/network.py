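"""Per-cell Boolean gene regulatory network.

Each tumour cell carries a copy of a Boolean network whose input nodes are
driven by the local microenvironment (nutrient concentrations compared
against activation thresholds) and by drug exposure (inhibitor-input nodes).
Internal and output nodes are updated *asynchronously*: on every sweep each
free node is recomputed once, in a random order, against the immediately
visible state.  Gene knockout / enrichment is modelled by forcing a node to
0 / 1 for the duration of a simulation.

The plain-text rule format is one declaration per line (``;`` also separates
statements, ``#`` starts a comment)::

    input Oxygen_supply @ oxygen >= 1.5   # bound to a substance + threshold
    input DNA_damage                       # unbound input, set externally
    inhibitor GLUT1I                       # drug-driven input node
    HIF1 := NOT Oxygen_supply              # internal node rule
    Proliferation := glycoATP OR mitoATP   # fate nodes recognised by name

Rules use ``AND``, ``OR``, ``NOT`` and parentheses.  Node names must be
valid identifiers and may not collide with the three keywords.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "NodeKind",
    "FixedState",
    "NodeSpec",
    "NetworkDefinition",
    "NetworkState",
    "Perturbation",
    "Phenotype",
    "NetworkDefinitionError",
    "load_network",
    "parse_network",
    "default_network_path",
    "set_inputs",
    "update_async",
    "read_fate",
]

FATE_NODE_NAMES = ("Proliferation", "Apoptosis", "Growth_Arrest", "Necrosis")
METABOLIC_NODE_NAMES = ("glycoATP", "mitoATP")

_KEYWORDS = {"AND", "OR", "NOT"}
_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<lpar>\()|(?P<rpar>\)))")


class NetworkDefinitionError(ValueError):
    """Raised for malformed network files or rule expressions."""


class NodeKind(enum.Enum):
    INPUT = "input"
    INHIBITOR_INPUT = "inhibitor-input"
    INTERNAL = "internal"
    OUTPUT = "output"


class FixedState(enum.Enum):
    FREE = "free"
    FORCED_0 = "forced_0"
    FORCED_1 = "forced_1"


class Phenotype(enum.Enum):
    """Cell fate decided by the network (Necrotic is set by the automaton)."""

    PROLIFERATION = "Proliferation"
    APOPTOSIS = "Apoptosis"
    GROWTH_ARREST = "Growth_Arrest"
    NECROTIC = "Necrotic"


@dataclass(frozen=True)
class Perturbation:
    """Knockout (forced 0) or enrichment (forced 1) of one node."""

    node: str
    mode: str  # "knockout" | "enrichment"

    def __post_init__(self) -> None:
        if self.mode not in ("knockout", "enrichment"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")

    @property
    def forced_value(self) -> int:
        return 0 if self.mode == "knockout" else 1


# ---------------------------------------------------------------------------
# Rule expressions


class _Expr:
    def evaluate(self, values: Mapping[str, int]) -> int:  # pragma: no cover
        raise NotImplementedError

    def names(self) -> set[str]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class _Var(_Expr):
    name: str

    def evaluate(self, values):
        return values[self.name]

    def names(self):
        return {self.name}


@dataclass(frozen=True)
class _Not(_Expr):
    arg: _Expr

    def evaluate(self, values):
        return 0 if self.arg.evaluate(values) else 1

    def names(self):
        return self.arg.names()


@dataclass(frozen=True)
class _And(_Expr):
    left: _Expr
    right: _Expr

    def evaluate(self, values):
        return self.right.evaluate(values) if self.left.evaluate(values) else 0

    def names(self):
        return self.left.names() | self.right.names()


@dataclass(frozen=True)
class _Or(_Expr):
    left: _Expr
    right: _Expr

    def evaluate(self, values):
        return 1 if self.left.evaluate(values) else self.right.evaluate(values)

    def names(self):
        return self.left.names() | self.right.names()


def _tokenize(expr: str, where: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise NetworkDefinitionError(
                f"{where}: unexpected character {expr[pos:].strip()[0]!r} in rule {expr!r}"
            )
        tokens.append(m.group("name") or m.group("lpar") or m.group("rpar"))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser, precedence NOT > AND > OR."""

    def __init__(self, tokens: list[str], where: str):
        self.tokens = tokens
        self.pos = 0
        self.where = where

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkDefinitionError(f"{self.where}: unexpected end of rule")
        self.pos += 1
        return tok

    def parse(self) -> _Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise NetworkDefinitionError(
                f"{self.where}: trailing token {self.peek()!r} in rule"
            )
        return expr

    def parse_or(self) -> _Expr:
        left = self.parse_and()
        while self.peek() == "OR":
            self.take()
            left = _Or(left, self.parse_and())
        return left

    def parse_and(self) -> _Expr:
        left = self.parse_not()
        while self.peek() == "AND":
            self.take()
            left = _And(left, self.parse_not())
        return left

    def parse_not(self) -> _Expr:
        if self.peek() == "NOT":
            self.take()
            return _Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> _Expr:
        tok = self.take()
        if tok == "(":
            expr = self.parse_or()
            if self.take() != ")":
                raise NetworkDefinitionError(f"{self.where}: unbalanced parentheses")
            return expr
        if tok in _KEYWORDS or tok in (")",):
            raise NetworkDefinitionError(f"{self.where}: misplaced token {tok!r}")
        return _Var(tok)


def parse_rule(expr: str, where: str = "<rule>") -> _Expr:
    tokens = _tokenize(expr, where)
    if not tokens:
        raise NetworkDefinitionError(f"{where}: empty rule")
    return _Parser(tokens, where).parse()


# ---------------------------------------------------------------------------
# Definition


@dataclass(frozen=True)
class InputBinding:
    substance: str
    threshold: float


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: NodeKind
    rule: _Expr | None = None
    fixed_state: FixedState = FixedState.FREE


@dataclass(frozen=True)
class NetworkDefinition:
    """Parsed Boolean network: ordered nodes, fate/metabolic read-outs and
    the substance bindings that drive the input layer."""

    nodes: tuple[NodeSpec, ...]
    input_bindings: Mapping[str, InputBinding] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        by_name = {}
        for spec in self.nodes:
            if spec.name in seen:
                raise NetworkDefinitionError(f"duplicate node {spec.name!r}")
            seen.add(spec.name)
            by_name[spec.name] = spec
        for spec in self.nodes:
            if spec.rule is not None:
                for ref in spec.rule.names():
                    if ref not in seen:
                        raise NetworkDefinitionError(
                            f"rule for {spec.name!r} references undeclared node {ref!r}"
                        )
            elif spec.kind in (NodeKind.INTERNAL, NodeKind.OUTPUT):
                raise NetworkDefinitionError(f"node {spec.name!r} has no rule")
        for name in self.input_bindings:
            if name not in seen:
                raise NetworkDefinitionError(f"binding for undeclared input {name!r}")
        object.__setattr__(self, "_by_name", by_name)

    # -- look-ups ----------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def node(self, name: str) -> NodeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise NetworkDefinitionError(f"unknown node {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.nodes)

    @property
    def output_names(self) -> tuple[str, ...]:
        return tuple(n for n in FATE_NODE_NAMES if n in self._by_name)

    @property
    def metabolic_names(self) -> tuple[str, ...]:
        return tuple(n for n in METABOLIC_NODE_NAMES if n in self._by_name)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(
            s.name
            for s in self.nodes
            if s.kind in (NodeKind.INPUT, NodeKind.INHIBITOR_INPUT)
        )

    @property
    def inhibitor_input_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.nodes if s.kind is NodeKind.INHIBITOR_INPUT)

    def free_updatable_names(self, forced: Mapping[str, int] | None = None) -> tuple[str, ...]:
        forced = forced or {}
        out = []
        for s in self.nodes:
            if s.kind in (NodeKind.INPUT, NodeKind.INHIBITOR_INPUT):
                continue
            if s.fixed_state is not FixedState.FREE or s.name in forced:
                continue
            out.append(s.name)
        return tuple(out)

    def require_fate_nodes(self) -> None:
        """Scenario-level contract: the four fate and two metabolic nodes exist."""
        missing = [n for n in FATE_NODE_NAMES + METABOLIC_NODE_NAMES if n not in self._by_name]
        if missing:
            raise NetworkDefinitionError(f"network lacks required nodes: {missing}")

    def with_perturbations(self, perturbations: Iterable[Perturbation]) -> "NetworkDefinition":
        """Return a copy with nodes forced per the perturbation list."""
        forced = {}
        for p in perturbations:
            if p.node not in self._by_name:
                raise NetworkDefinitionError(f"perturbation of unknown node {p.node!r}")
            forced[p.node] = FixedState.FORCED_0 if p.mode == "knockout" else FixedState.FORCED_1
        nodes = tuple(
            replace(s, fixed_state=forced.get(s.name, s.fixed_state)) for s in self.nodes
        )
        return NetworkDefinition(nodes, self.input_bindings)

    def forced_values(self) -> dict[str, int]:
        out = {}
        for s in self.nodes:
            if s.fixed_state is FixedState.FORCED_0:
                out[s.name] = 0
            elif s.fixed_state is FixedState.FORCED_1:
                out[s.name] = 1
        return out


# ---------------------------------------------------------------------------
# State


@dataclass
class NetworkState:
    """Binary value per declared node; forced nodes pinned at every access."""

    values: dict[str, int]

    @classmethod
    def initial(cls, defn: NetworkDefinition) -> "NetworkState":
        values = {name: 0 for name in defn.names}
        values.update(defn.forced_values())
        return cls(values)

    def copy(self) -> "NetworkState":
        return NetworkState(dict(self.values))

    def __getitem__(self, name: str) -> int:
        return self.values[name]

    def __setitem__(self, name: str, value: int) -> None:
        if name not in self.values:
            raise KeyError(name)
        self.values[name] = 1 if value else 0


# ---------------------------------------------------------------------------
# Parsing network files

_INPUT_RE = re.compile(
    r"^(?P<kw>input|inhibitor)\s+(?P<name>\S+)\s*(?:@\s*(?P<substance>\S+)\s*>=\s*(?P<thr>\S+))?$"
)


def _check_name(name: str, where: str) -> str:
    if not _NAME_RE.fullmatch(name) or name in _KEYWORDS:
        raise NetworkDefinitionError(f"{where}: invalid node name {name!r}")
    return name


def parse_network(text: str, source: str = "<string>") -> NetworkDefinition:
    nodes: list[NodeSpec] = []
    bindings: dict[str, InputBinding] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for stmt in filter(None, (s.strip() for s in line.split(";"))):
            where = f"{source}:{lineno}"
            m = _INPUT_RE.match(stmt)
            if m:
                name = _check_name(m.group("name"), where)
                kind = NodeKind.INPUT if m.group("kw") == "input" else NodeKind.INHIBITOR_INPUT
                if m.group("substance"):
                    try:
                        thr = float(m.group("thr"))
                    except ValueError:
                        raise NetworkDefinitionError(
                            f"{where}: bad threshold {m.group('thr')!r}"
                        ) from None
                    bindings[name] = InputBinding(m.group("substance"), thr)
                nodes.append(NodeSpec(name, kind))
                continue
            if ":=" in stmt:
                name, expr = (part.strip() for part in stmt.split(":=", 1))
                _check_name(name, where)
                rule = parse_rule(expr, where)
                kind = NodeKind.OUTPUT if name in FATE_NODE_NAMES else NodeKind.INTERNAL
                nodes.append(NodeSpec(name, kind, rule=rule))
                continue
            raise NetworkDefinitionError(f"{source}:{lineno}: cannot parse {stmt!r}")
    return NetworkDefinition(tuple(nodes), bindings)


def load_network(path) -> NetworkDefinition:
    """Parse a plain-text network definition file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_network(fh.read(), source=str(path))


def default_network_path():
    """Path of the curated default regulatory network shipped with the package."""
    return resources.files("symbiosim.data") / "default_network.net"


def load_default_network() -> NetworkDefinition:
    return parse_network(default_network_path().read_text(), source="default_network.net")


# ---------------------------------------------------------------------------
# Dynamics


def set_inputs(
    state: NetworkState,
    defn: NetworkDefinition,
    local: Mapping[str, float],
    forced: Mapping[str, int] | None = None,
) -> NetworkState:
    """Drive bound input nodes from local substance concentrations.

    An input is active iff its substance concentration is >= its activation
    threshold (inclusive, so the boundary case is deterministic).  Unbound
    inputs and inhibitor inputs are left untouched; forced nodes keep their
    forced value.
    """
    forced_all = defn.forced_values()
    if forced:
        forced_all.update(forced)
    for name, binding in defn.input_bindings.items():
        if name in forced_all:
            state.values[name] = forced_all[name]
            continue
        try:
            conc = local[binding.substance]
        except KeyError:
            raise KeyError(
                f"input {name!r} is bound to substance {binding.substance!r} "
                "which is missing from the local concentrations"
            ) from None
        state.values[name] = 1 if conc >= binding.threshold else 0
    for name, val in forced_all.items():
        state.values[name] = val
    return state


def update_async(
    state: NetworkState,
    defn: NetworkDefinition,
    n_sweeps: int = 1,
    rng: np.random.Generator | None = None,
    forced: Mapping[str, int] | None = None,
    trace: list | None = None,
) -> NetworkState:
    """Asynchronous update: ``n_sweeps`` passes, each visiting every free
    internal/output node once in an rng-drawn random order, recomputing its
    rule against the immediately visible state.

    The smallest asynchronous time step is a single node update; passing a
    ``trace`` list collects a snapshot of the state after every individual
    node update (used for reachability analyses).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    free = list(defn.free_updatable_names(forced))
    values = state.values
    rules = {name: defn.node(name).rule for name in free}
    for _ in range(n_sweeps):
        order = rng.permutation(len(free))
        for idx in order:
            name = free[idx]
            values[name] = rules[name].evaluate(values)
            if trace is not None:
                trace.append(dict(values))
    return state


def read_fate(state: NetworkState, defn: NetworkDefinition) -> Phenotype:
    """Active fate with precedence Apoptosis > Proliferation > Growth_Arrest;
    Growth_Arrest when no fate node is active."""
    v = state.values
    if v.get("Apoptosis", 0):
        return Phenotype.APOPTOSIS
    if v.get("Proliferation", 0):
        return Phenotype.PROLIFERATION
    return Phenotype.GROWTH_ARREST
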