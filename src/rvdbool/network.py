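"""Validated Boolean networks: ordered variables, one update rule each.

A :class:`BooleanNetwork` is a closed synchronous system — every input a
rule reads must itself be a declared variable. External interventions
(therapies) are modelled as ordinary variables with identity self-rules,
so that a value written into them persists on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Sequence

from .expressions import (
    And,
    BooleanExpression,
    Majority,
    Not,
    Or,
    Var,
    free_variables,
    signed_variables,
)

__all__ = ["VariableSpec", "BooleanNetwork", "Edge", "Role"]

Role = Literal["biological", "intervention"]


@dataclass(frozen=True)
class VariableSpec:
    """One network node.

    Parameters
    ----------
    index : int
        1-based position in the state vector.
    name : str
        Unique machine name, no whitespace (e.g. ``"VEGF"``, ``"RAS"``).
    role : {"biological", "intervention"}
        Intervention variables represent external therapies and carry
        identity self-rules.
    group : str
        Process category (oxygenation/ischemia, oxidative stress, ...);
        free-form, used for display and export only.
    annotation : str
        Free-text description of the biology, not serialized to rule files.
    """

    index: int
    name: str
    role: Role = "biological"
    group: str = ""
    annotation: str = ""


@dataclass(frozen=True)
class Edge:
    """Signed dependency ``source -> target`` derived from the rules."""

    source: int
    target: int
    sign: Literal["activating", "inhibiting", "mixed"]


class BooleanNetwork:
    """Ordered variables plus exactly one Boolean update rule per variable."""

    def __init__(
        self,
        variables: Iterable[VariableSpec],
        rules: Mapping[int, BooleanExpression],
        name: str = "network",
    ):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        self.rules: dict[int, BooleanExpression] = dict(rules)
        self.name = name
        self._index_by_name = {v.name: v.index for v in self.variables}

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.name == other.name
            and self.variables == other.variables
            and self.rules == other.rules
        )

    def __repr__(self) -> str:
        return f"BooleanNetwork({self.name!r}, n={self.n})"

    def variable(self, key: int | str) -> VariableSpec:
        """Look up a variable by index or by name."""
        idx = self.index_of(key)
        return self.variables[idx - 1]

    def index_of(self, key: int | str) -> int:
        if isinstance(key, str):
            try:
                return self._index_by_name[key]
            except KeyError:
                raise KeyError(f"unknown variable name {key!r}") from None
        if not 1 <= key <= self.n:
            raise KeyError(f"unknown variable index {key}")
        return key

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Check all structural invariants; return violations (empty = valid).

        Violations are reported as data rather than raised, so a partially
        transcribed model can be inspected.
        """
        violations: list[str] = []
        seen_idx: set[int] = set()
        seen_names: set[str] = set()
        for v in self.variables:
            if v.index in seen_idx:
                violations.append(f"duplicate index {v.index}")
            seen_idx.add(v.index)
            if not v.name or any(c.isspace() for c in v.name):
                violations.append(f"invalid name {v.name!r} for variable {v.index}")
            if v.name in seen_names:
                violations.append(f"duplicate name {v.name!r}")
            seen_names.add(v.name)
        expected = set(range(1, self.n + 1))
        if seen_idx != expected:
            violations.append(
                f"indices are not contiguous 1..{self.n}: got {sorted(seen_idx)}"
            )
        for idx in sorted(expected):
            if idx not in self.rules:
                violations.append(f"missing rule for variable {idx}")
        for idx in sorted(self.rules):
            if idx not in expected:
                violations.append(f"rule for undeclared variable {idx}")
                continue
            dangling = free_variables(self.rules[idx]) - expected
            for d in sorted(dangling):
                violations.append(
                    f"dangling reference: rule for variable {idx} reads undeclared variable {d}"
                )
        return violations

    def require_valid(self) -> "BooleanNetwork":
        violations = self.validate()
        if violations:
            raise ValueError("invalid network: " + "; ".join(violations))
        return self

    # -- topology --------------------------------------------------------

    def topology(self) -> list[Edge]:
        """Signed dependency edges ``b -> a`` for every b free in rule F_a.

        The sign is *activating* when b only occurs un-negated in F_a,
        *inhibiting* when it only occurs negated, *mixed* otherwise.
        """
        self.require_valid()
        edges: list[Edge] = []
        for target in range(1, self.n + 1):
            for source, parities in sorted(signed_variables(self.rules[target]).items()):
                if parities == {+1}:
                    sign = "activating"
                elif parities == {-1}:
                    sign = "inhibiting"
                else:
                    sign = "mixed"
                edges.append(Edge(source=source, target=target, sign=sign))
        return edges

    def to_networkx(self):
        """Export the signed dependency graph as a ``networkx.DiGraph``.

        Nodes are variable names with ``index``/``role``/``group``
        attributes; edges carry a ``sign`` attribute.
        """
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        for v in self.variables:
            g.add_node(v.name, index=v.index, role=v.role, group=v.group)
        for e in self.topology():
            g.add_edge(
                self.variables[e.source - 1].name,
                self.variables[e.target - 1].name,
                sign=e.sign,
            )
        return g

    # -- evaluation helpers ----------------------------------------------

    def compiled_rules(self) -> list[Callable[[Sequence[int]], int]]:
        """Closure-compiled update functions, ordered by variable index.

        Semantically identical to :func:`rvdbool.expressions.evaluate`
        (asserted by the property-test suite); used by the simulation
        engine to keep long trajectories cheap.
        """
        return [_compile(self.rules[i]) for i in range(1, self.n + 1)]


def _compile(expr: BooleanExpression) -> Callable[[Sequence[int]], int]:
    if isinstance(expr, Var):
        i = expr.index - 1
        return lambda s: s[i]
    if isinstance(expr, Not):
        f = _compile(expr.child)
        return lambda s: 1 - f(s)
    if isinstance(expr, And):
        fs = [_compile(c) for c in expr.children]
        return lambda s: 1 if all(f(s) for f in fs) else 0
    if isinstance(expr, Or):
        fs = [_compile(c) for c in expr.children]
        return lambda s: 1 if any(f(s) for f in fs) else 0
    if isinstance(expr, Majority):
        fs = [_compile(c) for c in expr.children]
        k = len(fs)
        return lambda s: 1 if 2 * sum(f(s) for f in fs) >= k else 0
    raise TypeError(f"not a BooleanExpression: {expr!r}")
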