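"""Boolean rule expressions.

The update function of every network variable is a small expression tree
over five node kinds:

* :class:`Var` — reads the current value of a variable (1-based index),
* :class:`Not` — logical negation (a repressor input),
* :class:`And` / :class:`Or` — n-ary conjunction / disjunction (n >= 2),
* :class:`Majority` — the rounded-mean threshold: the node is 1 iff the
  mean of its children's values is >= 1/2 (round-half-up).

With three binary inputs the mean lies in {0, 1/3, 2/3, 1}, so a
three-child :class:`Majority` is exactly the 2-of-3 majority vote; the
half-up convention only matters for even child counts, which the packaged
disease model never produces but user models may.

Expressions are immutable values; evaluation is pure and never mutates
the state vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence, Union

__all__ = [
    "BooleanExpression",
    "Var",
    "Not",
    "And",
    "Or",
    "Majority",
    "UnknownVariableError",
    "evaluate",
    "free_variables",
    "signed_variables",
    "walk",
]


class UnknownVariableError(KeyError):
    """A variable reference points outside the state vector / network."""

    def __init__(self, index: int, n: int | None = None):
        self.index = index
        if n is None:
            msg = f"unknown variable index {index}"
        else:
            msg = f"unknown variable index {index} (state has {n} variables)"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


@dataclass(frozen=True)
class Var:
    """Reference to a network variable by its 1-based index."""

    index: int

    def __post_init__(self) -> None:
        if not isinstance(self.index, int) or self.index < 1:
            raise ValueError(f"variable index must be a positive integer, got {self.index!r}")


@dataclass(frozen=True)
class Not:
    child: "BooleanExpression"


@dataclass(frozen=True)
class And:
    children: tuple["BooleanExpression", ...]

    def __init__(self, *children: "BooleanExpression"):
        object.__setattr__(self, "children", _as_children(children))
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple["BooleanExpression", ...]

    def __init__(self, *children: "BooleanExpression"):
        object.__setattr__(self, "children", _as_children(children))
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")


@dataclass(frozen=True)
class Majority:
    """Round-half-up mean threshold over the children (>= 1/2 -> 1)."""

    children: tuple["BooleanExpression", ...]

    def __init__(self, *children: "BooleanExpression"):
        object.__setattr__(self, "children", _as_children(children))
        if len(self.children) < 1:
            raise ValueError("MAJORITY requires at least 1 child")


BooleanExpression = Union[Var, Not, And, Or, Majority]


def _as_children(children) -> tuple:
    # allow And(a, b) and And(*[a, b]) alike; a single iterable argument
    # is unpacked so fixtures can pass lists
    if len(children) == 1 and isinstance(children[0], (list, tuple)):
        children = tuple(children[0])
    return tuple(children)


def evaluate(expr: BooleanExpression, state: Sequence[int]) -> int:
    """Evaluate ``expr`` against an ordered 0/1 state vector.

    ``state[i-1]`` holds the value of variable ``i``. Returns 0 or 1.

    Raises
    ------
    UnknownVariableError
        If a :class:`Var` index falls outside the state vector.
    """
    if isinstance(expr, Var):
        if expr.index > len(state):
            raise UnknownVariableError(expr.index, len(state))
        return 1 if state[expr.index - 1] else 0
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        for c in expr.children:
            if not evaluate(c, state):
                return 0
        return 1
    if isinstance(expr, Or):
        for c in expr.children:
            if evaluate(c, state):
                return 1
        return 0
    if isinstance(expr, Majority):
        total = sum(evaluate(c, state) for c in expr.children)
        # round-half-up on the mean: total/n >= 1/2
        return 1 if 2 * total >= len(expr.children) else 0
    raise TypeError(f"not a BooleanExpression: {expr!r}")


def walk(expr: BooleanExpression) -> Iterator[BooleanExpression]:
    """Yield every node of the tree, parents before children."""
    yield expr
    if isinstance(expr, Not):
        yield from walk(expr.child)
    elif isinstance(expr, (And, Or, Majority)):
        for c in expr.children:
            yield from walk(c)


def free_variables(expr: BooleanExpression) -> set[int]:
    """The set of variable indices referenced anywhere in ``expr``."""
    return {node.index for node in walk(expr) if isinstance(node, Var)}


def signed_variables(expr: BooleanExpression) -> dict[int, set[int]]:
    """Map each referenced index to its occurrence polarities.

    +1 marks an occurrence under an even number of negations (activating),
    -1 an occurrence under an odd number (inhibiting). An index may carry
    both when it appears with mixed polarity.
    """
    out: dict[int, set[int]] = {}

    def visit(node: BooleanExpression, parity: int) -> None:
        if isinstance(node, Var):
            out.setdefault(node.index, set()).add(parity)
        elif isinstance(node, Not):
            visit(node.child, -parity)
        else:
            for c in node.children:
                visit(c, parity)

    visit(expr, +1)
    return out
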