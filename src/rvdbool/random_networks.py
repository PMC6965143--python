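"""Seeded random Boolean networks for property testing.

Each variable receives a random expression tree over at most
``max_inputs`` distinct variables, drawn over all operator kinds
(NOT/AND/OR/MAJ plus bare references). Generation is fully determined by
the seed, so failures reproduce.
"""

from __future__ import annotations

import random

from .expressions import And, BooleanExpression, Majority, Not, Or, Var
from .network import BooleanNetwork, VariableSpec

__all__ = ["generate_random_network", "random_expression"]


def random_expression(
    rng: random.Random, candidates: list[int], budget: int = 4
) -> BooleanExpression:
    """A random expression reading only indices in ``candidates``."""
    if budget <= 1 or rng.random() < 0.3:
        leaf: BooleanExpression = Var(rng.choice(candidates))
        return Not(leaf) if rng.random() < 0.3 else leaf
    kind = rng.choice(["and", "or", "maj", "not"])
    if kind == "not":
        return Not(random_expression(rng, candidates, budget - 1))
    n_children = rng.randint(2, min(3, max(2, budget)))
    children = [
        random_expression(rng, candidates, budget // n_children)
        for _ in range(n_children)
    ]
    if kind == "and":
        return And(*children)
    if kind == "or":
        return Or(*children)
    return Majority(*children)


def generate_random_network(
    n_vars: int, max_inputs: int, seed: int
) -> BooleanNetwork:
    """Generate a valid random network, deterministically from ``seed``."""
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if max_inputs < 1:
        raise ValueError("max_inputs must be >= 1")
    rng = random.Random(seed)
    variables = [
        VariableSpec(index=i, name=f"v{i}", group="random")
        for i in range(1, n_vars + 1)
    ]
    rules: dict[int, BooleanExpression] = {}
    for i in range(1, n_vars + 1):
        k = rng.randint(1, min(max_inputs, n_vars))
        candidates = rng.sample(range(1, n_vars + 1), k)
        rules[i] = random_expression(rng, candidates)
    net = BooleanNetwork(variables, rules, name=f"random_n{n_vars}_s{seed}")
    return net.require_valid()
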