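"""Independent oracle for the packaged disease model.

A deliberately naive second transcription of the 24 update rules as
plain Python lambdas over a 1-based dict, with its own brute-force
iteration loop. It shares no code with the package's AST, compiler or
engine, so agreement between the two is a genuine cross-check of the
transcription and the synchronous semantics.
"""

from __future__ import annotations

maj = lambda *xs: 1 if 2 * sum(xs) >= len(xs) else 0
NOT = lambda x: 1 - x

PLAIN_RULES = {
    1: lambda s: NOT(s[22]) & NOT(s[13]),
    2: lambda s: NOT(s[1]),
    3: lambda s: s[2] & s[4],
    4: lambda s: NOT(s[24]) & (s[2] | s[18]),
    5: lambda s: s[21] | NOT(s[3]),
    6: lambda s: NOT(s[21]) & (NOT(s[5]) | s[3] | s[8]),
    7: lambda s: NOT(s[23]) & (NOT(s[5]) | s[15] | NOT(s[9])),
    8: lambda s: NOT(s[21]) & (s[6] & s[18]),
    9: lambda s: NOT(s[7]) | s[10] | s[21],
    10: lambda s: NOT(s[7]) | s[20],
    11: lambda s: s[7],
    12: lambda s: maj(s[4], NOT(s[9]), s[14]),
    13: lambda s: s[11] & s[12],
    14: lambda s: s[8] | s[4],
    15: lambda s: s[14],
    16: lambda s: s[17],
    17: lambda s: maj(s[4], s[7], s[15]),
    18: lambda s: s[13],
    19: lambda s: s[16],
    **{i: (lambda s, i=i: s[i]) for i in range(20, 25)},
}


def plain_step(state: tuple[int, ...]) -> tuple[int, ...]:
    s = {i + 1: b for i, b in enumerate(state)}
    return tuple(PLAIN_RULES[i](s) for i in range(1, 25))


def plain_fixed_point(initial: tuple[int, ...], limit: int = 200) -> tuple[int, ...]:
    """Iterate until the state repeats once; fail loudly on a cycle."""
    state = tuple(initial)
    for _ in range(limit):
        nxt = plain_step(state)
        if nxt == state:
            return state
        state = nxt
    raise AssertionError("oracle iteration did not reach a fixed point")
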