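"""Define a small Boolean network in the rule DSL and find its attractor.

Shows the text dialect (!, &, |, MAJ), a scheduled perturbation, and
cycle detection on a toy oscillator.
"""

from rvdbool import (
    PerturbationEvent,
    ScenarioConfig,
    parse_rules,
    simulate,
    write_rules,
)

RULES = """\
#% network: toy_oscillator
targets, factors
#@ Drive role=intervention
A, !B & Drive
B, A
C, MAJ(A, B, C)
Drive, Drive
"""

network = parse_rules(RULES)
print("canonical form:")
print(write_rules(network))

# drive on: A/B chase each other in a 4-cycle
scenario = ScenarioConfig(name="driven", initial=(1, 0, 0, 1))
trajectory = simulate(network, scenario)
print(f"driven run: {trajectory.classification}, period={trajectory.period}")

# switching the drive off at t=6 collapses the oscillation
quenched = ScenarioConfig(
    name="quenched",
    initial=(1, 0, 0, 1),
    events=(PerturbationEvent(timepoint=6, variable=4, value=0),),
)
trajectory = simulate(network, quenched)
print(
    f"quenched run: {trajectory.classification} at "
    f"{[n for n, b in zip(network.names, trajectory.final_state) if b] or 'all-off'}"
)

# MAJ(A, B, C) keeps C latched once two of the three are on — the same
# rounded-mean threshold the disease model uses for vasoconstriction.
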