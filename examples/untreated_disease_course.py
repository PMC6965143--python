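"""Simulate untreated renovascular disease to its steady state.

Builds the packaged 24-variable network, runs the untreated scenario
(stenosis on, kidney initially quiescent) and prints which processes the
disease locks on or off once the state stops changing.
"""

from rvdbool import build_rvd_model, build_scenario, simulate

network = build_rvd_model()
trajectory = simulate(network, build_scenario("untreated"))

print(f"terminal behaviour : {trajectory.classification}")
print(f"settled after      : {trajectory.transient_length} cycles")

active = [n for n, b in zip(network.names, trajectory.final_state) if b]
inactive = [n for n, b in zip(network.names, trajectory.final_state) if not b]
print(f"active at steady state   ({len(active):2d}): {', '.join(active)}")
print(f"inactive at steady state ({len(inactive):2d}): {', '.join(inactive)}")

# Every deleterious process (ischemia, oxidative stress, inflammation,
# rarefaction, fibrosis) ends up on; every protective one (blood flow,
# ROS scavenging, NO, VEGF) ends up off — the self-sustaining vicious
# cycle that makes untreated disease progressive.
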