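import pytest

from rvdbool import build_rvd_model, build_scenario, run_study, simulate

# hand-derived fixed points (independent pen-and-paper iteration of the
# update rules from each printed initial state), as sets of active indices
EXPECTED_FIXED_POINTS = {
    "untreated": {2, 3, 4, 6, 7, 8, 11, 12, 13, 14, 15, 16, 17, 18, 19, 22},
    "simvastatin": {2, 3, 4, 5, 7, 9, 11, 12, 13, 14, 15, 16, 17, 18, 19, 21, 22},
    "antioxidant": {2, 3, 4, 6, 9, 10, 12, 14, 15, 16, 17, 19, 22, 23},
    "eta_blockade": {2, 5, 9, 10, 22, 24},
    "preventive_vegf": {2, 3, 4, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 22},
    "interventional_vegf": {2, 3, 4, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 22},
    "angioplasty_vegf": {1, 5, 9, 10, 20},
}


def active_set(state) -> set[int]:
    return {i + 1 for i, b in enumerate(state) if b}


@pytest.fixture(scope="session")
def rvd_model():
    return build_rvd_model()


@pytest.fixture(scope="session")
def study():
    """All seven packaged scenarios simulated once, with diffs and scores."""
    return run_study()


@pytest.fixture(scope="session")
def untreated_trajectory(rvd_model):
    return simulate(rvd_model, build_scenario("untreated"))
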