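"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from vrgaze.simulate import CohortSpec, make_scene, simulate_cohort


@pytest.fixture(scope="session")
def scene():
    return make_scene(seed=5)


@pytest.fixture(scope="session")
def small_cohort(scene):
    """Ledger-only cohort: 4+4 participants, 3 scenarios of 30 s."""
    spec = CohortSpec(
        n_per_group={"ADHD": 4, "control": 4},
        n_scenarios=3,
        scenario_duration_s=30.0,
        instruction_duration_s=4.0,
        seed=42,
    )
    return simulate_cohort(spec, scene=scene, render=False)


@pytest.fixture(scope="session")
def mini_rendered(scene):
    """Rendered cohort: 2+2 participants, 2 scenarios of 30 s, 0.1 deg noise."""
    spec = CohortSpec(
        n_per_group={"ADHD": 2, "control": 2},
        n_scenarios=2,
        scenario_duration_s=30.0,
        instruction_duration_s=5.0,
        seed=9,
    )
    return simulate_cohort(spec, scene=scene, render=True, noise_sd_deg=0.1)
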