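import pytest

from fieldtriage.simulate import ScenarioSpec, Segment, generate_scenario
from fieldtriage.survival import generate_case_grid, label_grid, train_survival_model
from fieldtriage.triage import ReferenceProfile


@pytest.fixture(scope="session")
def profile():
    return ReferenceProfile.default("s1")


@pytest.fixture(scope="session")
def default_grid():
    return generate_case_grid()


@pytest.fixture(scope="session")
def grid_labels(default_grid):
    return label_grid(default_grid, ReferenceProfile.default())


@pytest.fixture(scope="session")
def survival_model(default_grid, grid_labels):
    """The seeded two-stage model used across the suite."""
    return train_survival_model(default_grid, grid_labels, seed=42)


@pytest.fixture(scope="session")
def baseline_stream():
    """70 s of a healthy resting soldier (HR 72, RR 14, SBP 120, SpO2 97)."""
    spec = ScenarioSpec(
        soldier_id="s1", seed=7, segments=(Segment(duration_s=70.0),)
    )
    return generate_scenario(spec)


@pytest.fixture(scope="session")
def hemorrhage_stream():
    """2 min baseline then 3 min of progressive hemorrhage."""
    spec = ScenarioSpec(
        soldier_id="s2",
        seed=11,
        segments=(
            Segment(duration_s=120.0),
            Segment(duration_s=180.0, state="hemorrhage"),
        ),
    )
    return generate_scenario(spec)
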