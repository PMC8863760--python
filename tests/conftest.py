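import hypothesis
import pytest

from numstim import Arena, ConstraintSet, RadiusPolicy

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def circular_arena():
    return Arena(kind="circular", radius=100.0)


@pytest.fixture
def basic_cs(circular_arena):
    """A small, fully feasible constraint set used across modules."""
    return ConstraintSet(
        n=6,
        arena=circular_arena,
        spatial_target={"CH": 8000.0},
        magnitude_target={"TA": 500.0},
        radius_policy=RadiusPolicy(mode="equal"),
        accepted_error=0.01,
        generations=3,
        seed=11,
    )
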