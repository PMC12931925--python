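import numpy as np
import pytest

from circuitquant import (
    ConfluenceCondition,
    ConfluenceSpec,
    EventTableSpec,
    ImageSpec,
    ScreenSpec,
    generate_image_set,
)


@pytest.fixture(scope="session")
def defect_image():
    """A field with known intact, broken-ring, binucleate and debris objects."""
    spec = ImageSpec(width=384, height=384, n_cells=12, n_broken_ring=2,
                     n_binucleate=2, n_debris=3, seed=42)
    return generate_image_set(spec)


@pytest.fixture(scope="session")
def clean_image():
    spec = ImageSpec(width=320, height=320, n_cells=10, membrane_fraction=0.4, seed=5)
    return generate_image_set(spec)


@pytest.fixture
def event_spec():
    return EventTableSpec(n_events=10_000, seed=17)


@pytest.fixture
def screen_spec_noise_free():
    return ScreenSpec(
        effects={
            "binding_domain": {"RBD": (-0.6, -0.2)},
            "transactivation_domain": {"FLT": (0.4, 0.1)},
            "response_element": {"RE2": (0.25, 0.05)},
        },
        replicate_sd=0.0,
        seed=11,
    )


@pytest.fixture
def kill_conditions():
    return (
        ConfluenceCondition("EF1a_HSVTK", initial=12.0, growth_rate=0.02, kill_rate=0.06),
        ConfluenceCondition("GFP_control", initial=9.0, growth_rate=0.02, kill_rate=0.0),
        ConfluenceCondition("circuit", initial=11.0, growth_rate=0.02, kill_rate=0.04),
    )


@pytest.fixture
def confluence_spec(kill_conditions):
    return ConfluenceSpec(conditions=kill_conditions, noise_sd=0.0, seed=3)
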