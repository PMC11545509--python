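import numpy as np
import pytest

from pocketens.synthetic import BreathingSchedule, CageSpec, make_breathing_ensemble


@pytest.fixture(scope="session")
def sealed_cage_result():
    """Pipeline result for a small sealed all-carbon cage ensemble."""
    from pocketens.pipeline import analyze_replicates

    spec = CageSpec(cavity_radius=6.0, aperture_half_angle=0.0, apolar_fraction=1.0, seed=11)
    ensemble, truth = make_breathing_ensemble(
        spec, BreathingSchedule(n_frames=4, open_fraction=0.0, seed=11)
    )
    result = analyze_replicates([ensemble], enzyme="sealed-cage")
    return result, truth


@pytest.fixture(scope="session")
def breathing_cage_result():
    """Pipeline result for a 25-frame breathing cage, 64% open schedule."""
    from pocketens.pipeline import analyze_replicates

    spec = CageSpec(cavity_radius=6.0, aperture_half_angle=40.0, seed=7)
    ensemble, truth = make_breathing_ensemble(
        spec, BreathingSchedule(n_frames=25, open_fraction=0.64, seed=7)
    )
    result = analyze_replicates([ensemble], enzyme="breathing-cage")
    return result, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
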