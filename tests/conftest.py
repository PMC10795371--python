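import numpy as np
import pytest

from quollmove import MovementParams, StudyConfig, generate_landscape


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def params():
    return MovementParams()


@pytest.fixture(scope="session")
def small_landscape():
    """120x120-cell mosaic (1.2 km side) shared by the cheaper tests."""
    return generate_landscape(seed=11, n_rows=120, n_cols=120, smoothness=10.0)


@pytest.fixture(scope="session")
def study_landscape():
    """Full-size 400x400 landscape for pipeline-scale tests."""
    return generate_landscape(seed=7, n_rows=400, n_cols=400)


@pytest.fixture(scope="session")
def study_fixes(study_landscape, config, params):
    """One simulated study (9 individuals x 20 nights), exact positions."""
    from quollmove.simulate import simulate_study

    _, fixes, _, truth = simulate_study(
        study_landscape, config, seed=202, params=params,
        with_accel=False, gps_sigma=0.0,
    )
    return fixes, truth
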