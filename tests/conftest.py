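import numpy as np
import pytest

import lcspanel as L


@pytest.fixture(scope="session")
def preset():
    return L.nspn_like_preset()


@pytest.fixture(scope="session")
def cohort(preset):
    """One preset-calibrated cohort at the study size, with attrition."""
    return L.simulate_panel(preset, 785, seed=2024)


@pytest.fixture(scope="session")
def complete_cohort(preset):
    """Preset cohort with no wave-2 missingness (complete-data checks)."""
    from dataclasses import replace

    return L.simulate_panel(replace(preset, missing_rate=0.0), 600, seed=55)


@pytest.fixture(scope="session")
def fast():
    """Single-start optimizer options for simulation-heavy tests."""
    return L.FitOptions(n_starts=1)
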