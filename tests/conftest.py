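import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fovtopo.phantom import ScanGrid, make_boundary_profiles, phenotype_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def control_phenotype():
    return phenotype_preset("control")


@pytest.fixture
def small_grid():
    """A compact rendering grid: 256 columns, 160 rows (retina fits)."""
    return ScanGrid(n_ascans=256, n_rows=160)


@pytest.fixture
def control_scan(control_phenotype):
    """Full-size noise-free control scan: contours + ground truth."""
    return make_boundary_profiles(control_phenotype)
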