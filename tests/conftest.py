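import numpy as np
import pytest

from kpsfusion.synthetic import CohortConfig, TumorGeometry, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30 patients with volumes on a small grid (shared, read-only)."""
    cfg = CohortConfig(grid_shape=(32, 48, 48))
    clinical, studies = simulate_cohort(30, config=cfg, seed=42)
    return clinical, studies, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_geometry():
    return TumorGeometry(center=(16, 24, 24), core_radii=(4, 6, 6),
                         edema_margin=3.0, brain_center=(15.5, 23.5, 23.5),
                         brain_radii=(14, 21, 21))
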