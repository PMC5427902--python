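import numpy as np
import pytest

from esontcp import (
    AxialInterval,
    CohortConfig,
    EsophagusGeometry,
    LogisticV50Params,
    VoxelDoseMap,
    published_registry,
)

# Synthetic logistic-V50 coefficients for unit testing only: the published
# coefficients are not part of this package and must be transcribed by users.
KWINT_FIXTURE_G2 = LogisticV50Params(intercept=-2.0, slope=0.05, v50_mode="percent")
KWINT_FIXTURE_G3 = LogisticV50Params(intercept=-3.5, slope=0.05, v50_mode="percent")


@pytest.fixture(scope="session")
def registry():
    """All four models, logistic ones carrying the synthetic test coefficients."""
    return published_registry(kwint_g2=KWINT_FIXTURE_G2, kwint_g3=KWINT_FIXTURE_G3)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=20120901)


@pytest.fixture
def two_level_map():
    """Half the volume at 10 Gy, half at 30 Gy."""
    return VoxelDoseMap("p1", "SD", "ESO_whole", [5.0, 5.0], [10.0, 30.0])


@pytest.fixture
def worked_geometry():
    """Esophagus [0, 200), tumor [80, 130), field [60, 150), 0.15 cc/mm."""
    return EsophagusGeometry(
        esophagus=AxialInterval(0.0, 200.0),
        tumor=AxialInterval(80.0, 130.0),
        field=AxialInterval(60.0, 150.0),
        voxel_length_mm=1.0,
        cross_section_cc_per_mm=0.15,
    )


def random_voxel_map(rng: np.random.Generator, max_dose: float = 70.0) -> VoxelDoseMap:
    n = int(rng.integers(1, 40))
    return VoxelDoseMap(
        "p", "SD", "s",
        voxel_volume_cc=rng.uniform(0.05, 2.0, n),
        dose_gy=rng.uniform(0.0, max_dose, n),
    )
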