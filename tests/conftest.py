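import numpy as np
import pytest

from stenoshear.cohort import DESK_PRESET, GridPreset, generate_cohort
from stenoshear.geometry import resample_centerline, template_centerline
from stenoshear.stenosis import apply_stenosis, build_surface, make_stenosis_spec

#: tiny grid for fast model smoke tests (32 stations -> 28 kept, 8 sectors)
TINY_PRESET = GridPreset("tiny", 32, 8)


@pytest.fixture(scope="session")
def straight_cl():
    return resample_centerline(template_centerline("straight"), 640, 80.0)


@pytest.fixture(scope="session")
def throat_station(straight_cl):
    """A station index near mid-vessel to pin lesion throats exactly on."""
    return 320


@pytest.fixture(scope="session")
def concentric_lattice(straight_cl, throat_station):
    """Straight vessel with a station-aligned concentric round lesion,
    AR = 0.16 (the 1.2 mm throat reference case)."""
    pos = float(straight_cl.arc_coord[throat_station])
    spec = make_stenosis_spec("concentric_round", 0.16, pos)
    profile = apply_stenosis(straight_cl, [spec])
    return build_surface(straight_cl, profile, 40), spec


@pytest.fixture(scope="session")
def desk_cohort():
    """The desk-scale benchmark cohort: 100 vessels on the 160x20 lattice."""
    dataset, manifest = generate_cohort(100, DESK_PRESET, seed=1234)
    return dataset, manifest


@pytest.fixture(scope="session")
def tiny_cohort():
    dataset, _ = generate_cohort(12, TINY_PRESET, seed=99)
    return dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
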