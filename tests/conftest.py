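import numpy as np
import pytest

from tatdose.decay import chain_inventory, load_nuclide
from tatdose.microspec import DomainGeometry, reference_electron_spectrum, z_star_1d
from tatdose.mkm import MKMParams
from tatdose.phantom import build_phantom
from tatdose.volumes import CTVolume


@pytest.fixture(scope="session")
def geom():
    return DomainGeometry()


@pytest.fixture(scope="session")
def params():
    """Default HSG-cell parameters without microdosimetric calibration."""
    return MKMParams()


@pytest.fixture(scope="session")
def params_cal(geom):
    """Parameters with z*_1D,ref computed from the reference electron
    spectrum (fixed seed)."""
    ref = reference_electron_spectrum(geom, n_samples=100_000, seed=42)
    return MKMParams().with_reference(z_star_1d(ref, geom))


@pytest.fixture(scope="session")
def at211_inventory():
    return chain_inventory(load_nuclide("At-211"))


@pytest.fixture(scope="session")
def f18():
    return load_nuclide("F-18")


@pytest.fixture()
def water_phantom():
    """16^3 all-water phantom with 4 mm voxels (voxel mass 6.4e-5 kg)."""
    ct = CTVolume(hu=np.zeros((16, 16, 16)), spacing_mm=(4.0, 4.0, 4.0))
    return build_phantom(ct)
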