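import numpy as np
import pytest

from gabaquant.core import MEGA_PRESS_DEFAULTS, PRESS_DEFAULTS, AcquisitionParams, FID
from gabaquant.quantify import TissueFractions
from gabaquant.simulate import default_difference_basis


@pytest.fixture(scope="session")
def mega_params() -> AcquisitionParams:
    return MEGA_PRESS_DEFAULTS


@pytest.fixture(scope="session")
def press_params() -> AcquisitionParams:
    return PRESS_DEFAULTS


@pytest.fixture(scope="session")
def basis():
    return default_difference_basis()


@pytest.fixture(scope="session")
def theta() -> TissueFractions:
    # study-mean voxel composition: GM 33.2 %, WM 52.0 %, CSF 14.8 %
    return TissueFractions(theta_gm=0.332, theta_wm=0.520, theta_csf=0.148)


def make_line_fid(
    params: AcquisitionParams,
    freq_hz: float,
    amplitude: float = 1.0,
    linewidth_hz: float = 5.0,
    phase_rad: float = 0.0,
    label: str = "OFF",
) -> FID:
    """Single Lorentzian line as a damped complex exponential."""
    t = params.time_axis()
    samples = (
        amplitude
        * np.exp(1j * phase_rad)
        * np.exp((2j * np.pi * freq_hz - np.pi * linewidth_hz) * t)
    )
    return FID(samples=samples, params=params, label=label)


@pytest.fixture(scope="session")
def line_fid_factory():
    return make_line_fid
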