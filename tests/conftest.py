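import numpy as np
import pytest

from myoperf import ProtocolParams, default_cohort_config, generate_phantom
from myoperf.regions import build_t1_assignment


@pytest.fixture(scope="session")
def params():
    return ProtocolParams()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default cohort phantom, diastole, noise off."""
    cfg = default_cohort_config().replace(snr=np.inf)
    return generate_phantom(cfg, "diastole")


@pytest.fixture(scope="session")
def true_t1_assignment(noiseless_phantom):
    ph = noiseless_phantom
    return build_t1_assignment(
        "pixel_map",
        shape=ph.series.shape,
        geometry=ph.geometry,
        t1_map=ph.t1_map,
        blood_t1=ph.truth["t1"]["blood"],
        phase=ph.phase,
    )


def make_true_assignment(phantom):
    return build_t1_assignment(
        "pixel_map",
        shape=phantom.series.shape,
        geometry=phantom.geometry,
        t1_map=phantom.t1_map,
        blood_t1=phantom.truth["t1"]["blood"],
        phase=phantom.phase,
    )
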