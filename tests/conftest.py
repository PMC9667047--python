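import numpy as np
import pytest

from mpmri import phantom
from mpmri.pipeline import StudyConfig


@pytest.fixture(scope="session")
def het_truth():
    return phantom.make_phantom(phantom.HETEROGENEOUS, 6, (48, 48), seed=7)


@pytest.fixture(scope="session")
def hom_truth():
    return phantom.make_phantom(phantom.HOMOGENEOUS, 6, (48, 48), seed=7)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture()
def uniform_truth():
    """Phantom whose tumor voxels all share one truth value per map."""
    truth = phantom.make_phantom(phantom.HOMOGENEOUS, 3, (32, 32), seed=3)
    for pmap, value in ((truth.t1_ms, 1000.0), (truth.t2_ms, 40.0),
                        (truth.adc_mm2_per_s, 1.0e-3), (truth.s0_au, 500.0),
                        (truth.ktrans_per_min, 0.25), (truth.ve_frac, 0.4),
                        (truth.vp_frac, 0.02), (truth.gd_ug_per_g, 50.0)):
        pmap.values[:] = value
    return truth
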