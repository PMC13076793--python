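import numpy as np
import pytest

from pamangio.forward import AcquisitionSpec, OpticalSpec, TransducerSpec
from pamangio.phantom import PhantomSpec, grow_vascular_phantom


@pytest.fixture(scope="session")
def transducer():
    return TransducerSpec()


@pytest.fixture(scope="session")
def optics():
    return OpticalSpec()


@pytest.fixture(scope="session")
def quiet_acquisition():
    return AcquisitionSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    """A small day-6 network used by several suites (generated once)."""
    spec = PhantomSpec(volume_size_um=(400.0, 400.0, 300.0), culture_day=6,
                       rng_seed=11)
    return grow_vascular_phantom(spec)
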