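import numpy as np
import pytest

from smfluor.photonsim import EmitterModel, simulate_decay_photons
from smfluor.stream import AcquisitionConfig


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """80 MHz pulsed excitation, 50 us ALEX alternation, 256 TCSPC bins."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def mono_emitter() -> EmitterModel:
    """Single 4 ns lifetime, unpolarized emission, no blinking."""
    return EmitterModel(lifetimes_ns=(4.0,), fractions=(1.0,), r0=0.0,
                        rot_times_ns=(), rot_amplitudes=())


@pytest.fixture(scope="session")
def mono_stream(mono_emitter, acq):
    """3e5-photon TCSPC stream of the mono-exponential emitter."""
    return simulate_decay_photons(mono_emitter, acq, 300_000, seed=101)


@pytest.fixture(scope="session")
def free_dye_stream(acq):
    """Fast free-dye rotator: 4 ns lifetime, rho = 0.14 ns, r0 = 0.4."""
    emitter = EmitterModel(lifetimes_ns=(4.0,), fractions=(1.0,),
                           rot_times_ns=(0.14,), rot_amplitudes=(1.0,))
    return simulate_decay_photons(emitter, acq, 500_000, seed=102)


def assert_rel_close(value, expected, rtol, msg=""):
    assert expected != 0
    rel = abs(value - expected) / abs(expected)
    assert rel <= rtol, (msg or f"value {value} vs expected {expected}: "
                         f"relative error {rel:.4f} > {rtol}")
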