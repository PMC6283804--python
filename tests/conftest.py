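import pytest

from hybridose.core import RegionLabel
from hybridose.synthetic import (
    GroundTruthKinetics,
    NoiseOptions,
    default_phantom,
)


@pytest.fixture(scope="session")
def phantom():
    ph = default_phantom()
    ph.validate()
    return ph


@pytest.fixture(scope="session")
def phantom_labels(phantom):
    return phantom.label_volume()


@pytest.fixture
def noiseless_options():
    """Everything deterministic: no Poisson, no blur, no couch shifts."""
    return NoiseOptions(poisson=False, spect_blur_fwhm_mm=0.0, couch_shift_px=0)


def make_kinetics(
    uptakes=None,
    half_lives=None,
    a0=2000.0,
    times=(3.0, 24.0, 48.0),
    tau=0.0,
    **kwargs,
):
    """Kinetics factory with compact region dicts."""
    uptakes = uptakes or {RegionLabel.LIVER: 0.3}
    if half_lives is None:
        half_lives = {r: 12.6 for r in uptakes}
    return GroundTruthKinetics(
        uptake_fractions=uptakes,
        half_lives_h=half_lives,
        injected_activity_MBq=a0,
        scan_times_h=times,
        dead_time_tau_s=tau,
        **kwargs,
    )


@pytest.fixture
def kinetics_factory():
    return make_kinetics
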