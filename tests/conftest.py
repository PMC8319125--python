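import numpy as np
import pytest

import omiflim as of
from omiflim.core import TimeAxis


@pytest.fixture(scope="session")
def irf() -> of.IRFCurve:
    """Gaussian IRF (FWHM 250 ps) on the default 256-bin / 12.5 ns axis."""
    return of.synth_irf(250.0, 600.0)


@pytest.fixture(scope="session")
def axis(irf) -> TimeAxis:
    return irf.axis


def constant_maps(shape, channel="NADPH", *, alpha1=0.75, tau1=400.0,
                  tau2=2400.0, intensity=5000.0, valid=None):
    """LifetimeMaps with spatially constant parameters (test helper)."""
    full = lambda v: np.full(shape, float(v))
    tau_m = alpha1 * tau1 + (1 - alpha1) * tau2
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return of.LifetimeMaps(
        alpha1=full(alpha1), alpha2=full(1 - alpha1), tau1=full(tau1),
        tau2=full(tau2), tau_m=full(tau_m), offset=full(0.0),
        intensity=full(intensity), chi2=full(1.0), valid=valid,
        channel=channel)
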