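import numpy as np
import pytest

from dlnmx.basis import BasisSpec
from dlnmx.history import ExposureProfile
from dlnmx.survfit import CrossBasisTerm, FittedDLNM


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def toy_fit(fx_spec: BasisSpec, wl_spec: BasisSpec, lag_grid, eta, vcov=None) -> FittedDLNM:
    """A FittedDLNM with hand-set coefficients, for prediction oracles."""
    eta = np.asarray(eta, dtype=float)
    if vcov is None:
        vcov = 0.01 * np.eye(eta.size)
    term = CrossBasisTerm("x", fx_spec, wl_spec, np.asarray(lag_grid), 0, eta.size)
    return FittedDLNM(
        eta=eta,
        vcov=np.asarray(vcov, dtype=float),
        loglik=0.0,
        df_total=eta.size,
        n_events=1,
        terms={"x": term},
    )


@pytest.fixture
def pulse_profile():
    """20 units/year during years 1-15, zero afterwards."""
    return ExposureProfile("p", 1, np.where(np.arange(1, 61) <= 15, 20.0, 0.0))
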