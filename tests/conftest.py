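import numpy as np
import pytest

from drcsi.model import SpectralModel
from drcsi.phantom import default_phantom, simulate_dataset
from drcsi.preprocess import (
    extract_1d_subset,
    l2_normalize,
    polarity_correct,
    powder_average,
)
from drcsi.protocol import build_grid, make_protocol_preset


@pytest.fixture(scope="session")
def t1t2_protocol():
    return make_protocol_preset("t1t2")


@pytest.fixture(scope="session")
def small_phantom():
    """24 x 24 phantom, noiseless signed data: fast solver-level fixture."""
    spec = default_phantom(24, snr=None, seed=0)
    return spec


@pytest.fixture(scope="session")
def small_conditioned(t1t2_protocol):
    """Conditioned (powder-averaged, signed, normalized) 24 x 24 signals at
    SNR 100, with the phantom spec for ground-truth comparisons."""
    spec = default_phantom(24, snr=100.0, seed=7)
    raw = simulate_dataset(spec, t1t2_protocol)
    sv = l2_normalize(polarity_correct(powder_average(raw)))
    return spec, sv


@pytest.fixture(scope="session")
def small_t1_fit(small_conditioned):
    """1D T1 ADMM fit of the small conditioned phantom."""
    spec, sv = small_conditioned
    sub = extract_1d_subset(sv, "T1")
    model = SpectralModel(sub, grid=build_grid(["T1"]))
    res = model.fit()
    return spec, sv, sub, res
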