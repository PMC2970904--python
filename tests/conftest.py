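import numpy as np
import pytest

from ildnfit.torsion_model import ildn_parameters

ILDN_KEYS = [
    ("ILE", "chi1"),
    ("LEU", "chi1"),
    ("ASP", "chi1"),
    ("ASP", "chi2"),
    ("ASN", "chi1"),
    ("ASN", "chi2"),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20100517)


@pytest.fixture(params=ILDN_KEYS, ids=[f"{r}-{a}" for r, a in ILDN_KEYS])
def ildn_entry(request):
    residue, angle = request.param
    series, definition = ildn_parameters(residue, angle)
    return residue, angle, series, definition
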