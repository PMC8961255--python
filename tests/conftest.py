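import pytest

from npirepro import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table1_dprime():
    return load_fixture("table1_dprime")


#: Printed case-study statistics for the five adjacent-dose comparisons.
TABLE2 = {
    ("A", "B"): dict(reject=True, p=0.0003, es=0.226, d=2.041, rp_t=0.937, rp_w=0.902),
    ("B", "C"): dict(reject=True, p=0.0000, es=0.366, d=3.213, rp_t=1.000, rp_w=1.000),
    ("C", "D"): dict(reject=True, p=0.0007, es=0.178, d=1.753, rp_t=0.880, rp_w=0.862),
    ("D", "E"): dict(reject=True, p=0.0191, es=0.097, d=1.038, rp_t=0.586, rp_w=0.606),
    ("E", "F"): dict(reject=False, p=0.5977, es=-0.013, d=-0.115, rp_t=0.911, rp_w=0.935),
}

#: The bundled data carry 4 printed decimals, so statistics derived from them
#: can differ from values computed on unrounded data by a couple of units in
#: the last printed digit.
ATOL_3DP = 2e-3
ATOL_4DP = 2e-4
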