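import pytest

from sparselabel import data
from sparselabel.states import LabelScheme


@pytest.fixture(scope="session")
def vil():
    return LabelScheme.from_dict(data.VIL_SCHEME)


@pytest.fixture(scope="session")
def kgs():
    return LabelScheme.from_dict(data.KGS_SCHEME)


@pytest.fixture(scope="session")
def gfp_cd16a():
    return data.GFP_CD16A


#: tryptic peptides named in the figures, all present at 1 missed cleavage
NAMED_PEPTIDES = [
    "EEDPIHLR",
    "SAMPEGYVQER",
    "AVVFLEPQWYR",
    "TISFKDDGTYK",
    "FEGDTLVNR",
    "YFHHNSDFYIPK",
]


@pytest.fixture(scope="session")
def named_peptides():
    return list(NAMED_PEPTIDES)
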