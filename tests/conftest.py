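import numpy as np
import pytest

from ssmotif.discovery import SSMotif
from ssmotif.hairpins import SSString

WORKED_SEQ = "UUCCCAAAGUUGAGAA"
WORKED_STRUCT = "(((.((....)).)))"
WORKED_SS_TEXT = "ULULCLCDCLALADADGDUDURGRADGRARAR"


def ss_from_text(text: str) -> SSString:
    """Concrete ss-string from compact symbol text (test helper)."""
    m = SSMotif.from_text(text)
    assert all(s.is_concrete for s in m.symbols)
    return SSString(nuc=m.nuc_codes, struct=m.struct_codes)


@pytest.fixture
def worked_example():
    return WORKED_SEQ, WORKED_STRUCT, WORKED_SS_TEXT


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
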