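import random

import pytest

from pathforge.core import Pathway, build_pathway, default_dictionary

#: The eight-activity reference pathway used across the suite: an elevated
#: PSA of 45 ng/ml leading to diagnosis, a Gleason 4+3 grade, hormone therapy
#: and 37 radiotherapy sessions, then PSA falling to 0.2 and twice below the
#: 0.1 ng/ml assay limit.
REFERENCE_ROWS = [
    ("1", -28, "P", "45"),
    ("1", 0, "D", "2"),
    ("1", 1, "G", "4+3"),
    ("1", 1, "H", "Cyproterone Acetate"),
    ("1", 151, "R", "37"),
    ("1", 260, "P", "0.2"),
    ("1", 340, "P", "<0.1"),
    ("1", 539, "P", "<0.1"),
]


@pytest.fixture(scope="session")
def reference_rows():
    return list(REFERENCE_ROWS)


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture()
def reference_pathway(dictionary) -> Pathway:
    rows = list(REFERENCE_ROWS)
    random.Random(0).shuffle(rows)
    return build_pathway(rows, dictionary)


@pytest.fixture(scope="session")
def make_pathway(dictionary):
    """Build a pathway from compact (time, code, value) triples."""

    def _make(acts, pid="p"):
        return build_pathway([(pid, t, c, v) for t, c, v in acts], dictionary)

    return _make
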