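import numpy as np
import pytest

from sadscale.otu_io import AbundanceVector, OTUTable


@pytest.fixture
def toy_table() -> OTUTable:
    """3 OTUs x 2 samples with one zero-total-in-subset OTU."""
    counts = np.array([[2, 3], [0, 5], [1, 0]], dtype=np.int64)
    return OTUTable(("a", "b", "c"), ("s1", "s2"), counts)


@pytest.fixture
def small_vector() -> AbundanceVector:
    return AbundanceVector(("a", "b", "c", "d"), np.array([5, 5, 2, 1]))


def write_tsv(path, text):
    path.write_text(text)
    return path
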