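import numpy as np
import pytest

import isocloud as ic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bubble_graph():
    """Two transcripts sharing prefix and suffix around distinct middles.

    The classic bubble: P + M1 + S and P + M2 + S.  Returns
    (graph, k, transcripts).
    """
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    prefix = "".join(rng.choice(bases, 80))
    suffix = "".join(rng.choice(bases, 80))
    m1 = "".join(rng.choice(bases, 60))
    m2 = "".join(rng.choice(bases, 60))
    t1, t2 = prefix + m1 + suffix, prefix + m2 + suffix
    k = 21
    graph = ic.build_graph([t1, t2], k)
    return graph, k, (t1, t2)


def random_reads(rng, n_reads, read_len_range=(20, 60), alphabet="ACGT"):
    reads = []
    for _ in range(n_reads):
        L = int(rng.integers(*read_len_range))
        reads.append("".join(rng.choice(list(alphabet), L)))
    return reads
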