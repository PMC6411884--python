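import numpy as np
import pytest

from paleovia import simulate
from paleovia.adna import AlignedRead


@pytest.fixture(scope="session")
def two_sphere_params():
    """Two well-separated blurred spheres, one mildly and one heavily damaged."""
    return simulate.ImageSimParams(
        nuclei=[
            simulate.NucleusSpec((22.0, 14.0, 14.0), 5.0, 100.0, 1.0),
            simulate.NucleusSpec((22.0, 34.0, 34.0), 5.0, 100.0, 3.0),
        ],
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_sphere_stack(two_sphere_params):
    return simulate.gen_nucleus_stack(two_sphere_params)


def make_read(rid, start, seq, strand="+", qual=35, reference="ref"):
    return AlignedRead(
        id=rid, reference=reference, start=start, strand=strand,
        sequence=seq, qualities=np.full(len(seq), qual, dtype=int),
    )


@pytest.fixture
def simple_reads():
    #            0123456789
    # reference: ACGTACGTAC (given in tests that need it)
    return [
        make_read("r1", 0, "ACGTA"),
        make_read("r2", 2, "GTACG"),
        make_read("r3", 0, "ACGTA", strand="-"),
    ]
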