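import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from denoise_impact import (
    DEFAULT_PRIMER,
    NoiseModel,
    RawRead,
    RawReadSet,
    SimulationDesign,
    generate_community,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(20, abundance_shape=1.2, divergence=0.06, seed=42)


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign.full_crossing(
        reads_per_sample=200, seed=42, hosts=("h1", "h2"), richness=(1, 32), replicates=(1,)
    )


@pytest.fixture(scope="session")
def small_rawset(small_community, small_design):
    return simulate_reads(small_community, small_design, NoiseModel(), primer=DEFAULT_PRIMER)


@pytest.fixture(scope="session")
def clean_rawset(small_community, small_design):
    """Zero-noise reads: every read equals its template."""
    return simulate_reads(small_community, small_design, NoiseModel.noiseless(), primer=DEFAULT_PRIMER)


def make_read(read_id, seq, sample="s1", qual=None, primer=DEFAULT_PRIMER, **kw):
    bases = primer + seq
    q = np.full(len(bases), 35, dtype=np.int16) if qual is None else np.asarray(qual, dtype=np.int16)
    return RawRead(read_id, sample, bases, q, kw.pop("true_taxon", "t1"), None, [], **kw)


@pytest.fixture()
def toy_reads():
    return make_read
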