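import numpy as np
import pytest

from teanchor import SimConfig, load_default_ctcf_pwm
from teanchor.core import GenomicInterval
from teanchor.motifs import MotifHit
from teanchor.pipeline import run_synthetic
from teanchor.simulate import generate_dataset

SEED = 7


@pytest.fixture(scope="session")
def pwm():
    return load_default_ctcf_pwm()


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(SimConfig(seed=SEED))


@pytest.fixture(scope="session")
def pipeline_result():
    return run_synthetic(SimConfig(seed=SEED))


def make_hit(chrom="chr1", start=1000, width=19, strand="+", score=12.0):
    return MotifHit(interval=GenomicInterval(chrom, start, start + width, strand),
                    strand=strand, score=score)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
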