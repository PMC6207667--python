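import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from arfcaliper import simulate
from arfcaliper.core import GenomicInterval, Peak, PeakSet


@pytest.fixture(scope="session")
def small_genome():
    """100 kb i.i.d. genome at maize-like GC."""
    return simulate.simulate_genome(100_000, 0.47, seed=11)


@pytest.fixture(scope="session")
def planted():
    """400 kb genome with DR7, ER11 and IR2 elements planted."""
    genome = simulate.simulate_genome(400_000, 0.47, seed=21)
    plan = [
        simulate.PlantSpec("DR", 7, 220),
        simulate.PlantSpec("ER", 11, 220),
        simulate.PlantSpec("IR", 2, 220),
    ]
    return simulate.plant_motif_architecture(genome, plan, seed=22)


def make_peakset(tf_id, coords, clade=".", subclade=".", signal=1.0, chrom="chr1"):
    """PeakSet from a list of (start, end) tuples, summit at midpoint."""
    peaks = [
        Peak(GenomicInterval(chrom, s, e), summit_offset=(e - s) // 2,
             signal=signal, name=f"{tf_id}_{i}")
        for i, (s, e) in enumerate(coords)
    ]
    return PeakSet(tf_id, clade, subclade, peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
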