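import numpy as np
import pytest

from lncland.formats import CoverageTrack, Transcript
from lncland.pipeline import RunConfig, run_all
from lncland.sim import SimConfig


@pytest.fixture(scope="session")
def default_run():
    """One full simulate-then-analyze run at the default study conditions."""
    return run_all(RunConfig())


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run["truth"]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_track(rng, length, chromosome="chr1", strand="+",
                 signal_prob=0.3, signal_level=30.0):
    """A track with random noise plus a few rectangular signal blocks."""
    density = rng.poisson(2.0, size=length).astype(float)
    n_blocks = rng.integers(0, 5)
    for _ in range(n_blocks):
        if rng.random() > signal_prob:
            continue
        s = int(rng.integers(0, max(1, length - 50)))
        w = int(rng.integers(20, 400))
        density[s:min(s + w, length)] += signal_level * rng.uniform(0.5, 4.0)
    return CoverageTrack(chromosome, strand, density)


def random_transcripts(rng, n, genome_size, chromosome="chr1", prefix="t"):
    """Random stranded transcripts, possibly overlapping, for oracle tests."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, genome_size - 250))
        length = int(rng.integers(200, min(2500, genome_size - start)))
        out.append(Transcript(
            id=f"{prefix}{i:03d}", chromosome=chromosome,
            strand="+" if rng.random() < 0.5 else "-",
            start=start, end=start + length,
            biotype="mRNA" if prefix == "m" else "lncRNA",
        ))
    return out
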