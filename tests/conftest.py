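import numpy as np
import pytest

from smsmap import SequenceRecord, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    """10 kb random genome shared by read-scale tests."""
    return generate_genome(10_000, 0.5, seed=99)


def random_read_from(genome: SequenceRecord, rng, length: int,
                     error_rate: float = 0.0):
    """Copy a read from a random genome interval, optionally perturbed."""
    start = int(rng.integers(0, len(genome) - length + 1))
    seq = genome.bases[start : start + length]
    if error_rate:
        seq = perturb(seq, rng, error_rate)
    return seq, start


def perturb(seq: str, rng, rate: float) -> str:
    """Simple independent edit injector (not the package simulator)."""
    bases = "ACGT"
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 3:
            out.append(bases[int(rng.integers(0, 4))])  # substitution
        elif r < 2 * rate / 3:
            out.append(bases[int(rng.integers(0, 4))])  # insertion
            out.append(ch)
        elif r < rate:
            pass  # deletion
        else:
            out.append(ch)
    return "".join(out)
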