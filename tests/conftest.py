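import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitopool.phylotree import HaplotypeDefinition, PhyloTreeDB, Variant
from mitopool.readmodel import AlignedFragment, SampleAlignment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_reference() -> str:
    rng = np.random.default_rng(1234)
    return "".join(rng.choice(list("ACGT"), size=400))


@pytest.fixture
def toy_db(toy_reference) -> PhyloTreeDB:
    """Three haplotypes with two private variants each, on a 400 bp genome."""

    def private(pos):
        ref = toy_reference[pos - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        return Variant(pos, ref, alt)

    haplotypes = {
        "H1a": HaplotypeDefinition("H1a", (private(50), private(120))),
        "H2": HaplotypeDefinition("H2", (private(200), private(260))),
        "U5a": HaplotypeDefinition("U5a", (private(310), private(360))),
    }
    return PhyloTreeDB(
        reference_id="toy_ref",
        genome_length=400,
        haplotypes=haplotypes,
        haplogroup_labels=("H", "HV", "U5"),
    )


def make_fragment(read_id: str, start: int, bases: str, q: float = 30.0) -> AlignedFragment:
    """A contiguous fragment with a uniform Phred quality."""
    n = len(bases)
    return AlignedFragment(
        read_id=read_id,
        positions=np.arange(start, start + n, dtype=np.int64),
        bases=np.array(list(bases), dtype="U1"),
        error_probs=np.full(n, 10 ** (-q / 10)),
    )


def make_sample(fragments, genome_length=400, sample_id="s", reference_id="toy_ref"):
    return SampleAlignment(
        sample_id=sample_id,
        reference_id=reference_id,
        genome_length=genome_length,
        fragments=tuple(fragments),
    )


@pytest.fixture
def fragment_factory():
    return make_fragment


@pytest.fixture
def sample_factory():
    return make_sample
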