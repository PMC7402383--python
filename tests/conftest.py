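import numpy as np
import pytest
from hypothesis import settings

from asmqc.seqio import ReadRecord
from asmqc.simulate import FixtureSpec, make_labeled_sam, random_genome

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    return random_genome(5000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def labeled_fixture(reference, tmp_path_factory):
    """A 700-read synthetic SAM with uniform-ish label mix and known truth."""
    sam = tmp_path_factory.mktemp("sam") / "fixture.sam"
    spec = FixtureSpec(n_reads=700, read_length=100, seed=7)
    truth, reads = make_labeled_sam(spec, reference, sam)
    return {"sam": sam, "truth": truth, "reads": reads, "spec": spec}


def random_read(rng: np.random.Generator, length: int, read_id: str = "r") -> ReadRecord:
    bases = "".join(rng.choice(list("ACGT"), size=length))
    quals = tuple(int(q) for q in rng.integers(0, 42, size=length))
    return ReadRecord(read_id, bases, quals)
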