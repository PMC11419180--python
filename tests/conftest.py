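import io
import random

import pytest

from wgakit import MutationSpec, SequenceStore, generate_pair, read_maf
from wgakit.convert import maf_to_alignment

TOY_TARGET = "ACGTACGTAC"
TOY_QUERY = "ACGTTCTAC"
TOY_QUERY_GAPPED = "ACGTTC-TAC"
TOY_MAF = (
    "a\n"
    "s ref.chr1 0 10 + 10 ACGTACGTAC\n"
    "s qry.chr1 0 9 + 9 ACGTTC-TAC\n"
    "\n"
)


@pytest.fixture
def toy_block():
    return next(read_maf(io.StringIO(TOY_MAF)))


@pytest.fixture
def toy_record(toy_block):
    return maf_to_alignment(toy_block)


@pytest.fixture
def toy_store():
    return SequenceStore({"ref.chr1": TOY_TARGET, "qry.chr1": TOY_QUERY})


def random_spec(seed: int, with_inversion: bool = False) -> MutationSpec:
    """A moderately mutated genome pair: 20 SNPs, 3 insertions and 3
    deletions of 1-80 bp, optionally one 40 bp inversion."""
    rng = random.Random(seed * 7919 + 13)
    return MutationSpec(
        n_snps=20,
        insertions=tuple(rng.randint(1, 80) for _ in range(3)),
        deletions=tuple(rng.randint(1, 80) for _ in range(3)),
        inversion=40 if with_inversion else None,
        seed=seed,
    )


@pytest.fixture
def pair_factory():
    def make(seed: int, with_inversion: bool = False, ref_length: int = 1000):
        return generate_pair(ref_length, random_spec(seed, with_inversion))

    return make
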