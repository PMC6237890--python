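import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from pinnevo.io_formats import CodonAlignment, LabeledTree, ProteinAlignment

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture
def toy_codon_alignment() -> CodonAlignment:
    return CodonAlignment(
        "toy", ["A", "B", "C"], ["ATGAAATGC", "ATGAAGTGT", "ATAAAATGC"]
    )


@pytest.fixture
def star_tree() -> LabeledTree:
    return LabeledTree.from_newick("(A:0.12,B:0.3,C:0.27);")


@pytest.fixture
def cherry_tree() -> LabeledTree:
    return LabeledTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")


@pytest.fixture
def toy_protein_alignment() -> ProteinAlignment:
    return ProteinAlignment("toyp", ["A", "B", "C"], ["MKW", "MRW", "LKC"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
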