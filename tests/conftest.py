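from importlib import resources

import numpy as np
import pytest
from hypothesis import settings

from isomirkit import read_mature_annotations, read_precursor_fasta

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mir140_reference():
    """The packaged hsa-mir-140 hairpin with both mature annotations."""
    data = resources.files("isomirkit.data")
    with resources.as_file(data / "hsa-mir-140.fa") as fasta:
        precursors = read_precursor_fasta(fasta)
    with resources.as_file(data / "hsa-mir-140.gff3") as gff:
        annotations = read_mature_annotations(gff, precursors)
    return precursors, annotations


@pytest.fixture
def rng():
    return np.random.default_rng(20160808)


MIR140_3P = "TACCACAGGGTAGAACCACGG"
MIR140_3P_ISOMIR = "ACCACAGGGTAGAACCACGGAC"


@pytest.fixture(scope="session")
def mature_140():
    return MIR140_3P


@pytest.fixture(scope="session")
def isomir_140():
    return MIR140_3P_ISOMIR
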