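import pytest

from corkosc import FamilySpec, LabeledMsa, simulate_labeled_family
from corkosc.seq import Msa, SequenceRecord


@pytest.fixture(scope="session")
def default_family():
    """The default synthetic family: 3 groups x 10 sequences, 400 columns,
    5 planted diagnostic columns, divergence 0.3, noise 0.05, seed 7."""
    return simulate_labeled_family(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def default_labeled_msa(default_family):
    return LabeledMsa(default_family.protein_msa, default_family.labels)


def make_msa(rows, ids=None):
    """Small helper: build an Msa from a list of equal-length strings."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Msa.from_records(SequenceRecord(i, r) for i, r in zip(ids, rows))
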