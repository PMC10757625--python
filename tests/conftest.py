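import pytest

from biopepscan import (
    BiopeptideLibrary,
    BiopeptideRecord,
    ProteinRecord,
)


def make_record(pid, seq, activities=("ACE inhibitor",), name=None, mass=None):
    return BiopeptideRecord(pid, name or f"peptide {pid}", seq, mass, tuple(activities))


@pytest.fixture
def tiny_library():
    """Five peptides over three activity categories; P4/P5 share a sequence."""
    return BiopeptideLibrary(
        [
            make_record("P1", "AA", ("ACE inhibitor",)),
            make_record("P2", "AD", ("ACE inhibitor",)),
            make_record("P3", "GGG", ("DPP-4 inhibitor",)),
            make_record("P4", "WKV", ("antioxidative",)),
            make_record("P5", "WKV", ("DPP-4 inhibitor", "antioxidative")),
        ],
        provenance="fixture",
    )


@pytest.fixture
def tiny_proteome():
    return [
        ProteinRecord("prot1", "first", "AADAA"),
        ProteinRecord("prot2", "second", "GGGGWKV"),
        ProteinRecord("prot3", "no hits", "MMMMM"),
    ]
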