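import numpy as np
import pytest

from dupsel.core_io import (
    STANDARD_CODE,
    CodonAlignment,
    SequenceRecord,
    build_codon_alignment,
)


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def tiny_alignment():
    """Three short in-frame sequences with a few substitutions."""
    records = [
        SequenceRecord(id="a", residues="ATGAAATTTGGGCCA"),
        SequenceRecord(id="b", residues="ATGAAGTTTGGGCCA"),
        SequenceRecord(id="c", residues="ATGAAATTCGGACCA"),
    ]
    return build_codon_alignment(records)


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "seqs.fasta"
    path.write_text(">a first\nATGAAA\n>b second\nATGCCC\n")
    return path
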