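import pytest

from naspkit.seqio import GeneticCode, Sequence, SequenceSet


@pytest.fixture(scope="session")
def std_code() -> GeneticCode:
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def ciliate_code() -> GeneticCode:
    return GeneticCode.ciliate()


def nt(seq_id: str, residues: str) -> Sequence:
    return Sequence(id=seq_id, residues=residues, kind="nucleotide")


def aa(seq_id: str, residues: str) -> Sequence:
    return Sequence(id=seq_id, residues=residues, kind="protein")


def nt_set(*pairs: tuple[str, str]) -> SequenceSet:
    return SequenceSet(nt(i, r) for i, r in pairs)


def aa_set(*pairs: tuple[str, str]) -> SequenceSet:
    return SequenceSet(aa(i, r) for i, r in pairs)
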