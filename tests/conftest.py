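import numpy as np
import pytest

from domyseq.reference import PlasmidMap
from domyseq.scenarios import _CODON_FOR, _SENSE_CODONS


def build_toy_plasmid(
    orf_aa: int = 100,
    length: int = 600,
    cds_start: int = 60,
    seed: int = 0,
    peptide_inserts: tuple = (),
    name: str = "pTOY",
) -> PlasmidMap:
    """Small random plasmid with a stop-free ORF, for unit tests."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=orf_aa - 1)
    ]
    for start_res, pep in peptide_inserts:
        for j, aa in enumerate(pep):
            codons[start_res - 1 + j] = _CODON_FOR[aa]
    orf = "".join(codons) + "TAA"
    backbone_len = length - len(orf)
    assert backbone_len >= cds_start
    backbone = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=backbone_len)])
    seq = backbone[:cds_start] + orf + backbone[cds_start:]
    return PlasmidMap(name=name, sequence=seq, cds_start=cds_start, cds_aa_length=orf_aa)


@pytest.fixture
def toy_plasmid() -> PlasmidMap:
    return build_toy_plasmid()


@pytest.fixture(scope="session")
def toy_plasmid_session() -> PlasmidMap:
    return build_toy_plasmid()
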