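import numpy as np
import pytest

from termbias.proteome import ProteinRecord
from termbias.simulate import AMINO_ACIDS, DEFAULT_BULK_FREQ


def make_record(
    aa_seq: str,
    protein_id: str = "p1",
    genome_id: str = "g1",
    stop_codon: str = "TAA",
    codon_table_id: int = 11,
    **kwargs,
) -> ProteinRecord:
    """Build a consistent record by back-translating with fixed codons."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[codon_table_id]
    first_codon = {}
    for codon, aa in sorted(table.forward_table.items()):
        first_codon.setdefault(aa, codon)
    codons = tuple(first_codon[aa] for aa in aa_seq)
    return ProteinRecord(
        protein_id=protein_id,
        genome_id=genome_id,
        aa_seq=aa_seq,
        codon_seq=codons,
        stop_codon=stop_codon,
        codon_table_id=codon_table_id,
        **kwargs,
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    p = np.array([DEFAULT_BULK_FREQ[a] for a in AMINO_ACIDS])
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=p / p.sum()))


@pytest.fixture(scope="session")
def null_proteome():
    """A no-bias synthetic proteome reused by several tests."""
    from termbias.simulate import ProteomeConfig, gen_proteome

    table, truth = gen_proteome(ProteomeConfig(n_genes=1500, seed=11))
    return table, truth
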