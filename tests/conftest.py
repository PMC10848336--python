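from __future__ import annotations

import numpy as np
import pytest

from vlfscan.seqtable import AMINO_ACID, NUCLEOTIDE, SequenceTable


def make_table(rows, alphabet=NUCLEOTIDE) -> SequenceTable:
    """Build a SequenceTable from (specimen_id, species, sequence) triples."""
    ids = [r[0] for r in rows]
    species = [r[1] for r in rows]
    residues = np.array([list(r[2]) for r in rows], dtype="<U1")
    return SequenceTable(alphabet, ids, species, residues)


def uniform_table(n, seq, species="Sp one", alphabet=NUCLEOTIDE) -> SequenceTable:
    """n identical copies of one sequence, one species."""
    return make_table([(f"S{i:05d}", species, seq) for i in range(n)], alphabet)


def one_variant_table(n, base_seq, row, position, symbol, alphabet=NUCLEOTIDE):
    """n copies of base_seq with a single substitution in one record."""
    rows = [(f"S{i:05d}", "Sp one", base_seq) for i in range(n)]
    seq = list(base_seq)
    seq[position - 1] = symbol
    rows[row] = (rows[row][0], rows[row][1], "".join(seq))
    return make_table(rows, alphabet)


@pytest.fixture
def fasta_file(tmp_path):
    """Tiny aligned FASTA with '|'-delimited headers (length 12)."""
    text = (
        ">GBGC1668-06|NC 005317|Thunnus alalunga|COI-5P\nACGTACGTACGT\n"
        ">SPEC2|x|Thunnus alalunga|COI-5P\nacgtacgtacgu\n"
        ">SPEC3|y|Gadus morhua|COI-5P\nACGTACGTACGA\n"
    )
    path = tmp_path / "mini.fasta"
    path.write_text(text)
    return path
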