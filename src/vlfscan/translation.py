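"""Codon translation and amino-acid residue typing.

Barcode alignments are assumed to start on codon position 1, so residue *j*
of the translation comes from nucleotides ``3j-2 .. 3j`` (1-based).  Codon
tables come from Biopython's NCBI tables; the mitochondrial tables matter
here because COI is mitochondrially encoded (e.g. TGA codes tryptophan, not
stop, under the vertebrate mitochondrial code).

Codons containing ambiguity codes are resolved through their IUPAC
expansions: if every resolution yields the same residue the codon translates
normally, otherwise it becomes 'X'.  In-frame stops are rendered '*'; both
'X' and '*' are non-canonical for frequency purposes, so they never enter
variant statistics — stop codons are a validation signal (NUMTs, frame
errors), not a variant class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable as _NCBI
from Bio.Data.IUPACData import ambiguous_dna_values

from .seqtable import AMINO_ACID, NUCLEOTIDE, SequenceTable

#: Supported codon-table ids -> NCBI translation table numbers.
CODON_TABLE_IDS = {
    "standard": 1,
    "vertebrate_mitochondrial": 2,
    "invertebrate_mitochondrial": 5,
}

STOP = "*"
UNKNOWN = "X"


def get_codon_table(table_id: str) -> _NCBI.CodonTable:
    """NCBI codon table for one of the supported ids."""
    try:
        ncbi_id = CODON_TABLE_IDS[table_id]
    except KeyError:
        raise ValueError(
            f"unknown codon table {table_id!r}; choose from {sorted(CODON_TABLE_IDS)}"
        ) from None
    return _NCBI.unambiguous_dna_by_id[ncbi_id]


def _codon_map(table_id: str) -> dict[str, str]:
    """codon -> residue map with ambiguity codes resolved where unambiguous."""
    tab = get_codon_table(table_id)
    base: dict[str, str] = dict(tab.forward_table)
    for codon in tab.stop_codons:
        base[codon] = STOP
    return base


def translate_codon(codon: str, table_id: str = "vertebrate_mitochondrial") -> str:
    """Translate one 3-mer; ambiguity-aware, 'X' when resolutions disagree."""
    mapping = _codon_map(table_id)
    codon = codon.upper().replace("U", "T")
    if codon in mapping:
        return mapping[codon]
    # expand IUPAC codes; anything with no expansion (gaps, '?') forces X
    expansions = []
    for base in codon:
        exp = ambiguous_dna_values.get(base)
        if not exp:
            return UNKNOWN
        expansions.append(exp)
    residues = {
        mapping[a + b + c]
        for a in expansions[0]
        for b in expansions[1]
        for c in expansions[2]
    }
    return residues.pop() if len(residues) == 1 else UNKNOWN


def translate(
    table: SequenceTable, codon_table: str = "vertebrate_mitochondrial"
) -> SequenceTable:
    """Translate a nucleotide table into an amino-acid table, frame 1.

    A trailing partial codon is dropped with a warning.  Specimen and species
    labels carry over unchanged.
    """
    if table.alphabet != NUCLEOTIDE:
        raise ValueError("translate expects a nucleotide table")
    n_codons = table.seqlength // 3
    if table.seqlength % 3:
        import warnings

        warnings.warn(
            f"alignment length {table.seqlength} is not a codon multiple; "
            f"dropping trailing {table.seqlength % 3} nt"
        )
    mapping = _codon_map(codon_table)
    cache: dict[str, str] = {}
    out = np.empty((table.n_records, n_codons), dtype="<U1")
    for r in range(table.n_records):
        row = table.residues[r]
        for k in range(n_codons):
            codon = row[3 * k] + row[3 * k + 1] + row[3 * k + 2]
            aa = mapping.get(codon)
            if aa is None:
                aa = cache.get(codon)
                if aa is None:
                    aa = translate_codon(codon, codon_table)
                    cache[codon] = aa
            out[r, k] = aa
    return SequenceTable(
        AMINO_ACID, list(table.specimen_ids), list(table.species_names), out
    )


@dataclass
class ResidueTypeScheme:
    """Partition of the 20 amino acids into physicochemical classes.

    The default five-way scheme (nonpolar / aromatic / polar-uncharged /
    positive / negative) is a conventional choice; a variant that changes the
    class of the modal residue is a stronger hint of a structural effect than
    one that stays within class.
    """

    classes: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_CLASSES))

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.classes)
        if missing:
            raise ValueError(f"scheme misses amino acids: {sorted(missing)}")


_DEFAULT_CLASSES: dict[str, str] = {}
for _aa in "GAVLIPM":
    _DEFAULT_CLASSES[_aa] = "nonpolar"
for _aa in "FWY":
    _DEFAULT_CLASSES[_aa] = "aromatic"
for _aa in "STCNQ":
    _DEFAULT_CLASSES[_aa] = "polar-uncharged"
for _aa in "KRH":
    _DEFAULT_CLASSES[_aa] = "positive"
for _aa in "DE":
    _DEFAULT_CLASSES[_aa] = "negative"


def residue_class(symbol: str, scheme: ResidueTypeScheme | None = None) -> str:
    """Class label for a canonical amino acid; non-canonical input is an error."""
    scheme = scheme or ResidueTypeScheme()
    try:
        return scheme.classes[symbol]
    except KeyError:
        raise ValueError(f"{symbol!r} is not a canonical amino acid") from None


def amino_acid_analysis(
    table: SequenceTable,
    p: float = 0.001,
    own: SequenceTable | None = None,
    own_classification: str = "own",
):
    """VLF pipeline on an amino-acid table (pre-translated or from :func:`translate`).

    Identical contract to :func:`vlfscan.core.vlf_analysis`; the default
    alignment width in barcode work is 216 residues (648 nt / 3).
    """
    from .core import vlf_analysis

    if table.alphabet != AMINO_ACID:
        raise ValueError("amino_acid_analysis expects an amino-acid table")
    return vlf_analysis(table, p=p, own=own, own_classification=own_classification)
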