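"""Aligned sequence tables and FASTA ingestion.

The canonical in-memory container is :class:`SequenceTable`: an aligned,
equal-length block of protein-coding sequences, one row per specimen, with a
specimen identifier and a species name attached to every row.  Input is plain
FASTA whose headers carry '|'-delimited metadata fields, e.g.::

    >GBGC1668-06|NC 005317|Thunnus alalunga|COI-5P

where the specimen identifier and species name sit at user-chosen field
positions (1-based; defaults 1 and 3).

Alignment positions are 1-based and inclusive throughout the package, and
position 1 is assumed to be codon position 1 of the reading frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

#: Canonical symbols per alphabet.  Everything else (N, IUPAC ambiguity
#: codes, '-', 'X', '*') is retained in the matrix but tagged non-canonical:
#: it never enters frequency numerators and is never flagged as a variant.
CANONICAL = {
    NUCLEOTIDE: "ACGT",
    AMINO_ACID: "ACDEFGHIKLMNPQRSTVWY",
}


class FastaParseError(ValueError):
    """Malformed FASTA header (too few '|'-delimited fields, empty field)."""


class AlignmentLengthError(ValueError):
    """A record's sequence length disagrees with the declared alignment length."""


@dataclass
class SequenceTable:
    """An aligned block of sequences with per-record specimen/species labels.

    Parameters
    ----------
    alphabet
        ``"nucleotide"`` or ``"amino-acid"``.
    specimen_ids, species_names
        Per-record labels, file order preserved.
    residues
        ``(n_records, seqlength)`` array of single uppercase characters.
    """

    alphabet: str
    specimen_ids: list[str]
    species_names: list[str]
    residues: np.ndarray

    def __post_init__(self) -> None:
        if self.alphabet not in CANONICAL:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = np.asarray(self.residues, dtype="<U1")
        if self.residues.ndim != 2:
            raise ValueError("residues must be a 2-D (records x positions) array")
        n = self.residues.shape[0]
        if not (len(self.specimen_ids) == len(self.species_names) == n):
            raise ValueError("label lists and residue matrix disagree in length")
        for i, (sid, sp) in enumerate(zip(self.specimen_ids, self.species_names)):
            if not sid:
                raise ValueError(f"record {i}: empty specimen_id")
            if not sp:
                raise ValueError(f"record {i}: empty species_name")

    @property
    def n_records(self) -> int:
        return self.residues.shape[0]

    @property
    def seqlength(self) -> int:
        return self.residues.shape[1]

    def canonical_mask(self) -> np.ndarray:
        """Boolean (records x positions) mask of canonical symbols."""
        return np.isin(self.residues, list(CANONICAL[self.alphabet]))

    def subset(self, indices) -> "SequenceTable":
        """New table containing the given record indices, order preserved."""
        idx = np.asarray(indices, dtype=int)
        return SequenceTable(
            self.alphabet,
            [self.specimen_ids[i] for i in idx],
            [self.species_names[i] for i in idx],
            self.residues[idx].copy(),
        )

    def trim(self, trim5: int = 0, trim3: int = 0) -> "SequenceTable":
        """Drop ``trim5`` leading and ``trim3`` trailing alignment columns."""
        if trim5 < 0 or trim3 < 0 or trim5 + trim3 >= self.seqlength:
            raise ValueError("degenerate trim: nothing (or less) would remain")
        stop = self.seqlength - trim3
        return SequenceTable(
            self.alphabet,
            list(self.specimen_ids),
            list(self.species_names),
            self.residues[:, trim5:stop].copy(),
        )


@dataclass
class ValidationReport:
    """Alignment sanity report: length uniformity, ambiguity load, stop codons."""

    uniform_length: bool
    offending_records: list[tuple[str, int]]
    non_canonical_fraction: dict[str, float]
    stop_codon_hits: list[tuple[str, int]] = field(default_factory=list)


def _parse_header(header: str, pos1: int, pos2: int, recno: int) -> tuple[str, str]:
    fields = [f.strip() for f in header.split("|")]
    need = max(pos1, pos2)
    if len(fields) < need:
        raise FastaParseError(
            f"record {recno} ({header!r}): header has {len(fields)} '|'-delimited "
            f"fields, need at least {need}"
        )
    specimen_id = fields[pos1 - 1]
    species = fields[pos2 - 1]
    if not specimen_id:
        raise FastaParseError(f"record {recno} ({header!r}): empty specimen field")
    if not species:
        raise FastaParseError(f"record {recno} ({header!r}): empty species field")
    return specimen_id, species


def read_fasta_matrix(
    path,
    seqlength: int = 648,
    pos1: int = 1,
    pos2: int = 3,
    alphabet: str = NUCLEOTIDE,
) -> SequenceTable:
    """Read an aligned, '|'-headed FASTA file into a :class:`SequenceTable`.

    Every sequence must have exactly ``seqlength`` characters; a mismatch is
    an error naming the record — there is no silent padding or truncation.
    Sequences are uppercased; for nucleotide tables 'U' is mapped to 'T'.
    File order is preserved.  Duplicate specimen identifiers are allowed but
    logged as a warning.
    """
    ids: list[str] = []
    species: list[str] = []
    rows: list[list[str]] = []
    for recno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        sid, sp = _parse_header(rec.description, pos1, pos2, recno)
        seq = str(rec.seq).upper()
        if alphabet == NUCLEOTIDE:
            seq = seq.replace("U", "T")
        if len(seq) != seqlength:
            raise AlignmentLengthError(
                f"record {recno} ({sid}): sequence length {len(seq)} != "
                f"declared alignment length {seqlength}"
            )
        ids.append(sid)
        species.append(sp)
        rows.append(list(seq))
    if not rows:
        raise FastaParseError(f"no FASTA records found in {path}")
    if len(set(ids)) != len(ids):
        logger.warning("duplicate specimen identifiers present in %s", path)
        warnings.warn(f"duplicate specimen identifiers present in {path}")
    return SequenceTable(alphabet, ids, species, np.array(rows, dtype="<U1"))


def validate_alignment(table: SequenceTable, codon_table: str | None = None) -> ValidationReport:
    """Report length uniformity, per-record ambiguity fraction and stop codons.

    ``codon_table`` (a codon-table id, see :mod:`vlfscan.translation`) only
    applies to nucleotide tables: in-frame stop codons are then listed as
    ``(specimen_id, codon_index)`` pairs with 1-based codon indices.
    """
    mask = table.canonical_mask()
    frac = 1.0 - mask.mean(axis=1)
    report = ValidationReport(
        uniform_length=True,  # construction enforces equal row lengths
        offending_records=[],
        non_canonical_fraction={
            sid: float(f) for sid, f in zip(table.specimen_ids, frac)
        },
    )
    if codon_table is not None and table.alphabet == NUCLEOTIDE:
        from .translation import get_codon_table

        tab = get_codon_table(codon_table)
        n_codons = table.seqlength // 3
        for r in range(table.n_records):
            row = table.residues[r]
            for k in range(n_codons):
                codon = "".join(row[3 * k : 3 * k + 3])
                if codon in tab.stop_codons:
                    report.stop_codon_hits.append((table.specimen_ids[r], k + 1))
    return report
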