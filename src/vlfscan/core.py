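"""Flagging and classification of very-low-frequency variants (VLFs).

A VLF is a canonical symbol whose relative frequency at its alignment
position, across the whole reference library, is strictly below the cutoff
``p`` (default 0.001).  Flagged records are then classified within species:

singleton
    the (position, symbol) combination occurs in exactly one member of its
    species — the pattern enriched at read ends and suspected to be
    PCR/sequencing error;
shared
    the same combination occurs in two or more conspecific sequences — more
    consistent with inherited biological variation.

Sharing requires identity of species AND position AND symbol; two different
rare symbols at one position within one species are two singletons.
Cross-species co-occurrence is ignored.

The "own" pathway flags a query subset against the frequency matrix of a
larger reference library without perturbing it, which is what makes
species-level analyses possible (within a 125-sequence species no frequency
can be below 0.001, but against an 11,000-record library it can).
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field

import numpy as np

from .frequency import FrequencyMatrix, ModalSummary, frequency_matrix, modal_summary
from .seqtable import CANONICAL, SequenceTable

SINGLETON = "singleton"
SHARED = "shared"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class VlfRecord:
    """One flagged variant: who, where, what, how rare, and its class."""

    specimen_id: str
    species_name: str
    position: int  # 1-based alignment position
    symbol: str
    frequency: float
    vlf_class: str = UNCLASSIFIED

    def classified(self, vlf_class: str) -> "VlfRecord":
        return VlfRecord(
            self.specimen_id,
            self.species_name,
            self.position,
            self.symbol,
            self.frequency,
            vlf_class,
        )


@dataclass
class VlfResult:
    """Bundle returned by :func:`vlf_analysis` (and its amino-acid twin).

    The bookkeeping identity
    ``sum(specimen_counts) == sum(position_counts) == singleton + shared ==
    len(vlf_records)`` holds by construction and is re-asserted here.
    """

    alphabet: str
    seqlength: int
    p: float
    modal: ModalSummary
    specimen_counts: "OrderedDict[str, int]"
    position_counts: np.ndarray
    sas: np.ndarray  # (seqlength, 2): singleton, shared counts per position
    vlf_records: list[VlfRecord]
    own_specimen_counts: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    own_position_counts: np.ndarray | None = None
    own_records: list[VlfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = len(self.vlf_records)
        if sum(self.specimen_counts.values()) != total:
            raise AssertionError("specimen tally out of step with record list")
        if int(self.position_counts.sum()) != total:
            raise AssertionError("position tally out of step with record list")
        if int(self.sas.sum()) != total:
            raise AssertionError("singleton/shared tally out of step with record list")
        if not np.array_equal(self.sas.sum(axis=1), self.position_counts):
            raise AssertionError("per-position singleton+shared != position count")

    @property
    def n_singleton(self) -> int:
        return int(self.sas[:, 0].sum())

    @property
    def n_shared(self) -> int:
        return int(self.sas[:, 1].sum())

    @property
    def total(self) -> int:
        return len(self.vlf_records)


def flag_vlfs(
    table: SequenceTable, fmat: FrequencyMatrix, p: float = 0.001
) -> list[VlfRecord]:
    """Flag every canonical residue whose library frequency is < ``p``.

    ``fmat`` need not come from ``table`` itself — passing a reference
    library's matrix with a query table is the "own" pathway.  A symbol
    absent from the matrix altogether (frequency 0) is flagged.
    """
    if table.alphabet != fmat.alphabet:
        raise ValueError("table and frequency matrix alphabets differ")
    if table.seqlength != fmat.seqlength:
        raise ValueError("table and frequency matrix lengths differ")
    if not 0.0 < p < 1.0:
        raise ValueError("cutoff p must lie strictly in (0, 1)")
    symbols = CANONICAL[table.alphabet]
    # map residues to symbol column indices; -1 marks non-canonical
    lut = np.full(128, -1, dtype=np.int8)
    for j, s in enumerate(symbols):
        lut[ord(s)] = j
    codes = lut[table.residues.view(np.uint32).astype(np.int64).clip(0, 127)]
    canonical = codes >= 0
    freq = np.ones_like(codes, dtype=float)
    rows, cols = np.nonzero(canonical)
    freq[rows, cols] = fmat.freqs[cols, codes[rows, cols]]
    hit_r, hit_c = np.nonzero(canonical & (freq < p))
    return [
        VlfRecord(
            table.specimen_ids[r],
            table.species_names[r],
            int(c) + 1,
            str(table.residues[r, c]),
            float(freq[r, c]),
        )
        for r, c in zip(hit_r, hit_c)
    ]


def classify_singleton_shared(
    records: list[VlfRecord], table: SequenceTable
) -> list[VlfRecord]:
    """Assign singleton/shared classes within species.

    A record is shared iff at least two flagged sequences of the same species
    carry the same canonical symbol at the same position; otherwise singleton.
    ``table`` is accepted for interface symmetry (the flagged set already
    carries species labels) and to emphasise that records must originate from
    it.
    """
    key_counts = Counter(
        (rec.species_name, rec.position, rec.symbol) for rec in records
    )
    return [
        rec.classified(
            SHARED
            if key_counts[(rec.species_name, rec.position, rec.symbol)] >= 2
            else SINGLETON
        )
        for rec in records
    ]


def _tally(
    records: list[VlfRecord], specimen_ids: list[str], seqlength: int
) -> tuple["OrderedDict[str, int]", np.ndarray, np.ndarray]:
    spec = OrderedDict((sid, 0) for sid in specimen_ids)
    pos = np.zeros(seqlength, dtype=np.int64)
    sas = np.zeros((seqlength, 2), dtype=np.int64)
    for rec in records:
        spec[rec.specimen_id] += 1
        pos[rec.position - 1] += 1
        sas[rec.position - 1, 0 if rec.vlf_class == SINGLETON else 1] += 1
    return spec, pos, sas


def vlf_analysis(
    table: SequenceTable,
    p: float = 0.001,
    own: SequenceTable | None = None,
    own_classification: str = "own",
) -> VlfResult:
    """Full VLF pipeline: frequencies -> modal summary -> flag -> classify -> tally.

    When ``own`` is supplied its sequences are flagged against the frequency
    matrix of ``table`` only; own records present in the reference contribute
    to the frequencies as reference members, nothing is re-counted.
    ``own_classification`` selects where singleton/shared classes of own
    records are established: ``"own"`` (default) within the own set's species
    labels, ``"reference"`` against conspecific carriers in the reference
    library.
    """
    fmat = frequency_matrix(table)
    modal = modal_summary(fmat, p)
    records = classify_singleton_shared(flag_vlfs(table, fmat, p), table)
    spec, pos, sas = _tally(records, table.specimen_ids, table.seqlength)
    result = VlfResult(
        alphabet=table.alphabet,
        seqlength=table.seqlength,
        p=p,
        modal=modal,
        specimen_counts=spec,
        position_counts=pos,
        sas=sas,
        vlf_records=records,
    )
    if own is not None:
        own_flagged = flag_vlfs(own, fmat, p)
        if own_classification == "own":
            own_classified = classify_singleton_shared(own_flagged, own)
        elif own_classification == "reference":
            own_classified = _classify_against_reference(own_flagged, table)
        else:
            raise ValueError("own_classification must be 'own' or 'reference'")
        ospec, opos, _ = _tally(own_classified, own.specimen_ids, own.seqlength)
        result.own_specimen_counts = ospec
        result.own_position_counts = opos
        result.own_records = own_classified
    return result


def _classify_against_reference(
    records: list[VlfRecord], reference: SequenceTable
) -> list[VlfRecord]:
    """Shared iff >= 2 conspecific reference sequences carry the variant."""
    species = np.asarray(reference.species_names)
    out = []
    for rec in records:
        carriers = int(
            (
                (reference.residues[:, rec.position - 1] == rec.symbol)
                & (species == rec.species_name)
            ).sum()
        )
        out.append(rec.classified(SHARED if carriers >= 2 else SINGLETON))
    return out


def separate_by_species(table: SequenceTable) -> "OrderedDict[str, SequenceTable]":
    """Partition records by exact species name, first-appearance order."""
    groups: "OrderedDict[str, list[int]]" = OrderedDict()
    for i, sp in enumerate(table.species_names):
        groups.setdefault(sp, []).append(i)
    return OrderedDict((sp, table.subset(idx)) for sp, idx in groups.items())


def count_singleton_species(table: SequenceTable) -> int:
    """Number of species names represented by exactly one record."""
    counts = Counter(table.species_names)
    return sum(1 for c in counts.values() if c == 1)
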