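"""Nucleotide/amino-acid concordance at the codon level.

A nucleotide VLF is *concordant* when the same specimen carries an
amino-acid VLF at the codon containing it.  Concordant variants are the ones
most plausibly real at the protein level; a nucleotide VLF whose codon still
translates to a common residue is synonymous noise.  The result also counts
variants that change the physicochemical residue type relative to the modal
residue at that codon — type changes suggest an effect on protein structure
and are a further error signal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import VlfResult
from .frequency import ModalSummary
from .translation import ResidueTypeScheme


@dataclass
class ConcordanceResult:
    """Matched nucleotide/amino-acid VLF pairs and summary counters.

    matched
        one entry per concordant nucleotide VLF:
        (specimen_id, nt position, aa index, codon position 1|2|3).
    codons
        concordant nucleotide VLFs tallied by codon position (3 counts).
    concordNuc / concordAA
        nucleotide VLFs matched / distinct amino-acid VLFs matched by >= 1
        nucleotide VLF (a codon with two nt VLFs gives concordNuc 2,
        concordAA 1).
    concordantType / aminoAcidType
        residue-type changes versus the modal residue, among concordant
        amino-acid VLFs / among all amino-acid VLFs.
    sequences
        specimens carrying at least one nucleotide VLF and at least one
        amino-acid VLF.
    """

    matched: list[tuple[str, int, int, int]]
    codons: tuple[int, int, int]
    concordantType: int
    aminoAcidType: int
    concordNuc: int
    concordAA: int
    sequences: int


def codon_index(nt_position: int) -> tuple[int, int]:
    """Map a 1-based nucleotide position to (aa index, codon position).

    Frame 1 throughout: position 1 is codon position 1 of residue 1, so
    ``aa_index = ceil(i/3)`` and ``codon_position = ((i-1) mod 3) + 1``.
    """
    if nt_position < 1:
        raise ValueError("positions are 1-based")
    return (nt_position + 2) // 3, (nt_position - 1) % 3 + 1


def concordance(
    nt: VlfResult,
    aa: VlfResult,
    aa_modal: ModalSummary | None = None,
    scheme: ResidueTypeScheme | None = None,
) -> ConcordanceResult:
    """Relate nucleotide VLFs to amino-acid VLFs codon by codon.

    ``nt`` and ``aa`` must describe the same specimens with
    ``nt.seqlength == 3 * aa.seqlength``.  ``aa_modal`` defaults to the modal
    summary embedded in ``aa``; residue-type changes are measured against the
    modal residue at the variant's codon (skipped when the modal symbol is
    itself non-canonical, e.g. '*').
    """
    if nt.seqlength != 3 * aa.seqlength:
        raise ValueError(
            f"nucleotide length {nt.seqlength} is not 3 x amino-acid length "
            f"{aa.seqlength}"
        )
    aa_modal = aa_modal or aa.modal
    scheme = scheme or ResidueTypeScheme()

    aa_sites = {(rec.specimen_id, rec.position): rec for rec in aa.vlf_records}
    matched: list[tuple[str, int, int, int]] = []
    codons = [0, 0, 0]
    matched_aa_keys: set[tuple[str, int]] = set()
    for rec in nt.vlf_records:
        idx, cpos = codon_index(rec.position)
        if (rec.specimen_id, idx) in aa_sites:
            matched.append((rec.specimen_id, rec.position, idx, cpos))
            codons[cpos - 1] += 1
            matched_aa_keys.add((rec.specimen_id, idx))

    def type_changed(rec) -> bool:
        modal_sym = str(aa_modal.modal_seq[rec.position - 1])
        if modal_sym not in scheme.classes:
            return False
        return scheme.classes[rec.symbol] != scheme.classes[modal_sym]

    concordant_type = sum(
        1
        for rec in aa.vlf_records
        if (rec.specimen_id, rec.position) in matched_aa_keys and type_changed(rec)
    )
    aa_type = sum(1 for rec in aa.vlf_records if type_changed(rec))
    nt_specimens = {rec.specimen_id for rec in nt.vlf_records}
    aa_specimens = {rec.specimen_id for rec in aa.vlf_records}
    return ConcordanceResult(
        matched=matched,
        codons=tuple(codons),
        concordantType=concordant_type,
        aminoAcidType=aa_type,
        concordNuc=len(matched),
        concordAA=len(matched_aa_keys),
        sequences=len(nt_specimens & aa_specimens),
    )
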