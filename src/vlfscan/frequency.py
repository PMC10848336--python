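"""Positional frequency matrices and modal/conservation summaries.

The frequency matrix is the heart of the method: for every alignment column
it tallies each canonical symbol and divides by the total number of records
``N``.  The denominator is always ``N`` — records carrying a gap or ambiguity
code at a column still count toward the denominator, so canonical frequencies
at such columns sum to less than one.  This makes the cutoff semantics "a
variant rarer than p across the whole library", which is what ties the
default p = 0.001 to the requirement of at least 1000 sequences.

From the matrix we derive the modal (most frequent) and second-modal symbol
per position and three conservation counts:

``con100``
    positions where the modal symbol has frequency exactly 1,
``conp``
    positions where the modal frequency is >= 1 - p,
``combine``
    positions where the top-two frequencies jointly reach >= 1 - p.

Conservation uses >= (1 - p); variant flagging (:mod:`vlfscan.core`) uses a
strict < p.  Ties for the modal symbol are broken alphabetically so every
summary is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqtable import CANONICAL, SequenceTable


@dataclass
class FrequencyMatrix:
    """Per-position canonical symbol counts and relative frequencies.

    ``counts`` and ``freqs`` are ``(seqlength, n_symbols)`` arrays with
    columns ordered as in ``symbols`` (alphabetical).  ``freqs = counts / N``
    exactly, with ``N`` the total record count of the source table.
    """

    alphabet: str
    symbols: str
    N: int
    counts: np.ndarray
    freqs: np.ndarray

    @property
    def seqlength(self) -> int:
        return self.counts.shape[0]

    def symbol_index(self, symbol: str) -> int:
        i = self.symbols.find(symbol)
        if i < 0:
            raise KeyError(f"{symbol!r} is not canonical for {self.alphabet}")
        return i

    def frequency(self, position: int, symbol: str) -> float:
        """Relative frequency of ``symbol`` at 1-based ``position``."""
        return float(self.freqs[position - 1, self.symbol_index(symbol)])


@dataclass
class ModalSummary:
    """Modal/second-modal consensus and conservation counts at cutoff ``p``."""

    modal_seq: np.ndarray
    second_modal_seq: np.ndarray
    con100: int
    conp: int
    combine: int
    p: float


def frequency_matrix(table: SequenceTable) -> FrequencyMatrix:
    """Tally canonical symbols per alignment column of ``table``.

    Non-canonical symbols are excluded from the counts but the denominator
    stays at ``N`` = number of records.
    """
    if table.n_records == 0:
        raise ValueError("cannot build a frequency matrix from an empty table")
    symbols = CANONICAL[table.alphabet]
    counts = np.zeros((table.seqlength, len(symbols)), dtype=np.int64)
    for j, sym in enumerate(symbols):
        counts[:, j] = (table.residues == sym).sum(axis=0)
    freqs = counts / float(table.n_records)
    return FrequencyMatrix(table.alphabet, symbols, table.n_records, counts, freqs)


def modal_summary(fmat: FrequencyMatrix, p: float = 0.001) -> ModalSummary:
    """Modal and second-modal consensus plus con100/conp/combine counts.

    Modal ties are resolved toward the alphabetically earlier symbol;
    ``np.argsort`` with a stable kind on the negated counts guarantees this
    because columns are already in alphabetical order.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("cutoff p must lie strictly in (0, 1)")
    order = np.argsort(-fmat.counts, axis=1, kind="stable")
    syms = np.array(list(fmat.symbols))
    top = order[:, 0]
    second = order[:, 1]
    rows = np.arange(fmat.seqlength)
    f1 = fmat.freqs[rows, top]
    f2 = fmat.freqs[rows, second]
    return ModalSummary(
        modal_seq=syms[top],
        second_modal_seq=syms[second],
        con100=int((f1 == 1.0).sum()),
        conp=int((f1 >= 1.0 - p).sum()),
        combine=int((f1 + f2 >= 1.0 - p).sum()),
        p=p,
    )
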