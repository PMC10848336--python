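"""Per-site and per-barcode error-rate estimation from second codon positions.

Second codon positions are the most conserved sites of a protein-coding
alignment — every substitution there is nonsynonymous — so variants at those
sites are treated as putative machine errors and extrapolated into library
error rates.  With S2/H2 the singleton/shared VLF counts restricted to
second positions, P2 the number of second positions per barcode and N the
number of barcodes:

``plain`` mode (default)::

    singleton = S2 / (P2 * N)
    shared    = H2 / (P2 * N)
    total     = (S2 + H2) / (P2 * N)

``literal`` mode subtracts the opposite class's raw count inside the
denominator::

    singleton = S2 / ((P2 - H2) * N)
    shared    = H2 / ((P2 - S2) * N)
    total     = (S2 + H2) / (P2 * N)

Plain mode is the default because it is additive (total = singleton +
shared) and matches published barcode error-rate tables at their printed
precision; the literal form is retained behind the mode flag.  When the
second-position VLF counts are small relative to P2*N the two modes agree to
well under 1% relative difference.

Per-barcode rates are per-site rates scaled by the barcode length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import UNCLASSIFIED, VlfRecord


@dataclass
class ErrorRateResult:
    """Second-position tallies and the rates derived from them.

    ``per_site`` and ``per_barcode`` are (singleton, shared, total) triples
    in errors/bp and errors/barcode; ``per_barcode = per_site * seqlength``
    exactly.
    """

    S2: int
    H2: int
    V2: int
    N: int
    P2: int
    seqlength: int
    mode: str
    per_site: tuple[float, float, float]
    per_barcode: tuple[float, float, float]


def second_position_tallies(
    records: list[VlfRecord], seqlength: int
) -> tuple[int, int, int]:
    """(singleton, shared, total) VLF counts at second codon positions.

    Second positions are alignment positions ≡ 2 (mod 3) under frame 1.
    Records must be classified.
    """
    s2 = h2 = 0
    for rec in records:
        if rec.vlf_class == UNCLASSIFIED:
            raise ValueError("records must be classified before tallying")
        if rec.position <= seqlength and rec.position % 3 == 2:
            if rec.vlf_class == "singleton":
                s2 += 1
            else:
                h2 += 1
    return s2, h2, s2 + h2


def error_rates(
    S2: int,
    H2: int,
    N: int,
    seqlength: int = 648,
    mode: str = "plain",
    P2: int | None = None,
) -> ErrorRateResult:
    """Compute singleton/shared/total error rates from second-position tallies.

    ``P2`` defaults to the number of second codon positions in a barcode of
    ``seqlength`` nt, ``(seqlength + 1) // 3``; it is overridable because a
    library trimmed to a non-standard length may still be rated against the
    standard 216 second positions.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if P2 is None:
        P2 = (seqlength + 1) // 3
    if mode == "plain":
        denom = P2 * N
        per_site = (S2 / denom, H2 / denom, (S2 + H2) / denom)
    elif mode == "literal":
        if H2 >= P2 or S2 >= P2:
            raise ValueError("literal mode denominator degenerates: counts >= P2")
        per_site = (
            S2 / ((P2 - H2) * N),
            H2 / ((P2 - S2) * N),
            (S2 + H2) / (P2 * N),
        )
    else:
        raise ValueError("mode must be 'plain' or 'literal'")
    per_barcode = tuple(r * seqlength for r in per_site)
    return ErrorRateResult(
        S2=S2,
        H2=H2,
        V2=S2 + H2,
        N=N,
        P2=P2,
        seqlength=seqlength,
        mode=mode,
        per_site=per_site,
        per_barcode=per_barcode,
    )


def error_rates_from_result(result, mode: str = "plain", P2: int | None = None) -> ErrorRateResult:
    """Convenience wrapper: tallies + rates straight from a ``VlfResult``."""
    s2, h2, _ = second_position_tallies(result.vlf_records, result.seqlength)
    n = len(result.specimen_counts)
    return error_rates(s2, h2, n, seqlength=result.seqlength, mode=mode, P2=P2)
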