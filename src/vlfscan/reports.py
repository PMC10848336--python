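"""Tabular (TSV) and JSON report writing for analysis results.

Column layouts are fixed so that downstream parsing is stable:

``vlf_records.tsv``
    specimen_id, species_name, position, symbol, frequency, vlf_class
``specimen_counts.tsv``
    specimen_id, vlf_count
``position_counts.tsv``
    position, vlf_count, singleton, shared
``summary.json``
    machine-readable run summary (full-precision floats).

Floats in TSV reports are printed with 3 significant figures; the JSON twin
keeps full precision.  Written VLF tables round-trip: re-parsing reproduces
the in-memory record list exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .core import VlfRecord, VlfResult
from .concord import ConcordanceResult
from .error_rates import ErrorRateResult

_RECORD_COLUMNS = [
    "specimen_id",
    "species_name",
    "position",
    "symbol",
    "frequency",
    "vlf_class",
]


def records_frame(records: list[VlfRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.astuple(r) for r in records], columns=_RECORD_COLUMNS
    )


def read_records_table(path) -> list[VlfRecord]:
    """Re-parse a written ``vlf_records.tsv`` into record objects."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str, "species_name": str})
    return [
        VlfRecord(
            row.specimen_id,
            row.species_name,
            int(row.position),
            row.symbol,
            float(row.frequency),
            row.vlf_class,
        )
        for row in df.itertuples()
    ]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_reports(result, out_dir) -> list[Path]:
    """Write the result's tables plus a JSON summary into ``out_dir``.

    Accepts a :class:`VlfResult`, :class:`ErrorRateResult` or
    :class:`ConcordanceResult`; returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(result, VlfResult):
        return _write_vlf(result, out)
    if isinstance(result, ErrorRateResult):
        return _write_error_rates(result, out)
    if isinstance(result, ConcordanceResult):
        return _write_concordance(result, out)
    raise TypeError(f"cannot report a {type(result).__name__}")


def _write_vlf(result: VlfResult, out: Path) -> list[Path]:
    paths = []
    p = out / "vlf_records.tsv"
    _write_tsv(records_frame(result.vlf_records), p)
    paths.append(p)

    p = out / "specimen_counts.tsv"
    _write_tsv(
        pd.DataFrame(
            result.specimen_counts.items(), columns=["specimen_id", "vlf_count"]
        ),
        p,
    )
    paths.append(p)

    p = out / "position_counts.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "position": range(1, result.seqlength + 1),
                "vlf_count": result.position_counts,
                "singleton": result.sas[:, 0],
                "shared": result.sas[:, 1],
            }
        ),
        p,
    )
    paths.append(p)

    if result.own_records or result.own_position_counts is not None:
        p = out / "own_vlf_records.tsv"
        _write_tsv(records_frame(result.own_records), p)
        paths.append(p)
        p = out / "own_specimen_counts.tsv"
        _write_tsv(
            pd.DataFrame(
                result.own_specimen_counts.items(),
                columns=["specimen_id", "vlf_count"],
            ),
            p,
        )
        paths.append(p)
        # reduced matrix: only own specimens that actually carry VLFs
        p = out / "own_vlf_reduced.tsv"
        reduced = records_frame(result.own_records)
        _write_tsv(reduced, p)
        paths.append(p)

    summary = {
        "alphabet": result.alphabet,
        "seqlength": result.seqlength,
        "p": result.p,
        "n_records_flagged": result.total,
        "n_singleton": result.n_singleton,
        "n_shared": result.n_shared,
        "con100": result.modal.con100,
        "conp": result.modal.conp,
        "combine": result.modal.combine,
        "modal_sequence": "".join(result.modal.modal_seq),
        "n_own_records_flagged": len(result.own_records),
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2))
    paths.append(p)
    return paths


def _write_error_rates(result: ErrorRateResult, out: Path) -> list[Path]:
    rows = []
    for i, label in enumerate(["singleton", "shared", "total"]):
        rows.append(
            {
                "class": label,
                "per_site": f"{result.per_site[i]:.3g}",
                "per_barcode": f"{result.per_barcode[i]:.3g}",
            }
        )
    p1 = out / "error_rates.tsv"
    pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
    p2 = out / "error_rates.json"
    p2.write_text(json.dumps(dataclasses.asdict(result), indent=2))
    return [p1, p2]


def _write_concordance(result: ConcordanceResult, out: Path) -> list[Path]:
    p1 = out / "concordance_matched.tsv"
    _write_tsv(
        pd.DataFrame(
            result.matched,
            columns=["specimen_id", "nt_position", "aa_index", "codon_position"],
        ),
        p1,
    )
    summary = dataclasses.asdict(result)
    summary.pop("matched")
    p2 = out / "concordance_summary.json"
    p2.write_text(json.dumps(summary, indent=2))
    return [p1, p2]
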