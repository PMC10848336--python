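"""Synthetic aligned barcode libraries with planted rare variants.

The generator builds exactly the structure the VLF statistics measure: a
library of many species (1-125 conspecific records each, geometric-ish sizes
around the ~4.2 specimens/species typical of barcode libraries), a dominant
modal sequence at every position, and *planted* low-frequency variants that
are either unique to one specimen (singleton) or repeated within one species
(shared).  Plant positions can be biased toward the 5'/3' tails, emulating
the end-enrichment of chromatogram errors.  Ambiguity (N) is sprinkled at a
configurable per-cell rate.

Because every departure from the modal sequence is planted deliberately, the
generator can enumerate the exact expected output of the pipeline
(:class:`PlantedTruth`), making end-to-end recovery checkable record by
record.  No substitution-model evolution is simulated: plants are
mechanistic, which is precisely what the frequency statistics respond to.

:func:`brute_force_oracle` is an independent re-implementation of flagging
by plain nested loops; it deliberately shares no counting code with
:mod:`vlfscan.frequency` and exists only as a test oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import SHARED, SINGLETON, VlfRecord
from .seqtable import CANONICAL, NUCLEOTIDE, SequenceTable
from .translation import get_codon_table


@dataclass(frozen=True)
class Plant:
    """One planted variant: ``symbol`` at ``position`` in ``specimens`` of ``species``.

    ``specimens`` are 0-based indices within the species' record block; two
    or more indices make the plant a shared variant by construction.
    """

    position: int
    symbol: str
    species: str
    specimens: tuple[int, ...]


@dataclass
class SimulationSpec:
    """Recipe for one synthetic library.

    Defaults describe a realistic reference library: 700 species with
    geometric size distribution truncated at 125 (N ≈ 2900 records), 648 bp
    alignments, cutoff p = 0.001, a light 0.1% ambiguity load.  ``plants``
    may be given explicitly or left None to be sampled via
    :func:`sample_plants` using ``n_singleton``/``n_shared``/``end_bias``.
    """

    seed: int = 0
    n_species: int = 700
    specimens_per_species: list[int] | int | None = None
    seqlength: int = 648
    alphabet: str = NUCLEOTIDE
    p: float = 0.001
    plants: list[Plant] | None = None
    n_singleton: int = 40
    n_shared: int = 15
    ambiguity_rate: float = 0.001
    end_bias: float = 0.5
    mean_specimens: float = 4.2
    max_specimens: int = 125


@dataclass
class PlantedTruth:
    """Ground truth the pipeline must recover exactly."""

    records: list[VlfRecord]
    specimen_counts: dict[str, int] = field(default_factory=dict)
    position_counts: np.ndarray | None = None


def _species_sizes(spec: SimulationSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.specimens_per_species, int):
        return [spec.specimens_per_species] * spec.n_species
    if spec.specimens_per_species is not None:
        return list(spec.specimens_per_species)
    sizes = rng.geometric(1.0 / spec.mean_specimens, size=spec.n_species)
    return [int(min(s, spec.max_specimens)) for s in sizes]


def _modal_sequence(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Background consensus; for nucleotides, built from sense codons so the
    translated modal sequence is stop-free under the vertebrate mito code."""
    if spec.alphabet != NUCLEOTIDE:
        return rng.choice(list(CANONICAL[spec.alphabet]), size=spec.seqlength)
    tab = get_codon_table("vertebrate_mitochondrial")
    sense = sorted(tab.forward_table)
    n_codons = spec.seqlength // 3
    codons = rng.choice(sense, size=n_codons)
    seq = list("".join(codons))
    # a trailing partial codon is padded with A's (still canonical)
    seq += ["A"] * (spec.seqlength - 3 * n_codons)
    return np.array(seq, dtype="<U1")


def sample_plants(
    spec: SimulationSpec,
    sizes: list[int],
    modal: np.ndarray,
    rng: np.random.Generator,
) -> list[Plant]:
    """Draw singleton and shared plants at distinct positions.

    With probability ``end_bias`` a plant's position falls in the outer 10%
    tails of the alignment, else anywhere — mimicking end-of-read error
    enrichment.  Positions are kept distinct across plants so each plant's
    library frequency is exactly its own carrier count / N.
    """
    L = spec.seqlength
    n_total = spec.n_singleton + spec.n_shared
    if n_total > L:
        raise ValueError("more plants requested than alignment positions")
    tail = max(1, L // 10)
    tail_positions = list(range(1, tail + 1)) + list(range(L - tail + 1, L + 1))
    positions: list[int] = []
    used: set[int] = set()
    while len(positions) < n_total:
        if rng.random() < spec.end_bias:
            pos = int(rng.choice(tail_positions))
        else:
            pos = int(rng.integers(1, L + 1))
        if pos not in used:
            used.add(pos)
            positions.append(pos)
    species_names = [f"Species {i:04d}" for i in range(len(sizes))]
    multi = [i for i, s in enumerate(sizes) if s >= 2]
    if spec.n_shared and not multi:
        raise ValueError("shared plants need at least one species with >= 2 records")
    plants: list[Plant] = []
    symbols = CANONICAL[spec.alphabet]
    for k, pos in enumerate(positions):
        alt = rng.choice([s for s in symbols if s != modal[pos - 1]])
        if k < spec.n_singleton:
            sp = int(rng.integers(0, len(sizes)))
            carriers = (int(rng.integers(0, sizes[sp])),)
        else:
            sp = int(rng.choice(multi))
            pair = rng.choice(sizes[sp], size=2, replace=False)
            carriers = tuple(int(x) for x in sorted(pair))
        plants.append(Plant(pos, str(alt), species_names[sp], carriers))
    return plants


def simulate_alignment(spec: SimulationSpec) -> tuple[SequenceTable, PlantedTruth]:
    """Build the synthetic table and its exact expected VLF output.

    Deterministic under ``spec.seed``.  Raises if any plant's library
    frequency would reach the cutoff (an infeasible plant would not be
    flagged, so the truth would be wrong by construction).
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _species_sizes(spec, rng)
    modal = _modal_sequence(spec, rng)
    N = sum(sizes)
    species_names = [f"Species {i:04d}" for i in range(len(sizes))]

    plants = spec.plants
    if plants is None:
        plants = sample_plants(spec, sizes, modal, rng)

    # species block offsets into the record axis
    offsets = np.cumsum([0] + sizes[:-1]).tolist()
    sp_index = {name: i for i, name in enumerate(species_names)}

    # feasibility: each (position, symbol) must stay under the cutoff
    carriers_at: Counter = Counter()
    for plant in plants:
        if not 1 <= plant.position <= spec.seqlength:
            raise ValueError(f"plant position {plant.position} outside alignment")
        if plant.symbol == modal[plant.position - 1]:
            raise ValueError(
                f"plant at {plant.position} uses the modal symbol {plant.symbol!r}"
            )
        carriers_at[(plant.position, plant.symbol)] += len(plant.specimens)
    for (pos, sym), k in carriers_at.items():
        if k / N >= spec.p:
            raise ValueError(
                f"infeasible plant: {sym!r}@{pos} carried by {k}/{N} records "
                f"(frequency {k / N:.2e} >= cutoff {spec.p})"
            )

    residues = np.tile(modal, (N, 1))
    specimen_ids = [f"SIM{r:06d}" for r in range(N)]
    record_species = [
        species_names[i] for i, size in enumerate(sizes) for _ in range(size)
    ]

    planted_cells: set[tuple[int, int]] = set()
    truth_records: list[VlfRecord] = []
    # class by the within-species rule applied to the merged plant list
    class_counts: Counter = Counter()
    for plant in plants:
        class_counts[(plant.species, plant.position, plant.symbol)] += len(
            plant.specimens
        )
    for plant in plants:
        base = offsets[sp_index[plant.species]]
        n_conspecific = class_counts[(plant.species, plant.position, plant.symbol)]
        cls = SHARED if n_conspecific >= 2 else SINGLETON
        for idx in plant.specimens:
            if idx >= sizes[sp_index[plant.species]]:
                raise ValueError(
                    f"plant specimen index {idx} exceeds species size for "
                    f"{plant.species}"
                )
            row = base + idx
            residues[row, plant.position - 1] = plant.symbol
            planted_cells.add((row, plant.position - 1))
            truth_records.append(
                VlfRecord(
                    specimen_ids[row],
                    plant.species,
                    plant.position,
                    plant.symbol,
                    carriers_at[(plant.position, plant.symbol)] / N,
                    cls,
                )
            )

    if spec.ambiguity_rate > 0:
        noise = rng.random((N, spec.seqlength)) < spec.ambiguity_rate
        for r, c in zip(*np.nonzero(noise)):
            if (int(r), int(c)) not in planted_cells:
                residues[r, c] = "N"

    table = SequenceTable(spec.alphabet, specimen_ids, record_species, residues)
    pos_counts = np.zeros(spec.seqlength, dtype=np.int64)
    spec_counts = {sid: 0 for sid in specimen_ids}
    for rec in truth_records:
        pos_counts[rec.position - 1] += 1
        spec_counts[rec.specimen_id] += 1
    truth = PlantedTruth(
        records=sorted(truth_records, key=lambda r: (r.specimen_id, r.position)),
        specimen_counts=spec_counts,
        position_counts=pos_counts,
    )
    return table, truth


def brute_force_oracle(table: SequenceTable, p: float = 0.001) -> list[VlfRecord]:
    """Naive O(N·L·|Σ|) reference flagging, used only as a test oracle.

    Counts symbols with plain Python dictionaries, position by position, and
    flags by the same strict < p rule.  Shares no code with the production
    frequency engine.
    """
    canonical = set(CANONICAL[table.alphabet])
    n = table.n_records
    out: list[VlfRecord] = []
    for col in range(table.seqlength):
        tally: dict[str, int] = {}
        for row in range(n):
            ch = str(table.residues[row, col])
            if ch in canonical:
                tally[ch] = tally.get(ch, 0) + 1
        for row in range(n):
            ch = str(table.residues[row, col])
            if ch in canonical and tally[ch] / n < p:
                out.append(
                    VlfRecord(
                        table.specimen_ids[row],
                        table.species_names[row],
                        col + 1,
                        ch,
                        tally[ch] / n,
                    )
                )
    return out


def random_table(
    seed: int,
    n_records: int = 60,
    seqlength: int = 30,
    n_species: int = 12,
    alphabet: str = NUCLEOTIDE,
    skew: float = 6.0,
) -> SequenceTable:
    """Small fully random table (no planted structure) for oracle comparisons.

    ``skew`` biases draws toward the first symbol so that columns have a
    dominant base with occasional rare variants, plus a sprinkle of N's.
    """
    rng = np.random.default_rng(seed)
    symbols = list(CANONICAL[alphabet]) + ["N", "-"]
    w = np.ones(len(symbols))
    w[0] = skew
    w[-2:] = 0.15
    w /= w.sum()
    residues = rng.choice(symbols, size=(n_records, seqlength), p=w)
    species = [f"Sp {rng.integers(0, n_species):03d}" for _ in range(n_records)]
    ids = [f"R{r:05d}" for r in range(n_records)]
    return SequenceTable(alphabet, ids, species, residues)
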