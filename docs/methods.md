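# Methods

## Model and assumptions

The method treats an aligned library of protein-coding sequences as a
column-independent frequency model. For each alignment column *i* and
canonical symbol *s*, the statistic of interest is the relative frequency
*f<sub>i</sub>(s) = count<sub>i</sub>(s)/N*, with *N* the number of records
in the library. A residue is a very-low-frequency variant (VLF) when its
frequency is **strictly below** the cutoff *p*. All higher-level outputs —
singleton/shared classes, tallies, error rates, profiles, sweeps — are
deterministic functions of the per-column counts.

Assumptions inherited from the barcode setting:

- sequences are aligned, equal-length, and indel-free within the analysed
  block; alignment itself is upstream (MUSCLE/MAFFT/MEGA or similar) and is
  only *validated* here (length uniformity, ambiguity load, in-frame stop
  codons);
- position 1 of the alignment is codon position 1 of the reading frame;
  second codon positions are therefore columns ≡ 2 (mod 3);
- the library is large: with *p* = 0.001 a variant can only fall below the
  cutoff when *N* > 1000, and the method is designed for libraries of
  thousands of records;
- species labels are exact strings; no synonym reconciliation is attempted
  (species name differences are a documented source of count discrepancies
  between implementations of this method, and resolving them is a taxonomy
  problem, not a statistics problem).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `p` | 0.001 | VLF cutoff frequency; "one error per 1000 positions". Conservation thresholds use ≥ 1 − p; flagging uses < p, strictly. |
| `seqlength` | 648 nt / 216 aa | standard animal barcode length; any length is accepted |
| `pos1`, `pos2` | 1, 3 | '|'-delimited FASTA header fields holding specimen id and species |
| `codon_table` | vertebrate_mitochondrial | NCBI tables 1 (standard), 2 (vertebrate mito), 5 (invertebrate mito) |
| `P2` | ⌊(seqlength+1)/3⌋ | second codon positions per barcode (216 at 648 bp); overridable so a library trimmed to a non-standard length (e.g. 652 bp for fishes) can still be rated against 216 second positions |
| window `n` | 30 bp | sliding-window size, step fixed at 1 bp |
| error-rate `mode` | plain | see below |

## Numerical and semantic choices

- **Denominator is always N.** Records with gaps/ambiguity at a column
  still count toward the denominator, so canonical frequencies at such
  columns sum to < 1. This keeps the cutoff meaning "rarer than p in the
  library", independent of per-column coverage.
- **Boundary semantics.** A variant at frequency exactly *p* (e.g. 1 carrier
  in 1000 records at p = 0.001) is *not* flagged; conservation counts use
  the inclusive complement (modal frequency ≥ 1 − p counts toward `conp`).
- **Ties** for the modal/second-modal symbol break alphabetically, making
  every summary deterministic.
- **`combine`** counts positions where the top-two frequencies *jointly*
  reach 1 − p. The alternative reading (either variant alone passes) is
  subsumed by `conp`; both totals appear in every report so the distinction
  is visible.
- **Sharing** requires identity of species AND position AND symbol. Two
  different rare symbols at one position in one species are two singletons —
  a shared variant is the *same* inherited allele, not any co-occurring
  rarity.
- **Own-sequence analysis** flags queries against the reference library's
  frequency matrix without re-counting; if the queries also exist in the
  reference they contribute to frequencies as reference members only.
  Singleton/shared classification of own records defaults to the own set's
  own labels (`own_classification="own"`); classification against the
  reference's conspecific carriers is selectable (`"reference"`). The two
  differ exactly when a query is alone in the own set but its variant has
  conspecific carriers in the reference.
- **Translation** resolves IUPAC ambiguity codes: a codon containing
  ambiguity translates normally when every resolution agrees (CTN → L),
  otherwise to 'X'. In-frame stops render '*'. Both 'X' and '*' are
  non-canonical: excluded from frequency numerators and never flagged —
  stop codons signal NUMTs/frame errors and are surfaced by validation
  instead.
- **Error-rate modes.** `plain` divides second-position counts by P2·N and
  is additive (total = singleton + shared). `literal` subtracts the
  opposite class's raw count from P2 inside the denominator, which breaks
  additivity and only agrees with `plain` when S2, H2 ≪ P2. Published
  barcode error-rate tables are reproduced by the plain form at their
  printed precision, so plain is the default; the literal form is kept
  behind the flag for fidelity to the displayed formulae.
- **Decile bins** use real-valued cut points (bin *k* covers (k−1)·L/10 < i
  ≤ k·L/10), so for L = 648 bins alternate between 64 and 65 positions.
- **Sliding-window statistic** is the per-site mean (window sum / n),
  reported separately for singleton and shared classes.
- **Trim sweeps** exploit column independence: per-column frequencies do not
  change when other columns are removed, so trimming is column deletion and
  remaining + removed = untrimmed exactly. A full-recompute mode exists
  solely to cross-check this identity and must (and does, in tests) give
  identical numbers.
- **Degenerate inputs.** Empty tables, cutoffs outside (0, 1), oversized
  windows, trims that leave nothing, and literal-mode denominators ≤ 0 are
  rejected with errors before any computation.

## Synthetic data generator

`vlfscan.simulate` builds libraries with exactly the structure the
statistics measure: many species with geometric size distribution (mean 4.2
specimens/species, truncated at 125 — the shape of real barcode libraries),
a single modal sequence built from mitochondrial sense codons (so its
translation is stop-free), and *planted* variants that are singleton (one
carrier) or shared (two carriers within one species) by construction.
Plant positions are biased toward the outer 10% tails of the alignment with
probability `end_bias` (default 0.5), emulating end-of-read error
enrichment; ambiguity (N) is sprinkled at `ambiguity_rate` (default 0.001
per cell, matching the <1% ambiguity requirement of curated barcode
records). The default 700 species (N ≈ 2900) keeps every 2-carrier plant
safely below the 0.001 cutoff while staying small enough for sub-second
analysis.

The generator refuses infeasible plants (frequency ≥ p) and emits the exact
expected pipeline output (`PlantedTruth`), so end-to-end recovery is checked
record by record, class by class.

What it deliberately does **not** emulate: substitution-model evolution
(no K2P/GTR), within-species haplotype structure, indels, NUMT chimeras, or
correlated errors. Passing tests therefore demonstrate that the statistics
compute what they claim on data with known truth — not that singleton VLFs
in real libraries *are* machine errors; that interpretation rests on the
biology (second-position conservation, end-of-read chromatogram decay), and
real variants of biological origin will be flagged whenever a species is
undersampled.

The brute-force oracle is an independent pure-Python recount (nested loops
and dicts) sharing no code with the vectorised engine; it exists only as a
test oracle.

## Problem sizes

Tests and the acceptance script run on simulated libraries of roughly
2,000–3,000 records at 90–648 bp and on 100 random 20–120 × 5–40 tables for
oracle comparison; a full 648 bp analysis of ~3000 records completes in well
under a second, and an 11,000-record library takes a few seconds.

## Known limitations

- Frequencies are library-wide; strongly structured libraries (deep
  intraspecific divergence, heavy sampling imbalance) blur the
  error/variation boundary, and the singleton/shared split only partially
  compensates.
- No confidence intervals on error rates.
- Whether a flagged variant is truly an artifact is not decidable from the
  alignment alone; trace-file inspection remains the ground truth, and this
  package only prioritises what to inspect.
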