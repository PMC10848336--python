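import numpy as np
import pytest

from vlfscan.core import (
    SHARED,
    SINGLETON,
    classify_singleton_shared,
    count_singleton_species,
    flag_vlfs,
    separate_by_species,
    vlf_analysis,
)
from vlfscan.frequency import frequency_matrix

from conftest import make_table, one_variant_table, uniform_table


def _key(rec):
    return (rec.specimen_id, rec.position, rec.symbol)


class TestFlagVlfs:
    def test_rare_variant_flagged(self):
        table = one_variant_table(2000, "AAAAA", 0, 5, "C")
        records = flag_vlfs(table, frequency_matrix(table), p=0.001)
        assert len(records) == 1
        rec = records[0]
        assert (rec.position, rec.symbol) == (5, "C")
        assert rec.frequency == pytest.approx(0.0005)

    def test_boundary_frequency_not_flagged(self):
        # 1 variant in 1000 records: frequency exactly p, strict < applies
        table = one_variant_table(1000, "AAAAA", 0, 5, "C")
        assert flag_vlfs(table, frequency_matrix(table), p=0.001) == []

    def test_all_identical_empty(self):
        table = uniform_table(50, "ACGTACGT")
        assert flag_vlfs(table, frequency_matrix(table), p=0.001) == []

    def test_non_canonical_never_flagged(self):
        table = one_variant_table(2000, "AAAAA", 0, 5, "N")
        assert flag_vlfs(table, frequency_matrix(table), p=0.001) == []

    def test_symbol_absent_from_matrix_is_flagged(self):
        # query residue never seen in the reference: frequency 0 < p
        ref = uniform_table(2000, "AAAAA")
        own = make_table([("Q1", "Sp q", "AACAA")])
        records = flag_vlfs(own, frequency_matrix(ref), p=0.001)
        assert len(records) == 1
        assert records[0].frequency == 0.0

    def test_alphabet_mismatch_rejected(self):
        nt = uniform_table(5, "ACGT")
        aa = uniform_table(5, "MKLV", alphabet="amino-acid")
        with pytest.raises(ValueError):
            flag_vlfs(aa, frequency_matrix(nt), p=0.001)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(42)
        from vlfscan.simulate import random_table

        table = random_table(7, n_records=200, seqlength=25)
        grids = [0.005, 0.02, 0.05, 0.2]
        fmat = frequency_matrix(table)
        sets = [
            {_key(r) for r in flag_vlfs(table, fmat, p)} for p in grids
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestClassification:
    def test_conspecific_pair_is_shared(self):
        rows = [(f"S{i}", "Sp one", "AAAAA") for i in range(3000)]
        rows[0] = ("S0", "Sp one", "AACAA")
        rows[1] = ("S1", "Sp one", "AACAA")
        table = make_table(rows)
        records = classify_singleton_shared(
            flag_vlfs(table, frequency_matrix(table), p=0.001), table
        )
        assert len(records) == 2
        assert all(r.vlf_class == SHARED for r in records)

    def test_cross_species_pair_stays_singleton(self):
        rows = [(f"S{i}", f"Sp {i % 100}", "AAAAA") for i in range(3000)]
        rows[0] = ("S0", "Sp A", "AACAA")
        rows[1] = ("S1", "Sp B", "AACAA")
        table = make_table(rows)
        records = classify_singleton_shared(
            flag_vlfs(table, frequency_matrix(table), p=0.001), table
        )
        assert len(records) == 2
        assert all(r.vlf_class == SINGLETON for r in records)

    def test_different_symbols_are_two_singletons(self):
        rows = [(f"S{i}", "Sp one", "AAAAA") for i in range(3000)]
        rows[0] = ("S0", "Sp one", "AACAA")
        rows[1] = ("S1", "Sp one", "AAGAA")
        table = make_table(rows)
        records = classify_singleton_shared(
            flag_vlfs(table, frequency_matrix(table), p=0.001), table
        )
        assert sorted(r.vlf_class for r in records) == [SINGLETON, SINGLETON]

    def test_empty_in_empty_out(self):
        table = uniform_table(5, "ACGT")
        assert classify_singleton_shared([], table) == []


class TestVlfAnalysis:
    def test_bookkeeping_identity(self):
        from vlfscan.simulate import SimulationSpec, simulate_alignment

        table, _ = simulate_alignment(SimulationSpec(seed=3))
        result = vlf_analysis(table, p=0.001)
        assert (
            sum(result.specimen_counts.values())
            == int(result.position_counts.sum())
            == result.n_singleton + result.n_shared
            == result.total
        )

    def test_own_identical_to_modal_has_no_vlfs(self):
        ref = one_variant_table(2000, "ACGTACGTA", 0, 5, "G")
        own = make_table([("Q1", "Sp q", "ACGTACGTA")])
        result = vlf_analysis(ref, p=0.001, own=own)
        assert result.own_records == []
        assert sum(result.own_specimen_counts.values()) == 0

    def test_own_flagged_against_reference_matrix_only(self):
        # a variant common within the own set but absent from the reference
        ref = uniform_table(2000, "AAAAA")
        own = make_table([(f"Q{i}", "Sp q", "AACAA") for i in range(5)])
        result = vlf_analysis(ref, p=0.001, own=own)
        assert len(result.own_records) == 5
        assert all(r.frequency == 0.0 for r in result.own_records)
        # classified within the own set: five conspecific carriers -> shared
        assert all(r.vlf_class == SHARED for r in result.own_records)

    def test_own_reference_classification_mode(self):
        rows = [(f"S{i}", "Sp big", "AAAAA") for i in range(4000)]
        rows[0] = ("S0", "Sp big", "AACAA")
        rows[1] = ("S1", "Sp big", "AACAA")
        ref = make_table(rows)
        own = make_table([("S0", "Sp big", "AACAA")])
        within = vlf_analysis(ref, p=0.001, own=own, own_classification="own")
        against = vlf_analysis(ref, p=0.001, own=own, own_classification="reference")
        # alone in the own set -> singleton; two reference conspecifics -> shared
        assert within.own_records[0].vlf_class == SINGLETON
        assert against.own_records[0].vlf_class == SHARED

    def test_own_does_not_change_reference_result(self):
        ref = one_variant_table(2000, "ACGTACGTA", 0, 5, "G")
        own = make_table([("Q1", "Sp q", "ACCTACGTA")])
        with_own = vlf_analysis(ref, p=0.001, own=own)
        without = vlf_analysis(ref, p=0.001)
        assert with_own.vlf_records == without.vlf_records
        assert np.array_equal(with_own.position_counts, without.position_counts)


class TestSpeciesUtilities:
    def test_separate_preserves_partition(self):
        rows = (
            [("A1", "Sp a", "ACGT"), ("A2", "Sp a", "ACGT")]
            + [("B1", "Sp b", "ACGT")]
            + [(f"C{i}", "Sp c", "ACGT") for i in range(4)]
        )
        parts = separate_by_species(make_table(rows))
        assert [t.n_records for t in parts.values()] == [2, 1, 4]
        assert list(parts) == ["Sp a", "Sp b", "Sp c"]  # first-appearance order
        assert sum(t.n_records for t in parts.values()) == 7

    def test_separate_single_species_identity(self):
        table = uniform_table(3, "ACGT")
        parts = separate_by_species(table)
        assert len(parts) == 1
        only = next(iter(parts.values()))
        assert only.specimen_ids == table.specimen_ids

    def test_count_singleton_species(self):
        rows = [
            ("S1", "Sp a", "ACGT"),
            ("S2", "Sp b", "ACGT"),
            ("S3", "Sp c", "ACGT"),
            ("S4", "Sp c", "ACGT"),
        ]
        assert count_singleton_species(make_table(rows)) == 2
        rows = [("S1", "Sp a", "ACGT"), ("S2", "Sp a", "ACGT")]
        assert count_singleton_species(make_table(rows)) == 0
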