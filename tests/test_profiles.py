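import numpy as np
import pytest

from vlfscan.core import vlf_analysis
from vlfscan.profiles import (
    cutoff_sweep,
    decile_profile,
    render_plots,
    sliding_window,
    trim_sweep,
)
from vlfscan.simulate import SimulationSpec, simulate_alignment

from conftest import make_table, one_variant_table, uniform_table


@pytest.fixture(scope="module")
def sim_result():
    table, _ = simulate_alignment(
        SimulationSpec(seed=11, n_species=700, seqlength=90, n_singleton=12,
                       n_shared=6)
    )
    return table, vlf_analysis(table, p=0.001)


class TestDecileProfile:
    def test_zero_counts(self):
        result = vlf_analysis(uniform_table(10, "A" * 20), p=0.001)
        assert decile_profile(result).bins.sum() == 0

    def test_unit_counts_per_position(self):
        # L = 10: one position per decile, one VLF at each position
        rows = [(f"S{i:05d}", "Sp one", "A" * 10) for i in range(2000)]
        for j in range(10):
            sid, sp, seq = rows[j]
            s = list("A" * 10)
            s[j] = "C"
            rows[j] = (sid, sp, "".join(s))
        result = vlf_analysis(make_table(rows), p=0.001)
        profile = decile_profile(result)
        assert (profile.totals == 1).all()

    def test_totals_match_position_counts(self, sim_result):
        _, result = sim_result
        profile = decile_profile(result)
        assert profile.totals.sum() == result.position_counts.sum()
        assert profile.bins[:, 0].sum() == result.n_singleton
        assert profile.bins[:, 1].sum() == result.n_shared

    def test_real_valued_boundaries_for_648(self):
        # position 145 falls in decile 3: 2*64.8 = 129.6 < 145 <= 194.4
        from vlfscan.profiles import _decile_bin

        assert _decile_bin(145, 648) == 2
        assert _decile_bin(147, 648) == 2
        assert _decile_bin(190, 648) == 2
        assert _decile_bin(129, 648) == 1
        assert _decile_bin(195, 648) == 3


class TestSlidingWindow:
    def test_zero_counts(self):
        result = vlf_analysis(uniform_table(10, "A" * 40), p=0.001)
        win = sliding_window(result, n=30)
        assert (win.total == 0).all()
        assert len(win.starts) == 11

    def test_single_position_cluster(self):
        # count 3 at position 35 of 40: windows starting 6..11 cover it
        rows = [(f"S{i:05d}", "Sp one", "A" * 40) for i in range(4000)]
        for j in range(3):
            sid, sp, seq = rows[j]
            s = list(seq)
            s[34] = "C"
            rows[j] = (sid, sp, "".join(s))
        result = vlf_analysis(make_table(rows), p=0.001)
        win = sliding_window(result, n=30)
        expected = np.zeros(11)
        expected[5:11] = 3 / 30
        assert np.allclose(win.total, expected)

    def test_window_values_match_direct_recomputation(self, sim_result):
        _, result = sim_result
        win = sliding_window(result, n=30)
        for k, start in enumerate(win.starts):
            direct = result.position_counts[start - 1 : start - 1 + 30].sum() / 30
            assert win.total[k] == pytest.approx(direct)

    def test_oversized_window_rejected(self):
        result = vlf_analysis(uniform_table(5, "A" * 10), p=0.001)
        with pytest.raises(ValueError):
            sliding_window(result, n=11)


class TestTrimSweep:
    def test_no_trim_is_identity(self, sim_result):
        table, result = sim_result
        surf = trim_sweep(table, [0], [0], p=0.001)
        s, h, tot, removed = surf.cells[0, 0]
        assert (s, h, tot, removed) == (
            result.n_singleton,
            result.n_shared,
            result.total,
            0,
        )

    def test_conservation_identity(self, sim_result):
        table, result = sim_result
        surf = trim_sweep(table, [0, 5, 10, 20], [0, 5, 10, 20], p=0.001)
        assert (surf.cells[:, :, 2] + surf.cells[:, :, 3] == result.total).all()

    def test_monotone_in_each_axis(self, sim_result):
        table, _ = sim_result
        surf = trim_sweep(table, [0, 10, 20, 30], [0, 10, 20, 30], p=0.001)
        totals = surf.cells[:, :, 2]
        assert (np.diff(totals, axis=0) <= 0).all()
        assert (np.diff(totals, axis=1) <= 0).all()

    def test_fast_equals_full_recompute(self, sim_result):
        table, _ = sim_result
        fast = trim_sweep(table, [0, 7, 15], [0, 7], p=0.001)
        slow = trim_sweep(table, [0, 7, 15], [0, 7], p=0.001, recompute=True)
        assert np.array_equal(fast.cells[:, :, :3], slow.cells[:, :, :3])

    def test_degenerate_trim_rejected(self):
        table = uniform_table(5, "A" * 10)
        with pytest.raises(ValueError):
            trim_sweep(table, [5], [5], p=0.001)


class TestCutoffSweep:
    def test_p_below_reciprocal_n_gives_zero(self, sim_result):
        table, _ = sim_result
        surf = cutoff_sweep(table, [0.5 / table.n_records])
        assert surf.cells[0, 0, 2] == 0

    def test_totals_monotone_in_p(self, sim_result):
        table, _ = sim_result
        surf = cutoff_sweep(table, [0.0001, 0.001, 0.002, 0.005])
        totals = surf.cells[:, 0, 2]
        assert (np.diff(totals) >= 0).all()

    def test_default_cutoff_consistent_with_standard_run(self, sim_result):
        table, result = sim_result
        surf = cutoff_sweep(table, [0.001])
        assert surf.cells[0, 0, 2] == result.total

    def test_invalid_cutoff_rejected(self):
        table = uniform_table(5, "ACGT")
        with pytest.raises(ValueError):
            cutoff_sweep(table, [0.0])


class TestRenderPlots:
    def test_smoke_all_profiles(self, sim_result, tmp_path):
        table, result = sim_result
        targets = [
            (decile_profile(result), tmp_path / "dec.png"),
            (sliding_window(result, 30), tmp_path / "win.png"),
            (trim_sweep(table, [0, 5], [0, 5], p=0.001), tmp_path / "trim.png"),
            (cutoff_sweep(table, [0.001, 0.005]), tmp_path / "cut.png"),
        ]
        for profile, path in targets:
            render_plots(profile, path)
            assert path.exists() and path.stat().st_size > 0
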