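from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from askpoly import (HaplotypeAlignment, assign_expression_groups,
                     assign_latitude_groups, compare_window_profiles,
                     group_mean_comparison, nucleotide_diversity,
                     simulate_structured_region, sliding_window_diversity,
                     wilcoxon_rank_sum)
from askpoly.windows import GroupAssignment, window_offsets


class TestWindowDefinitions:
    def test_2500bp_region_yields_24_windows(self):
        offs = window_offsets(2500, 200, 100)
        assert len(offs) == 24
        assert offs[0] == (-2500, -2301)
        assert offs[-1] == (-200, -1)

    @pytest.mark.parametrize("L,window,step", [(1000, 200, 100), (730, 150, 40)])
    def test_window_count_formula(self, L, window, step):
        assert len(window_offsets(L, window, step)) == (L - window) // step + 1

    def test_window_larger_than_region_rejected(self):
        with pytest.raises(ValueError):
            window_offsets(100, 200, 100)

    def test_single_window_equals_whole_region_pi(self):
        _, aln, _ = simulate_structured_region(8, [(300, 0.02)], seed=2)
        profile = sliding_window_diversity(aln, window=300, step=300)
        assert len(profile.pi_site) == 1
        assert profile.pi_site[0] == pytest.approx(nucleotide_diversity(aln)[1])

    def test_diversity_confined_to_planted_band(self):
        segments = [(900, 0.0), (1100, 0.05), (500, 0.0)]  # -1600..-500 hot
        _, aln, _ = simulate_structured_region(12, segments, seed=6)
        profile = sliding_window_diversity(aln, 200, 100)
        for (start, end), pi in zip(profile.windows, profile.pi_site):
            overlaps_band = start <= -500 - 1 and end >= -1600
            if not overlaps_band:
                assert pi == 0.0
        in_band = [pi for (s, e), pi in zip(profile.windows, profile.pi_site)
                   if s >= -1600 and e <= -500]
        assert np.mean(in_band) > 0

    def test_mean_of_tiling_windows_equals_region_pi(self):
        _, aln, _ = simulate_structured_region(6, [(1000, 0.03)], seed=9)
        profile = sliding_window_diversity(aln, window=200, step=200)
        region_pi = nucleotide_diversity(aln)[1]
        assert np.mean(profile.pi_site) == pytest.approx(region_pi)


class TestGrouping:
    def _meta(self, lats):
        return pd.DataFrame({"latitude": lats},
                            index=[f"a{i}" for i in range(len(lats))])

    def test_latitude_bin_conventions(self):
        meta = self._meta([44.9, 45.0, 39.0, 60.0, 50.0, 61.2])
        g = assign_latitude_groups(meta)
        assert g.mapping["a0"] == "40-45"
        assert g.mapping["a1"] == "45-50"     # left-closed boundary
        assert "a2" not in g.mapping          # below all bins
        assert g.mapping["a3"] == "50-60"     # closed top of last bin
        assert g.mapping["a4"] == "50-60"
        assert "a5" not in g.mapping

    def test_expression_group_conventions(self):
        row = pd.Series({"a0": 100.0, "a1": 137.0, "a2": 480.0, "a3": 30.0,
                         "a4": 170.0, "a5": 169.9})
        g = assign_expression_groups(row)
        assert g.mapping["a0"] == "low"
        assert g.mapping["a1"] == "medium"    # half-open boundary
        assert g.mapping["a2"] == "high"      # closed top of range
        assert "a3" not in g.mapping
        assert g.mapping["a4"] == "high"
        assert g.mapping["a5"] == "medium"


def _exact_rank_sum_oracle(x, y, alternative):
    """Full-enumeration Mann-Whitney p-value for tie-free samples."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    if alternative == "less":
        return float((us <= u_obs).mean())
    if alternative == "greater":
        return float((us >= u_obs).mean())
    p_less = (us <= u_obs).mean()
    p_greater = (us >= u_obs).mean()
    return float(min(1.0, 2 * min(p_less, p_greater)))


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_rank_sum(x, x.copy(), "two-sided")[1] == 1.0

    def test_worked_example_one_sided(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less")
        assert p == pytest.approx(1 / 20)

    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_matches_enumeration_for_small_no_tie_samples(self, alternative):
        rng = np.random.default_rng(23)
        for _ in range(20):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = pooled[:nx], pooled[nx:]
            _, p = wilcoxon_rank_sum(x, y, alternative)
            assert p == pytest.approx(_exact_rank_sum_oracle(x, y, alternative),
                                      abs=1e-12)

    def test_tied_samples_use_corrected_normal_approximation(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [2.0, 3.0, 3.0, 4.0, 5.0, 6.0]
        _, p = wilcoxon_rank_sum(x, y, "two-sided")
        assert 0 < p < 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareWindowProfiles:
    def _alignments(self, focal_hot: bool, seed: int, n=24):
        base = [(900, 0.004), (1100, 0.004), (500, 0.004)]
        hot = [(900, 0.004), (1100, 0.04), (500, 0.004)]
        alns = {}
        for i, group in enumerate(["40-45", "45-50", "50-60"]):
            segs = hot if (group == "45-50" and focal_hot) else base
            _, aln, _ = simulate_structured_region(n, segs, seed=seed * 10 + i)
            alns[group] = aln
        return alns

    def test_identical_groups_nothing_significant(self):
        alns = self._alignments(focal_hot=False, seed=3)
        table = compare_window_profiles(alns, "45-50", seed=0, n_boot=50,
                                        alternative="greater")
        sig_cols = [c for c in table.columns if c.startswith("sig_")]
        # at alpha=0.05 a few false positives are possible but not a band
        assert table[sig_cols].to_numpy().mean() < 0.3

    def test_planted_band_flagged(self):
        alns = self._alignments(focal_hot=True, seed=4)
        table = compare_window_profiles(alns, "45-50", seed=0, n_boot=100)
        in_band = table[(table.window_start >= -1600) & (table.window_end <= -500)]
        frac = (in_band[["sig_vs_40-45", "sig_vs_50-60"]].to_numpy()).mean()
        assert frac > 0.8

    def test_windows_mode_band_test(self):
        alns = self._alignments(focal_hot=True, seed=5)
        table = compare_window_profiles(alns, "45-50", mode="windows",
                                        band=(-1600, -501))
        in_band = table[(table.window_start >= -1600) & (table.window_end <= -500)]
        assert in_band["sig_vs_40-45"].all()

    def test_single_group_rejected(self):
        alns = self._alignments(focal_hot=False, seed=6)
        with pytest.raises(ValueError):
            compare_window_profiles({"45-50": alns["45-50"]}, "45-50")


class TestGroupMeanComparison:
    def test_identical_groups_p_one(self):
        expr = pd.Series({"a1": 5.0, "a2": 6.0, "b1": 5.0, "b2": 6.0})
        groups = GroupAssignment({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "manual")
        summary, pairwise = group_mean_comparison(expr, groups)
        assert pairwise["p_value"].iloc[0] == 1.0
        assert summary.loc["A", "mean"] == 5.5

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(31)
        expr = pd.Series(
            {f"a{i}": v for i, v in enumerate(100 * np.exp(rng.normal(0, 0.3, 40)))} |
            {f"b{i}": v for i, v in enumerate(180 * np.exp(rng.normal(0, 0.3, 40)))})
        mapping = {k: ("A" if k.startswith("a") else "B") for k in expr.index}
        _, pairwise = group_mean_comparison(expr, GroupAssignment(mapping, "manual"))
        assert pairwise["p_value"].iloc[0] < 1e-4

    def test_empty_group_rejected(self):
        expr = pd.Series({"a1": 5.0})
        groups = GroupAssignment({"a1": "A", "zz": "B"}, "manual")
        with pytest.raises(ValueError):
            group_mean_comparison(expr, groups)
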