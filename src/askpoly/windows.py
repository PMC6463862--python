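"""Sliding-window diversity over promoter regions and grouped comparisons.

Windows are anchored at the transcription start site: the base immediately
upstream is offset -1, and 200 bp windows tile from the distal end with a
100 bp step, so a 2.5 kb region yields 24 windows (-2500..-2301 through
-200..-1).  Group comparisons use the Wilcoxon rank-sum (Mann-Whitney U)
test; the replication unit is configurable because windowed diversity is a
single number per group (see compare_window_profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import HaplotypeAlignment
from .popgen import nucleotide_diversity, per_column_pair_differences

LATITUDE_BINS = ((40.0, 45.0), (45.0, 50.0), (50.0, 60.0))
EXPRESSION_BOUNDS = (137.0, 170.0)
EXPRESSION_RANGE = (50.0, 480.0)


@dataclass
class WindowProfile:
    """Per-window nucleotide diversity for one region (optionally one group)."""

    region_id: str
    windows: list[tuple[int, int]]   # (start_offset, end_offset), TSS-relative
    pi_site: np.ndarray
    window_size: int
    step: int
    group: str | None = None


@dataclass
class GroupAssignment:
    """Accession -> group label under one grouping scheme."""

    mapping: dict[str, str]
    scheme: str

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.mapping.items() if g == group]

    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def window_offsets(L: int, window: int, step: int) -> list[tuple[int, int]]:
    """TSS-relative (start, end) offsets of all full windows in a region of
    length L ending at offset -1; count is floor((L - window)/step) + 1."""
    if window > L:
        raise ValueError("window larger than region")
    n_windows = (L - window) // step + 1
    return [(-L + k * step, -L + k * step + window - 1) for k in range(n_windows)]


def sliding_window_diversity(aln: HaplotypeAlignment, window: int = 200,
                             step: int = 100, group: str | None = None,
                             ) -> WindowProfile:
    """Per-window pi (per site) across a TSS-anchored upstream alignment."""
    offsets = window_offsets(aln.L, window, step)
    discordant = per_column_pair_differences(aln)
    n_pairs = aln.n * (aln.n - 1) / 2.0
    pis = np.empty(len(offsets))
    for k, (start, _) in enumerate(offsets):
        col = start + aln.L            # offset -L maps to column 0
        pis[k] = discordant[col:col + window].sum() / (n_pairs * window)
    return WindowProfile(aln.region_id, offsets, pis, window, step, group)


def assign_latitude_groups(metadata: pd.DataFrame,
                           bins=LATITUDE_BINS) -> GroupAssignment:
    """Bin accessions by latitude; bins are left-closed right-open except
    the last, which includes its upper bound.  Accessions outside all bins
    are left unassigned."""
    mapping = {}
    for acc, lat in metadata["latitude"].items():
        for i, (lo, hi) in enumerate(bins):
            last = i == len(bins) - 1
            if lo <= lat < hi or (last and lat == hi):
                mapping[acc] = f"{lo:g}-{hi:g}"
                break
    return GroupAssignment(mapping, "latitude-bins")


def assign_expression_groups(expression: pd.Series,
                             boundaries=EXPRESSION_BOUNDS,
                             value_range=EXPRESSION_RANGE) -> GroupAssignment:
    """Split accessions into low/medium/high expression groups.

    With the defaults: low = [50, 137) RPKM, medium = [137, 170),
    high = [170, 480]; values outside the overall range are unassigned.
    """
    lo_b, hi_b = boundaries
    lo_r, hi_r = value_range
    mapping = {}
    for acc, value in expression.items():
        if not lo_r <= value <= hi_r:
            continue
        if value < lo_b:
            mapping[acc] = "low"
        elif value < hi_b:
            mapping[acc] = "medium"
        else:
            mapping[acc] = "high"
    return GroupAssignment(mapping, "expression-ranges")


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      ) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test with midranks for ties.

    The p-value is exact (full enumeration) when min(n_x, n_y) <= 8 and
    there are no ties, and otherwise uses the normal approximation with tie
    and continuity corrections.  Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _bootstrap_window_pis(aln: HaplotypeAlignment, window: int, step: int,
                          n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n_windows) windowed pi over half-group accession resamples."""
    half = max(2, aln.n // 2)
    n_windows = (aln.L - window) // step + 1
    out = np.empty((n_boot, n_windows))
    for b in range(n_boot):
        idx = rng.choice(aln.n, size=half, replace=False)
        sub = HaplotypeAlignment(aln.region_id,
                                 [aln.accessions[i] for i in idx],
                                 aln.matrix[idx], aln.site_coords)
        out[b] = sliding_window_diversity(sub, window, step).pi_site
    return out


def compare_window_profiles(alignments: dict[str, HaplotypeAlignment],
                            focal_group: str, alpha: float = 0.05,
                            window: int = 200, step: int = 100,
                            mode: str = "bootstrap", n_boot: int = 100,
                            seed: int = 0, band: tuple[int, int] | None = None,
                            alternative: str = "greater") -> pd.DataFrame:
    """Per-window diversity comparison of a focal group against the others.

    ``mode="bootstrap"`` (default): each group's per-window pi is computed
    on ``n_boot`` half-group accession resamples and the rank-sum test
    compares resample distributions per window.  ``mode="windows"``: the
    windows inside ``band`` (TSS-relative offsets) are the replication
    units and one test is run per group pair, its p-value attached to every
    window in the band.  The default alternative "greater" asks whether the
    focal group is more diverse.
    """
    if focal_group not in alignments:
        raise ValueError(f"focal group {focal_group!r} missing")
    if len(alignments) < 2:
        raise ValueError("need at least two groups to compare")
    usable = {}
    for g, aln in alignments.items():
        if aln.n < 2:
            import warnings
            warnings.warn(f"group {g!r} has < 2 accessions; skipped")
            continue
        usable[g] = aln
    if focal_group not in usable or len(usable) < 2:
        raise ValueError("fewer than two usable groups")
    rng = np.random.default_rng(seed)
    offsets = window_offsets(next(iter(usable.values())).L, window, step)
    others = [g for g in usable if g != focal_group]

    mean_pi = {g: sliding_window_diversity(aln, window, step).pi_site
               for g, aln in usable.items()}
    records = []
    if mode == "bootstrap":
        boot = {g: _bootstrap_window_pis(aln, window, step, n_boot, rng)
                for g, aln in usable.items()}
        for k, (start, end) in enumerate(offsets):
            rec = {"window_start": start, "window_end": end}
            for g in usable:
                rec[f"pi_{g}"] = mean_pi[g][k]
            for g in others:
                _, p = wilcoxon_rank_sum(boot[focal_group][:, k], boot[g][:, k],
                                         alternative=alternative)
                rec[f"p_vs_{g}"] = p
                rec[f"sig_vs_{g}"] = p < alpha
            records.append(rec)
    elif mode == "windows":
        if band is None:
            band = (offsets[0][0], offsets[-1][1])
        in_band = [k for k, (s, e) in enumerate(offsets)
                   if s >= band[0] and e <= band[1]]
        band_p = {}
        for g in others:
            _, band_p[g] = wilcoxon_rank_sum(mean_pi[focal_group][in_band],
                                             mean_pi[g][in_band],
                                             alternative=alternative)
        for k, (start, end) in enumerate(offsets):
            rec = {"window_start": start, "window_end": end}
            for g in usable:
                rec[f"pi_{g}"] = mean_pi[g][k]
            for g in others:
                rec[f"p_vs_{g}"] = band_p[g] if k in in_band else np.nan
                rec[f"sig_vs_{g}"] = bool(k in in_band and band_p[g] < alpha)
            records.append(rec)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(records)


def group_mean_comparison(expression: pd.Series, groups: GroupAssignment,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means/medians plus pairwise two-sided rank-sum p-values.

    Returns (summary, pairwise) frames; raises on an empty group.
    """
    labels = groups.groups()
    samples = {}
    for g in labels:
        members = [a for a in groups.members(g) if a in expression.index]
        if not members:
            raise ValueError(f"group {g!r} is empty")
        samples[g] = expression.loc[members].to_numpy(dtype=float)
    summary = pd.DataFrame({
        "group": labels,
        "n": [samples[g].size for g in labels],
        "mean": [samples[g].mean() for g in labels],
        "median": [float(np.median(samples[g])) for g in labels],
    }).set_index("group")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            u, p = wilcoxon_rank_sum(samples[a], samples[b], "two-sided")
            rows.append({"group_a": a, "group_b": b, "U": u, "p_value": p})
    return summary, pd.DataFrame(rows)
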