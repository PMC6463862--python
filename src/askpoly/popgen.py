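"""Diversity statistics per gene region: segregating sites, nucleotide
diversity pi, Watterson's theta, Tajima's D with its beta-approximation
significance test, minor-allele-frequency spectra, and synonymous /
nonsynonymous classification of coding SNPs.

Missing data (N) is handled by pairwise deletion: a column counts as
segregating when it shows >= 2 distinct non-N alleles, and pairwise
differences are taken over sites where both sequences are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import HaplotypeAlignment, translate_cds
from .io import GeneModel, SnpTable

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class TajimaConstants:
    """The sample-size constants of Tajima's D variance formula."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("constants require n >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class PolymorphismSummary:
    """Per-region summary of within-species polymorphism."""

    region_id: str
    n: int
    L: int
    S: int
    pi_locus: float
    pi_site: float
    theta_locus: float
    theta_site: float
    tajima_d: float          # nan when undefined (S == 0)
    d_defined: bool
    d_significant: bool


def _codes(aln: HaplotypeAlignment) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.int8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    return lut[aln.matrix.view(np.uint32).astype(np.intp) & 0x7F]


def _allele_counts(aln: HaplotypeAlignment) -> np.ndarray:
    """(L, 5) counts of A,C,G,T,N per column."""
    codes = _codes(aln)
    counts = np.zeros((aln.L, 5), dtype=np.int64)
    for k in range(5):
        counts[:, k] = (codes == k).sum(axis=0)
    return counts


def per_column_pair_differences(aln: HaplotypeAlignment) -> np.ndarray:
    """Number of discordant called pairs per alignment column.

    Summing over columns and dividing by C(n, 2) gives pi_locus; window
    statistics reuse these counts without re-scanning the alignment.
    """
    counts = _allele_counts(aln)[:, :4]
    called = counts.sum(axis=1)
    return (called * (called - 1) - (counts * (counts - 1)).sum(axis=1)) / 2.0


def segregating_sites(aln: HaplotypeAlignment) -> int:
    """Number of columns with at least two distinct non-N alleles."""
    if aln.n < 2:
        raise ValueError("segregating sites require n >= 2")
    counts = _allele_counts(aln)[:, :4]
    return int(((counts > 0).sum(axis=1) >= 2).sum())


def nucleotide_diversity(aln: HaplotypeAlignment) -> tuple[float, float]:
    """Mean pairwise differences per pair (pi_locus) and per site (pi_site).

    Equivalent to summing, over columns, the number of discordant pairs of
    called sequences, divided by C(n, 2) — which is the pairwise-deletion
    double loop over all sequence pairs.
    """
    if aln.n < 2:
        raise ValueError("pi requires n >= 2")
    if aln.L == 0:
        raise ValueError("pi requires a non-empty alignment")
    discordant = per_column_pair_differences(aln)
    n_pairs = aln.n * (aln.n - 1) / 2.0
    pi_locus = float(discordant.sum() / n_pairs)
    return pi_locus, pi_locus / aln.L


def watterson_theta(S: int, n: int, L: int) -> tuple[float, float]:
    """Watterson's estimator theta_W = S / a1, per locus and per site."""
    if n < 2:
        raise ValueError("theta_W requires n >= 2")
    a1 = TajimaConstants.from_n(n).a1
    theta_locus = S / a1
    return theta_locus, theta_locus / L


def tajimas_d(aln: HaplotypeAlignment) -> tuple[float, bool]:
    """Tajima's D and a defined-flag (False, with D = nan, when S = 0)."""
    if aln.n < 3:
        raise ValueError("Tajima's D requires n >= 3")
    S = segregating_sites(aln)
    if S == 0:
        return float("nan"), False
    pi_locus, _ = nucleotide_diversity(aln)
    c = TajimaConstants.from_n(aln.n)
    numerator = pi_locus - S / c.a1
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var == 0.0:
        # n = 3 degenerates (c1 = c2 = 0); D is 0/0 there, defined only
        # when the numerator vanishes too
        return (0.0, True) if abs(numerator) < 1e-12 else (float("nan"), False)
    return numerator / sqrt(var), True


def tajima_d_beta_bounds(n: int) -> tuple[float, float, float, float]:
    """(Dmin, Dmax, alpha, beta) of the beta approximation to D's null.

    D is bounded: with many segregating sites the minimum is reached when
    every variant is a singleton and the maximum when every variant is at
    frequency 1/2 (odd-n form (n+1)/2n).  The null is approximated by a
    beta distribution rescaled to [Dmin, Dmax] with mean 0 and variance 1.
    """
    c = TajimaConstants.from_n(n)
    se = sqrt(c.e2)
    d_min = (2.0 / n - 1.0 / c.a1) / se
    d_max = ((n + 1) / (2.0 * n) - 1.0 / c.a1) / se
    alpha = -(1.0 + d_min * d_max) * d_max / (d_max - d_min)
    beta = (1.0 + d_min * d_max) * d_min / (d_max - d_min)
    return d_min, d_max, alpha, beta


def tajima_significance(D: float, n: int, alpha: float = 0.05) -> bool:
    """True iff D falls outside the two-sided (1 - alpha) interval of the
    beta-approximated neutral null for sample size n."""
    if n < 4:
        raise ValueError("significance approximation unsupported for n < 4")
    if not np.isfinite(D):
        raise ValueError("D must be defined")
    d_min, d_max, a_shape, b_shape = tajima_d_beta_bounds(n)
    if D <= d_min or D >= d_max:
        return True
    # (D - Dmin)/(Dmax - Dmin) ~ Beta(b_shape, a_shape) under the null
    x = (D - d_min) / (d_max - d_min)
    cdf = stats.beta(b_shape, a_shape).cdf(x)
    return bool(cdf < alpha / 2 or cdf > 1 - alpha / 2)


def summarize_region(aln: HaplotypeAlignment, alpha: float = 0.05,
                     ) -> PolymorphismSummary:
    """Full per-region polymorphism summary (the per-gene, per-region row)."""
    S = segregating_sites(aln)
    pi_locus, pi_site = nucleotide_diversity(aln)
    theta_locus, theta_site = watterson_theta(S, aln.n, aln.L)
    D, defined = tajimas_d(aln)
    significant = bool(defined and aln.n >= 4 and tajima_significance(D, aln.n, alpha))
    return PolymorphismSummary(aln.region_id, aln.n, aln.L, S, pi_locus, pi_site,
                               theta_locus, theta_site, D, defined, significant)


@dataclass
class MafSpectrum:
    """Minor-allele counts per SNP with per-class singleton fractions."""

    minor_counts: pd.Series            # index (chrom, pos)
    histogram: pd.Series               # minor-allele count -> number of SNPs
    singleton_fraction: dict[str, float]
    n_excluded_monomorphic: int


def maf_spectrum(snps: SnpTable, classes: dict[tuple[str, int], str] | None = None,
                 roster_size: int | None = None) -> MafSpectrum:
    """Minor-allele spectrum over the accession roster.

    Accessions without a record at a site are assumed to carry the reference
    allele, so the alt count at a site is the number of records and the ref
    count is roster_size minus that.  Sites that come out monomorphic are
    excluded and counted.  ``classes`` maps (chrom, pos) to a functional
    class ("nonsynonymous" / "synonymous" / "noncoding"); singleton
    fractions are reported per class and overall.
    """
    if roster_size is None:
        roster_size = len(snps.roster)
    alt_counts = snps.df.groupby(["chrom", "pos"]).size()
    poly = alt_counts[(alt_counts > 0) & (alt_counts < roster_size)]
    n_excluded = len(alt_counts) - len(poly)
    minor = np.minimum(poly, roster_size - poly).astype(int)
    histogram = minor.value_counts().sort_index()
    fractions = {}
    if len(minor):
        fractions["all"] = float((minor == 1).mean())
    if classes:
        labels = pd.Series({site: classes.get(site, "noncoding") for site in minor.index})
        for cls in sorted(labels.unique()):
            sub = minor[labels == cls]
            fractions[cls] = float((sub == 1).mean())
    return MafSpectrum(minor, histogram, fractions, n_excluded)


def build_frame_map(gene: GeneModel) -> dict[int, int]:
    """Map chromosomal positions of coding bases to 0-based CDS indices.

    On the minus strand index 0 is the first base of the start codon, i.e.
    the highest chromosomal coordinate of the last exon.
    """
    positions: list[int] = []
    for s, e in gene.exons:
        positions.extend(range(s, e + 1))
    if gene.strand == "-":
        positions.reverse()
    return {pos: i for i, pos in enumerate(positions)}


def classify_coding_snps(snps: SnpTable, cds: str, frame_map: dict[int, int],
                         strand: str = "+") -> pd.DataFrame:
    """Classify coding SNPs as synonymous or nonsynonymous.

    The alt allele is substituted into the reference codon and both codons
    translated under the standard code; stop gains/losses are classed
    nonsynonymous with a nonsense flag.  SNP alleles are chromosomal and are
    complemented for minus-strand genes.  Returns one row per distinct
    (chrom, pos, ref, alt) site.
    """
    comp = str.maketrans("ACGT", "TGCA")
    cds = cds.upper()
    rows = []
    sites = snps.df.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    for row in sites.itertuples(index=False):
        pos = int(row.pos)
        if pos not in frame_map:
            raise ValueError(f"SNP position {pos} not in the frame map")
        idx = frame_map[pos]
        ref_nt, alt_nt = row.ref, row.alt
        if strand == "-":
            ref_nt, alt_nt = ref_nt.translate(comp), alt_nt.translate(comp)
        codon_start = 3 * (idx // 3)
        codon = cds[codon_start:codon_start + 3]
        if codon[idx % 3] != ref_nt:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{pos}: CDS has "
                f"{codon[idx % 3]}, SNP states {ref_nt}")
        alt_codon = codon[:idx % 3] + alt_nt + codon[idx % 3 + 1:]
        aa_ref, aa_alt = translate_cds(codon), translate_cds(alt_codon)
        synonymous = aa_ref == aa_alt
        rows.append({
            "chrom": row.chrom, "pos": pos, "ref": row.ref, "alt": row.alt,
            "codon_ref": codon, "codon_alt": alt_codon,
            "aa_ref": aa_ref, "aa_alt": aa_alt,
            "snp_class": "synonymous" if synonymous else "nonsynonymous",
            "nonsense": (aa_ref == "*") != (aa_alt == "*"),
        })
    return pd.DataFrame(rows)
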