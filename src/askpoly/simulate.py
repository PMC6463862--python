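"""Synthetic inputs with known ground truth for every pipeline stage.

The SNP generator runs an internal Kingman coalescent with infinite-sites
mutations, so the analytic neutral expectations (E[S] = theta * L * a1,
E[pi_site] = theta) serve as independent oracles.  Codon pairs are evolved
under the same GY94 process the fitting code estimates; expression values
are log-normal with group-specific locations.  All generators are
bit-for-bit reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .assembly import HaplotypeAlignment
from .divergence import CODONS, build_rate_matrix, equal_codon_freqs
from .io import GeneModel, SnpRecord, SnpTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one simulated dataset."""

    seed: int
    theta_site: float = float("nan")
    omega_true: float = float("nan")
    kappa_true: float = float("nan")
    t_true: float = float("nan")
    group_means: dict = field(default_factory=dict)
    n_mutations: int = 0


@dataclass
class SimulatedLocus:
    """A reference locus with annotated UP / CDS / DN regions."""

    chrom: str
    reference: str            # full chromosome sequence
    gene: GeneModel
    up_interval: tuple[int, int]
    cds_interval: tuple[int, int]
    dn_interval: tuple[int, int]


def _random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _coalescent_branches(n: int, rng: np.random.Generator,
                         ) -> list[tuple[frozenset, float]]:
    """Simulate a Kingman genealogy; return (subtended leaf set, branch
    length) for every branch below the root."""
    branches: list[tuple[frozenset, float]] = []
    t = 0.0
    lineages = [frozenset([i]) for i in range(n)]
    node_height = {fs: 0.0 for fs in lineages}
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[j], lineages[i]      # pop higher index first
        del lineages[j], lineages[i]
        branches.append((a, t - node_height[a]))
        branches.append((b, t - node_height[b]))
        merged = a | b
        node_height[merged] = t
        lineages.append(merged)
    return branches


def simulate_structured_region(n_accessions: int, segments: list[tuple[int, float]],
                               seed: int, qual_min_frac: float = 0.95,
                               region_id: str = "sim", chrom: str = "chr1",
                               offset: int = 0,
                               ) -> tuple[SnpTable, HaplotypeAlignment, SimulationTruth]:
    """Coalescent SNPs over a region made of (length, theta_site) segments.

    One genealogy is drawn for the whole region; each segment receives
    infinite-sites mutations at its own Poisson rate theta*L/2 per unit of
    branch length, each at a distinct uniformly drawn site (collisions
    redrawn).  Haplotypes are rendered onto a random reference starting at
    chromosomal position ``offset + 1``.  Phred qualities are drawn so that
    ``qual_min_frac`` of calls are >= 25 and the rest below 25.
    """
    if n_accessions < 2:
        raise ValueError("coalescent simulation requires n >= 2")
    if any(theta < 0 or L <= 0 for L, theta in segments):
        raise ValueError("segment lengths must be positive and thetas >= 0")
    rng = np.random.default_rng(seed)
    total_len = sum(L for L, _ in segments)
    reference = _random_reference(total_len, rng)
    branches = _coalescent_branches(n_accessions, rng)

    used_sites: set[int] = set()
    mutations: list[tuple[int, frozenset]] = []   # (0-based site, carriers)
    seg_start = 0
    for L, theta in segments:
        for leafset, blen in branches:
            n_mut = rng.poisson(blen * theta * L / 2.0)
            for _ in range(n_mut):
                site = seg_start + int(rng.integers(L))
                while site in used_sites:
                    site = seg_start + int(rng.integers(L))
                used_sites.add(site)
                mutations.append((site, leafset))
        seg_start += L
    mutations.sort(key=lambda m: m[0])

    accessions = [f"acc{i:04d}" for i in range(n_accessions)]
    matrix = np.array([list(reference)] * n_accessions, dtype="<U1")
    records: list[SnpRecord] = []
    for site, carriers in mutations:
        ref_base = reference[site]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        for leaf in sorted(carriers):
            matrix[leaf, site] = alt_base
            if rng.random() < qual_min_frac:
                qual = float(rng.uniform(25.0, 45.0))
            else:
                qual = float(rng.uniform(10.0, 25.0))
            records.append(SnpRecord(chrom, offset + site + 1, ref_base, alt_base,
                                     accessions[leaf], round(qual, 1)))
    table = SnpTable.from_records(records, roster=accessions)
    coords = np.arange(offset + 1, offset + total_len + 1)
    aln = HaplotypeAlignment(region_id, accessions, matrix, site_coords=coords)
    theta_overall = sum(L * th for L, th in segments) / total_len
    truth = SimulationTruth(seed=seed, theta_site=theta_overall,
                            n_mutations=len(mutations))
    return table, aln, truth


def simulate_coalescent_snps(n_accessions: int, region_length: int,
                             theta_site: float, seed: int, **kw,
                             ) -> tuple[SnpTable, HaplotypeAlignment, SimulationTruth]:
    """Uniform-rate special case of :func:`simulate_structured_region`."""
    if theta_site < 0:
        raise ValueError("theta must be >= 0")
    return simulate_structured_region(n_accessions, [(region_length, theta_site)],
                                      seed, **kw)


def simulate_codon_pair(n_codons: int, t: float, kappa: float, omega: float,
                        seed: int, codon_freqs: np.ndarray | None = None,
                        ) -> tuple[str, str, SimulationTruth]:
    """Evolve a descendant codon sequence from a stationary ancestor.

    The ancestor is drawn from the stationary codon frequencies; each codon
    evolves independently for time t under the GY94 process (single-
    nucleotide changes, transition factor kappa, nonsynonymous factor
    omega) via transition-probability sampling.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if t < 0 or kappa <= 0 or omega < 0:
        raise ValueError("require t >= 0, kappa > 0, omega >= 0")
    rng = np.random.default_rng(seed)
    pi = equal_codon_freqs() if codon_freqs is None else np.asarray(codon_freqs)
    ancestor_idx = rng.choice(61, size=n_codons, p=pi)
    if t == 0:
        descendant_idx = ancestor_idx
    else:
        P = expm(build_rate_matrix(kappa, omega, pi) * t)
        P = np.clip(P, 0, None)
        P /= P.sum(axis=1, keepdims=True)
        descendant_idx = np.array([rng.choice(61, p=P[i]) for i in ancestor_idx])
    seq_a = "".join(CODONS[i] for i in ancestor_idx)
    seq_b = "".join(CODONS[i] for i in descendant_idx)
    truth = SimulationTruth(seed=seed, omega_true=omega, kappa_true=kappa, t_true=t)
    return seq_a, seq_b, truth


def simulate_expression(metadata: pd.DataFrame, groups: dict[str, str],
                        group_means: dict[str, float], noise_sd: float,
                        seed: int, gene: str = "ASK1") -> pd.DataFrame:
    """Log-normal RPKM values with group-specific locations.

    ``groups`` maps every accession in ``metadata`` to a group label and
    ``group_means`` gives each group's median RPKM; values are
    mean * exp(Normal(0, noise_sd)), so noise_sd = 0 returns the group
    means exactly.  Returns a genes x accessions expression matrix.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = [a for a in metadata.index if a not in groups]
    if missing:
        raise ValueError(f"accessions without a group: {missing[:5]}")
    rng = np.random.default_rng(seed)
    accs = list(metadata.index)
    values = np.array([group_means[groups[a]] for a in accs], dtype=float)
    values = values * np.exp(rng.normal(0.0, noise_sd, size=len(accs)))
    return pd.DataFrame([values], index=[gene], columns=accs)


def generate_gene_table(n_genes: int, family_member_indices: list[int],
                        spacing_spec: list[int], seed: int,
                        gene_length: int = 1000, chrom: str = "chr1",
                        first_start: int = 1001) -> list[GeneModel]:
    """A linear chromosome of gene models with exact intergenic spacing.

    ``spacing_spec`` gives the n_genes - 1 intergenic gaps (bp between the
    end of one gene and the start of the next).  Family members (by index)
    are named fam0, fam1, ...; the rest other0, other1, ....  Negative gaps
    (overlapping placements) raise.
    """
    if len(spacing_spec) != n_genes - 1:
        raise ValueError("spacing_spec must have n_genes - 1 gaps")
    if any(g < 0 for g in spacing_spec):
        raise ValueError("overlapping gene placements (negative gap)")
    rng = np.random.default_rng(seed)
    family = set(family_member_indices)
    genes, start = [], first_start
    fam_i = other_i = 0
    for i in range(n_genes):
        end = start + gene_length - 1
        if i in family:
            name, fam_i = f"fam{fam_i}", fam_i + 1
        else:
            name, other_i = f"other{other_i}", other_i + 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(name, chrom, strand, start, end, ((start, end),)))
        if i < n_genes - 1:
            start = end + spacing_spec[i] + 1
    return genes


def simulate_locus(cds_codons: int = 50, seed: int = 0, up_len: int = 500,
                   dn_len: int = 500, flank: int = 200, chrom: str = "chr1",
                   introns: list[int] | None = None) -> SimulatedLocus:
    """A reference locus with 500 bp UP, an in-frame CDS, and 500 bp DN.

    The CDS begins with ATG and ends with TGA, with internal stops avoided;
    ``introns`` optionally lists 0-based codon boundaries after which an
    intron (100 bp) is inserted, producing a multi-exon gene model.
    """
    rng = np.random.default_rng(seed)
    sense = [c for c in CODONS if c != "ATG"]
    body = [str(rng.choice(sense)) for _ in range(cds_codons - 2)]
    cds = "ATG" + "".join(body) + "TGA"
    intron_len = 100
    introns = sorted(introns or [])
    pieces, exon_lens, prev = [], [], 0
    for b in introns:
        pieces.append(cds[prev * 3:b * 3])
        exon_lens.append((b - prev) * 3)
        prev = b
    pieces.append(cds[prev * 3:])
    exon_lens.append(len(cds) - prev * 3)
    genomic = (_random_reference(intron_len, rng).join(pieces)
               if introns else cds)
    upstream = _random_reference(flank + up_len, rng)
    downstream = _random_reference(dn_len + flank, rng)
    reference = upstream + genomic + downstream
    gene_start = len(upstream) + 1
    exons, pos = [], gene_start
    for L in exon_lens:
        exons.append((pos, pos + L - 1))
        pos += L + intron_len
    gene_end = exons[-1][1]
    gene = GeneModel("simgene", chrom, "+", gene_start, gene_end, tuple(exons))
    return SimulatedLocus(
        chrom, reference, gene,
        up_interval=(gene_start - up_len, gene_start - 1),
        cds_interval=(gene_start, gene_end),
        dn_interval=(gene_end + 1, gene_end + dn_len),
    )
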