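"""Structural annotation of family members: flanking regions, intron
counts, and tandem-duplication clusters.

Upstream/downstream regions are defined relative to the coding strand:
for a minus-strand gene "upstream" lies at higher chromosomal coordinates
and the extracted sequence is reverse-complemented.  Regions are truncated
(not padded) at chromosome ends, with a truncation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .assembly import reverse_complement
from .io import GeneModel


@dataclass
class GeneRegions:
    """Up/CDS/down sequences for one gene plus their chromosomal intervals.

    Intervals are 1-based inclusive in chromosomal (forward) coordinates;
    an empty region is represented by ``None`` and an empty sequence.
    """

    gene_id: str
    chrom: str
    strand: str
    up: str
    cds: str
    dn: str
    up_interval: tuple[int, int] | None
    cds_intervals: tuple[tuple[int, int], ...]
    dn_interval: tuple[int, int] | None
    up_truncated: bool = False
    dn_truncated: bool = False


def extract_regions(gene: GeneModel, reference: dict[str, str] | str,
                    up_len: int = 500, dn_len: int = 500) -> GeneRegions:
    """Extract the flanking regions and spliced CDS of a gene.

    ``reference`` is either a chrom->sequence mapping or a single chromosome
    sequence.  For a + strand gene the upstream interval is
    [start-up_len, start-1] and downstream [end+1, end+dn_len]; on the -
    strand the two are mirrored and all sequences reverse-complemented.
    """
    chrom_seq = reference[gene.chrom] if isinstance(reference, dict) else reference
    chrom_len = len(chrom_seq)
    if gene.start < 1 or gene.end > chrom_len:
        raise ValueError(f"{gene.gene_id}: gene extends beyond chromosome bounds")

    def fetch(lo: int, hi: int) -> tuple[str, tuple[int, int] | None, bool]:
        truncated = lo < 1 or hi > chrom_len
        lo_c, hi_c = max(lo, 1), min(hi, chrom_len)
        if lo_c > hi_c:
            return "", None, True
        return chrom_seq[lo_c - 1:hi_c].upper(), (lo_c, hi_c), truncated

    exons = gene.exons if gene.exons else ((gene.start, gene.end),)
    cds = "".join(chrom_seq[s - 1:e].upper() for s, e in exons)

    if gene.strand == "+":
        up, up_iv, up_tr = fetch(gene.start - up_len, gene.start - 1)
        dn, dn_iv, dn_tr = fetch(gene.end + 1, gene.end + dn_len)
    else:
        up, up_iv, up_tr = fetch(gene.end + 1, gene.end + up_len)
        dn, dn_iv, dn_tr = fetch(gene.start - dn_len, gene.start - 1)
        up, dn, cds = (reverse_complement(up), reverse_complement(dn),
                       reverse_complement(cds))
    return GeneRegions(gene.gene_id, gene.chrom, gene.strand, up, cds, dn,
                       up_iv, tuple(exons), dn_iv, up_tr, dn_tr)


def count_introns(gene: GeneModel) -> int:
    """Intron count from the gene model: number of exons minus one."""
    if gene.n_exons < 1:
        raise ValueError(f"{gene.gene_id}: gene model has no exons")
    return gene.n_exons - 1


def find_tandem_duplicates(genes: list[GeneModel], family_ids: set[str],
                           max_intervening: int = 5, max_distance: int = 10_000,
                           distance_mode: str = "boundary",
                           ) -> list[tuple[str, str]]:
    """Pairs of family genes that are tandemly duplicated.

    A pair is reported iff both genes sit on the same chromosome, at most
    ``max_intervening`` annotated genes (of any family) lie strictly between
    them, and they are within ``max_distance`` bp.  Distance is measured
    between nearest gene boundaries by default (``distance_mode="boundary"``:
    start of the downstream gene minus end of the upstream one, floored at
    0 for overlaps); ``"start"`` measures between gene starts instead.
    """
    if distance_mode not in {"boundary", "start"}:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start))
    if order != list(range(len(genes))):
        raise ValueError("genes must be sorted by chromosome then start")

    family_idx = [i for i, g in enumerate(genes) if g.gene_id in family_ids]
    pairs = []
    for i, j in combinations(family_idx, 2):
        a, b = genes[i], genes[j]
        if a.chrom != b.chrom:
            continue
        if (j - i - 1) > max_intervening:
            continue
        if distance_mode == "boundary":
            dist = max(0, b.start - a.end)
        else:
            dist = b.start - a.start
        if dist <= max_distance:
            pairs.append(tuple(sorted((a.gene_id, b.gene_id))))
    return sorted(pairs)
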