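"""Per-accession allele assembly from SNP calls and outgroup assembly.

Allelic sequences are reconstructed by substituting quality-passing SNP
alleles into a reference region.  Two sequences are built per accession:
the variant allele (alt alleles substituted) and a reference-allele
reconstruction (ref alleles substituted).  The reconstruction must be 100%
identical to the reference for the variant allele to count as correctly
assembled — a mismatch signals a coordinate or assembly-version error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SnpTable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HaplotypeAlignment:
    """n assembled allelic sequences x L sites for one gene region.

    ``matrix`` holds single characters over {A,C,G,T,N}; ``site_coords``
    maps alignment columns back to 1-based chromosomal positions.
    """

    region_id: str
    accessions: list[str]
    matrix: np.ndarray  # (n, L) of single-character unicode
    site_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("alignment must be a non-empty 2-D matrix")
        if len(self.accessions) != self.matrix.shape[0]:
            raise ValueError("accession labels do not match row count")
        if self.site_coords is None:
            self.site_coords = np.arange(1, self.matrix.shape[1] + 1)
        self.site_coords = np.asarray(self.site_coords, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, region_id: str, named_seqs: list[tuple[str, str]],
                       site_coords=None) -> "HaplotypeAlignment":
        names = [n for n, _ in named_seqs]
        mat = np.array([list(s) for _, s in named_seqs], dtype="<U1")
        return cls(region_id, names, mat, site_coords)

    def sequence(self, accession: str) -> str:
        return "".join(self.matrix[self.accessions.index(accession)])

    def subset(self, accessions: list[str]) -> "HaplotypeAlignment":
        idx = [self.accessions.index(a) for a in accessions]
        return HaplotypeAlignment(self.region_id, list(accessions),
                                  self.matrix[idx], self.site_coords)

    def window(self, start_col: int, end_col: int) -> "HaplotypeAlignment":
        """Column slice [start_col, end_col) in 0-based alignment columns."""
        return HaplotypeAlignment(self.region_id, self.accessions,
                                  self.matrix[:, start_col:end_col],
                                  self.site_coords[start_col:end_col])


@dataclass
class AssemblyReport:
    region_id: str
    accession: str
    n_snps_applied: int
    n_snps_filtered_by_quality: int
    colzero_identity: bool
    mismatch_positions: list[int] = field(default_factory=list)


def assemble_alleles(interval: tuple[str, int, int], reference_seq: str,
                     snps: SnpTable, accession: str, qual_min: float = 25.0,
                     strand: str = "+", region_id: str = "region",
                     ) -> tuple[str, str, AssemblyReport]:
    """Build the variant allele and the reference-allele reconstruction.

    ``interval`` is (chrom, start, end), 1-based inclusive; ``reference_seq``
    is the region sequence in chromosomal forward orientation.  SNPs outside
    the interval are ignored; SNPs below ``qual_min`` are filtered and
    counted.  Substitution happens in chromosomal space; for minus-strand
    regions both outputs are reverse-complemented at the end.
    """
    chrom, start, end = interval
    if len(reference_seq) != end - start + 1:
        raise ValueError("reference sequence length does not match interval")
    reference_seq = reference_seq.upper()
    variant = list(reference_seq)
    recon = list(reference_seq)
    applied = filtered = 0
    mismatches = []
    acc_snps = snps.for_accession(accession)
    mask = (acc_snps["chrom"] == chrom) & acc_snps["pos"].between(start, end)
    for row in acc_snps[mask].itertuples(index=False):
        if row.qual < qual_min:
            filtered += 1
            continue
        i = int(row.pos) - start
        if reference_seq[i] != row.ref:
            mismatches.append(int(row.pos))
        variant[i] = row.alt
        recon[i] = row.ref
        applied += 1
    variant_seq, recon_seq = "".join(variant), "".join(recon)
    valid = not mismatches and recon_seq == reference_seq
    if strand == "-":
        variant_seq = reverse_complement(variant_seq)
        recon_seq = reverse_complement(recon_seq)
    report = AssemblyReport(region_id, accession, applied, filtered, valid, mismatches)
    return variant_seq, recon_seq, report


def assemble_alignment(interval: tuple[str, int, int], reference_seq: str,
                       snps: SnpTable, accessions: list[str] | None = None,
                       qual_min: float = 25.0, strand: str = "+",
                       region_id: str = "region", missing_as_n: bool = False,
                       ) -> tuple[HaplotypeAlignment, list[AssemblyReport]]:
    """Assemble variant alleles for many accessions into one alignment.

    Accessions with no SNP record at a site carry the reference allele
    (the 1001-genomes matrix reports variants only); ``missing_as_n=True``
    masks non-called sites to N instead.
    """
    if accessions is None:
        accessions = snps.roster
    seqs, reports = [], []
    for acc in accessions:
        variant, _, rep = assemble_alleles(interval, reference_seq, snps, acc,
                                           qual_min=qual_min, strand=strand,
                                           region_id=region_id)
        if missing_as_n:
            called = set(snps.for_accession(acc)["pos"])
            chars = list(variant)
            positions = (range(interval[2], interval[1] - 1, -1) if strand == "-"
                         else range(interval[1], interval[2] + 1))
            chars = ["N" if p not in called else c for c, p in zip(chars, positions)]
            variant = "".join(chars)
        seqs.append((acc, variant))
        reports.append(rep)
    coords = np.arange(interval[1], interval[2] + 1)
    if strand == "-":
        coords = coords[::-1]
    aln = HaplotypeAlignment.from_sequences(region_id, seqs, site_coords=coords)
    return aln, reports


def align_proteins_global(a: str, b: str, match: float = 1.0,
                          mismatch: float = -1.0, gap: float = -2.0,
                          ) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with linear gap cost.

    Ties are broken by preferring the diagonal (match/mismatch) move, then a
    gap in ``a``, then a gap in ``b``, giving a unique deterministic optimum.
    Returns (aligned_a, aligned_b, score).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    la, lb = len(a), len(b)
    score = np.empty((la + 1, lb + 1))
    score[0, :] = np.arange(lb + 1) * gap
    score[:, 0] = np.arange(la + 1) * gap
    sub = np.where(
        np.array(list(a))[:, None] == np.array(list(b))[None, :], match, mismatch)
    for i in range(1, la + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        row = score[i]
        prev = row[0]
        up = score[i - 1]
        for j in range(1, lb + 1):
            prev = max(diag[j - 1], prev + gap, up[j] + gap)
            row[j] = prev
    # traceback, honoring the tie-break order
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        here = score[i, j]
        if i > 0 and j > 0 and here == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif j > 0 and here == score[i, j - 1] + gap:  # gap in a
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
        else:  # gap in b
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[la, lb])


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; stops appear as '*'."""
    from Bio.Seq import Seq

    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    return str(Seq(cds).translate())


def assemble_outgroup(ref_cds: str, outgroup_cds: str,
                      protein_alignment: tuple[str, str] | None = None) -> str:
    """Project an outgroup CDS into reference coordinate space.

    Guided by the protein alignment of the two translations: alignment
    columns where the reference protein has a gap are removed (the outgroup
    codon is dropped), and columns where the outgroup has a gap become
    ``---`` placeholders.  The result always has the reference CDS length.
    """
    ref_cds, outgroup_cds = ref_cds.upper(), outgroup_cds.upper()
    for name, cds in (("reference", ref_cds), ("outgroup", outgroup_cds)):
        if len(cds) % 3 != 0:
            raise ValueError(f"{name} CDS length not divisible by 3")
    ref_prot = translate_cds(ref_cds)
    out_prot = translate_cds(outgroup_cds)
    if protein_alignment is None:
        aln_ref, aln_out, _ = align_proteins_global(ref_prot, out_prot)
    else:
        aln_ref, aln_out = protein_alignment
    if aln_ref.replace("-", "") != ref_prot or aln_out.replace("-", "") != out_prot:
        raise ValueError("protein alignment does not match the CDS translations")

    ref_codons = [ref_cds[i:i + 3] for i in range(0, len(ref_cds), 3)]
    out_codons = [outgroup_cds[i:i + 3] for i in range(0, len(outgroup_cds), 3)]
    result, ri, oi = [], 0, 0
    for ra, oa in zip(aln_ref, aln_out):
        if ra == "-":        # gap in reference: drop the outgroup codon
            oi += 1
            continue
        if oa == "-":        # outgroup deletion: placeholder codon
            result.append("---")
        else:
            result.append(out_codons[oi])
            oi += 1
        ri += 1
    assembled = "".join(result)
    assert len(assembled) == len(ref_cds)
    return assembled


def diff_sequences(reference: str, variant: str, start_pos: int = 1,
                   ) -> list[tuple[int, str, str]]:
    """Positions (1-based) where variant differs from reference, with alleles."""
    if len(reference) != len(variant):
        raise ValueError("sequences differ in length")
    return [(start_pos + i, r, v)
            for i, (r, v) in enumerate(zip(reference, variant)) if r != v]
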