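"""Readers, writers and tabular types for the formats the pipeline touches.

All internal coordinates are 1-based inclusive (the GFF3 convention);
conversion to 0-based half-open happens only at format boundaries.
Only biallelic SNPs are consumed: indels and multi-allelic records are
skipped and counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

SNP_TSV_COLUMNS = ["accession", "chrom", "pos", "ref", "alt", "qual"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class GffError(ParseError):
    """Raised for structural GFF3 problems (e.g. orphaned child features)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure in chromosomal coordinates.

    Coordinates are 1-based inclusive and stored unflipped, i.e. exactly as
    annotated on the chromosome; ``strand`` records orientation.  ``exons``
    are the coding segments (taken from CDS features when read from GFF3),
    sorted by chromosomal start and pairwise non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP call in one accession."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    accession_id: str
    quality: float

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref_allele}>{self.alt_allele}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.quality < 0:
            raise ValueError("quality must be non-negative")


class SnpTable:
    """Per-accession biallelic SNP calls with Phred qualities.

    Backed by a DataFrame with columns accession/chrom/pos/ref/alt/qual.
    At most one record per (accession, chrom, pos) is allowed; duplicates
    raise on construction.
    """

    def __init__(self, df: pd.DataFrame, roster: list[str] | None = None,
                 skip_counts: dict[str, int] | None = None) -> None:
        df = df.reindex(columns=SNP_TSV_COLUMNS).reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        df["qual"] = df["qual"].astype(float)
        bad = ~(df["ref"].isin(NUCLEOTIDES) & df["alt"].isin(NUCLEOTIDES))
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records with non-ACGT alleles")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("records with ref == alt")
        dup = df.duplicated(subset=["accession", "chrom", "pos"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                "duplicate SNP record for "
                f"({first['accession']}, {first['chrom']}, {first['pos']})"
            )
        self.df = df
        if roster is None:
            roster = sorted(df["accession"].unique())
        self.roster = list(roster)
        self.skip_counts = dict(skip_counts or {})

    @classmethod
    def from_records(cls, records: list[SnpRecord], roster: list[str] | None = None,
                     **kw) -> "SnpTable":
        df = pd.DataFrame(
            [(r.accession_id, r.chrom, r.pos, r.ref_allele, r.alt_allele, r.quality)
             for r in records],
            columns=SNP_TSV_COLUMNS,
        )
        return cls(df, roster=roster, **kw)

    def __len__(self) -> int:
        return len(self.df)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield SnpRecord(row.chrom, int(row.pos), row.ref, row.alt,
                            row.accession, float(row.qual))

    def for_accession(self, accession: str) -> pd.DataFrame:
        return self.df[self.df["accession"] == accession]

    def in_interval(self, chrom: str, start: int, end: int) -> "SnpTable":
        mask = (self.df["chrom"] == chrom) & self.df["pos"].between(start, end)
        return SnpTable(self.df[mask], roster=self.roster)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        a = self.df.sort_values(["accession", "chrom", "pos"]).reset_index(drop=True)
        b = other.df.sort_values(["accession", "chrom", "pos"]).reset_index(drop=True)
        return self.roster == other.roster and a.equals(b)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read accession metadata (TSV: accession, latitude, longitude, altitude).

    Altitude is kept as text because some sources record free text there
    (e.g. "parking lot").  Latitudes outside [-90, 90] raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ParseError(f"metadata must have columns {sorted(required)}")
    df["latitude"] = df["latitude"].astype(float)
    if not df["latitude"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    return df.set_index("accession")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an RPKM expression matrix (TSV, genes x accessions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("RPKM values must be non-negative")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate gene or accession labels")
    return df


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) pairs, order kept."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: expected '>' header, got {line[:20]!r}")
                break
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3; exons come from the CDS features of the
    primary (first-by-ID) transcript, or of the gene itself when no mRNA
    feature is present."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise GffError(
                    f"feature {feat.id!r} references missing parent {parent_id!r}")

    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        parent = mrnas[0] if mrnas else gene
        cds = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            cds = sorted(db.children(gene, featuretype="CDS", level=None),
                         key=lambda f: f.start)
        genes.append(GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
            exons=tuple((f.start, f.end) for f in cds),
        ))
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + mRNA + CDS lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna_id};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={mrna_id}.cds{i};Parent={mrna_id}\n")


def read_snps(path: str | Path, dialect: str = "tsv") -> SnpTable:
    """Read SNP calls from VCF (GT genotypes) or the TSV exchange dialect.

    Only biallelic SNPs with single-nucleotide A/C/G/T ref and alt are kept;
    indels, multi-allelic sites and malformed alleles are skipped with a
    logged count (available on the returned table as ``skip_counts``).
    Heterozygous genotypes take the alt allele and are counted.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"accession": str, "chrom": str})
        missing = set(SNP_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"SNP TSV missing columns: {sorted(missing)}")
        return SnpTable(df)
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")

    import pysam

    skip = {"indel": 0, "multiallelic": 0, "bad_allele": 0, "heterozygous": 0}
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        roster = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                skip["multiallelic"] += 1
                continue
            if len(alts) == 0:
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                skip["indel"] += 1
                continue
            if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                skip["bad_allele"] += 1
                continue
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for sample in roster:
                gt = rec.samples[sample].get("GT", ())
                calls = [a for a in (gt or ()) if a is not None]
                if not calls or not any(a == 1 for a in calls):
                    continue
                if len(set(calls)) > 1:
                    skip["heterozygous"] += 1  # alt taken, per inbred-line assumption
                rows.append((sample, rec.chrom, rec.pos, ref, alt, qual))
    for key, count in skip.items():
        if count:
            logger.info("read_snps(%s): skipped/flagged %d %s records", path, count, key)
    df = pd.DataFrame(rows, columns=SNP_TSV_COLUMNS)
    return SnpTable(df, roster=roster, skip_counts=skip)


def write_snps(table: SnpTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
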