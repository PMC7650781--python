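"""Domain types and standard-format I/O for allotetraploid amplicon genotyping.

The central container is a :class:`GenotypeMatrix`: an ordered list of SNP
sites, each carrying per-accession genotype calls and allele read depths (the
VCF GT/AD fields). Coordinates are 1-based in VCF-facing fields
(:attr:`VariantSite.position`) and converted exactly once, at the I/O
boundary, to the 0-based half-open convention used internally by interval
code.

Readers and writers delegate to pysam (VCF) and Biopython (FASTA/FASTQ); all
round trips are lossless for the fields named here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("polyamp")

DNA_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")

#: IUPAC two-base ambiguity codes, keyed by the frozenset of bases they denote.
IUPAC_2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
#: Expansion of every IUPAC code to the set of plain bases it covers.
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_ALPHABET = frozenset(IUPAC_EXPAND) | frozenset("acgtryswkmbdhvn")


class PolyampError(Exception):
    """Base class for all polyamp errors."""


class ParseError(PolyampError):
    """Raised when an input file cannot be parsed."""


class FormatError(PolyampError):
    """Raised when a parsed file lacks a required field or violates a format rule."""


class DataError(PolyampError):
    """Raised when data are internally inconsistent."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleCall:
    """One accession's call at one site: diploid-style GT plus allele depths.

    ``genotype`` is a pair of allele indices into ``[ref] + alts`` (unphased),
    or ``None`` for a missing call. ``allele_depths`` has one non-negative
    count per allele, ref first, or ``None`` when AD was absent.
    """

    genotype: Optional[tuple[int, int]] = None
    allele_depths: Optional[tuple[int, ...]] = None

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]


@dataclass
class VariantSite:
    """One SNP/variant site with per-accession calls and allele depths."""

    scaffold_id: str
    position: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: list[str]
    per_sample: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(
                f"{self.scaffold_id}: position {self.position} is not 1-based"
            )
        n_alleles = 1 + len(self.alt_alleles)
        for acc, call in self.per_sample.items():
            if call.allele_depths is not None:
                if len(call.allele_depths) != n_alleles:
                    raise DataError(
                        f"{self.key}: sample {acc} has {len(call.allele_depths)} "
                        f"allele depths for {n_alleles} alleles"
                    )
                if any(d < 0 for d in call.allele_depths):
                    raise DataError(f"{self.key}: negative allele depth for {acc}")
            if call.genotype is not None and not all(
                0 <= a < n_alleles for a in call.genotype
            ):
                raise DataError(f"{self.key}: genotype index out of range for {acc}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold_id, self.position)

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele] + list(self.alt_alleles)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles)

    @property
    def summed_depth(self) -> int:
        """Total read depth: allele depths summed over alleles and accessions."""
        return sum(
            sum(c.allele_depths)
            for c in self.per_sample.values()
            if c.allele_depths is not None
        )

    def called_bases(self, accession: str) -> Optional[frozenset[str]]:
        """Set of allele strings in this accession's genotype, or None if missing."""
        call = self.per_sample.get(accession)
        if call is None or call.genotype is None:
            return None
        return frozenset(self.alleles[i] for i in call.genotype)


@dataclass(frozen=True)
class AccessionMeta:
    """Panel membership of one accession.

    ``genome_class`` is A or B for diploid progenitor-genome accessions, K for
    the related diploid genome, AB for allotetraploids carrying both
    subgenomes.
    """

    accession_id: str
    ploidy: Optional[str] = None  # "diploid" | "tetraploid"
    genome_class: Optional[str] = None  # "A" | "B" | "K" | "AB"
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ploidy == "diploid" and self.genome_class not in (None, "A", "B", "K"):
            raise DataError(
                f"{self.accession_id}: diploid genome_class must be A, B or K"
            )
        if self.ploidy == "tetraploid" and self.genome_class not in (None, "AB"):
            raise DataError(f"{self.accession_id}: tetraploid genome_class must be AB")


@dataclass
class SubgenomeSequence:
    """One reference scaffold tagged with its subgenome of origin."""

    scaffold_id: str
    subgenome: str  # "A" | "B"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"{self.scaffold_id}: empty sequence")
        bad = set(self.sequence.upper()) - set(IUPAC_EXPAND)
        if bad:
            raise DataError(
                f"{self.scaffold_id}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenotypeMatrix:
    """Ordered sites x accessions container flowing through the pipeline."""

    sites: list[VariantSite] = field(default_factory=list)
    accessions: list[AccessionMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate accession ids")
        barcodes = [a.barcode for a in self.accessions if a.barcode]
        if len(set(barcodes)) != len(barcodes):
            raise DataError("duplicate barcodes in panel")
        id_set = set(ids)
        seen: set[tuple[str, int]] = set()
        for site in self.sites:
            if site.key in seen:
                raise DataError(f"duplicate site {site.key}")
            seen.add(site.key)
            extra = set(site.per_sample) - id_set
            if extra:
                raise DataError(f"site {site.key}: unknown accessions {sorted(extra)}")

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def copy(self) -> "GenotypeMatrix":
        sites = [
            replace(s, alt_alleles=list(s.alt_alleles), per_sample=dict(s.per_sample))
            for s in self.sites
        ]
        return GenotypeMatrix(sites=sites, accessions=list(self.accessions))

    def n_het_calls(self) -> int:
        return sum(
            1 for s in self.sites for c in s.per_sample.values() if c.is_het
        )


@dataclass
class FastqRead:
    """One FASTQ record; qualities are Phred scores (integer, offset removed)."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise DataError(
                f"{self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def read_vcf(path: str, panel: Optional[Sequence[AccessionMeta]] = None) -> GenotypeMatrix:
    """Read a VCF with GT (required) and AD (optional) into a GenotypeMatrix.

    Multi-allelic rows are preserved as-is. A missing AD field yields absent
    allele depths; downstream allele-balance code reports such calls as
    unassessable rather than guessing.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path}: VCF lacks the required GT FORMAT field")
        sample_ids = list(vcf.header.samples)
        meta = {a.accession_id: a for a in panel or []}
        accessions = [meta.get(s, AccessionMeta(accession_id=s)) for s in sample_ids]
        sites: list[VariantSite] = []
        for rec in vcf:
            per_sample: dict[str, SampleCall] = {}
            for sid in sample_ids:
                s = rec.samples[sid]
                gt = s.get("GT")
                genotype = None
                if gt is not None and len(gt) == 2 and None not in gt:
                    genotype = (gt[0], gt[1])
                ad = s.get("AD")
                depths = None
                if ad is not None and not all(d is None for d in ad):
                    depths = tuple(int(d) if d is not None else 0 for d in ad)
                per_sample[sid] = SampleCall(genotype=genotype, allele_depths=depths)
            sites.append(
                VariantSite(
                    scaffold_id=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or []),
                    per_sample=per_sample,
                )
            )
    return GenotypeMatrix(sites=sites, accessions=accessions)


def write_vcf(matrix: GenotypeMatrix, path: str, extra_header: Iterable[str] = ()) -> None:
    """Write a GenotypeMatrix as a plain-text VCF 4.2 with GT, AD and DP."""
    import pysam

    header = pysam.VariantHeader()
    for line in extra_header:
        header.add_line(f"##{line}")
    contigs = []
    for site in matrix.sites:
        if site.scaffold_id not in contigs:
            contigs.append(site.scaffold_id)
    for c in contigs:
        header.contigs.add(c)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref first)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for acc in matrix.accession_ids:
        header.add_sample(acc)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in matrix.sites:
            rec = out.new_record(
                contig=site.scaffold_id,
                start=site.position - 1,  # pysam takes 0-based start
                alleles=tuple(site.alleles),
            )
            for acc in matrix.accession_ids:
                call = site.per_sample.get(acc, SampleCall())
                s = rec.samples[acc]
                if call.genotype is None:
                    s["GT"] = (None, None)
                else:
                    s["GT"] = call.genotype
                if call.allele_depths is not None:
                    s["AD"] = call.allele_depths
                    s["DP"] = sum(call.allele_depths)
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping; duplicate ids error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> list[FastqRead]:
    """Read FASTQ (Phred+33) into FastqRead records."""
    reads: list[FastqRead] = []
    try:
        for rec in SeqIO.parse(path, "fastq"):
            reads.append(
                FastqRead(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ParseError(f"cannot parse FASTQ {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, path, "fastq")
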