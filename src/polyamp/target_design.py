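"""Homoeolog-aware amplicon target design.

Pipeline: pair each A-subgenome scaffold with its best homoeologous
B-subgenome scaffold from tabular alignment hits, find windows polymorphic
in *both* subgenomes (so one amplicon interrogates both), extract
SNP-containing sequence with flanks, and emit an IUPAC consensus of the
paired A/B sequences so that one primer pair amplifies both subgenomes
simultaneously.

Scaffold pairing consumes a standard 12-column tabular hit file (qseqid
sseqid pident length mismatch gapopen qstart qend sstart send evalue
bitscore) from any aligner; :func:`align_pair` provides a small built-in
Smith-Waterman for self-contained, test-scale runs. B-side coordinates are
mapped through the best hit's aligned span by constant offset — adequate at
scaffold-pairing granularity, a documented limitation for indel-rich pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_model import (
    IUPAC_2,
    DataError,
    SubgenomeSequence,
    VariantSite,
    logger,
)


@dataclass(frozen=True)
class HomoeologHit:
    """One alignment hit between an A-subgenome and a B-subgenome scaffold.

    Coordinates are 0-based half-open on each scaffold; ``strand`` is "-"
    when the B-side span is on the reverse strand.
    """

    a_scaffold: str
    b_scaffold: str
    alignment_length: int
    identity: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise DataError("alignment_length must be >= 1")

    @property
    def score(self) -> float:
        return self.identity * self.alignment_length

    def map_a_to_b(self, a_pos: int) -> int:
        """Map a 1-based A-scaffold position into B-scaffold coordinates by
        constant offset within the aligned span."""
        if self.strand == "+":
            return self.b_start + 1 + (a_pos - (self.a_start + 1))
        return self.b_end - (a_pos - (self.a_start + 1))


@dataclass
class TargetRegion:
    """One designed amplicon target: paired A/B intervals, constituent SNPs
    and the IUPAC consensus used for primer design and read mapping."""

    target_id: str
    a_interval: tuple[str, int, int]  # (scaffold, start, end) 0-based half-open
    b_interval: tuple[str, int, int]
    snps_a: list[VariantSite] = field(default_factory=list)
    snps_b: list[VariantSite] = field(default_factory=list)
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.a_interval[2] - self.a_interval[1]


@dataclass
class CandidateRegion:
    """A co-targeted window with >=2 SNPs on each subgenome."""

    a_scaffold: str
    b_scaffold: str
    anchor_pos: int  # 1-based A-scaffold anchor SNP
    snps_a: list[VariantSite] = field(default_factory=list)
    snps_b: list[VariantSite] = field(default_factory=list)


def read_hits_tsv(path: str) -> list[HomoeologHit]:
    """Parse a 12-column tabular alignment hit file into HomoeologHits.

    Subject coordinates with sstart > send denote reverse-strand hits and are
    normalised to forward coordinates with strand "-".
    """
    hits: list[HomoeologHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise DataError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            q, s, pident, length, _mm, _go, qs, qe, ss, se = parts[:10]
            qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            hits.append(
                HomoeologHit(
                    a_scaffold=q,
                    b_scaffold=s,
                    alignment_length=int(length),
                    identity=float(pident) / 100.0,
                    a_start=qs - 1,
                    a_end=qe,
                    b_start=ss - 1,
                    b_end=se,
                    strand=strand,
                )
            )
    return hits


def pair_scaffolds(
    hits: Iterable[HomoeologHit], min_len: int = 350
) -> tuple[dict[str, HomoeologHit], list[str], set[str]]:
    """Choose, per A scaffold, the best qualifying hit to a B scaffold.

    Hits qualify when alignment_length is strictly greater than ``min_len``;
    the best is the one maximising identity x alignment_length, ties broken
    toward the lexicographically smaller b_scaffold and flagged. Returns
    (pairing, unpaired A scaffolds, tie-flagged A scaffolds).
    """
    by_a: dict[str, list[HomoeologHit]] = {}
    for h in hits:
        by_a.setdefault(h.a_scaffold, []).append(h)
    pairing: dict[str, HomoeologHit] = {}
    unpaired: list[str] = []
    ties: set[str] = set()
    for a_scaffold, group in by_a.items():
        eligible = [h for h in group if h.alignment_length > min_len]
        if not eligible:
            unpaired.append(a_scaffold)
            continue
        best_score = max(h.score for h in eligible)
        best = sorted(
            (h for h in eligible if h.score == best_score),
            key=lambda h: h.b_scaffold,
        )
        if len(best) > 1 and best[0].b_scaffold != best[1].b_scaffold:
            ties.add(a_scaffold)
            logger.info("pair_scaffolds: tie for %s, chose %s", a_scaffold,
                        best[0].b_scaffold)
        pairing[a_scaffold] = best[0]
    return pairing, unpaired, ties


def align_pair(
    seq_a: str,
    seq_b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    a_scaffold: str = "A",
    b_scaffold: str = "B",
) -> HomoeologHit:
    """Optimal local (Smith-Waterman) alignment of two sequences.

    A small built-in aligner for self-contained test-scale runs; real-scale
    users supply a tabular hit file from a dedicated aligner. Traceback is
    deterministic: at equal scores diagonal is preferred over up (gap in b)
    over left (gap in a); the endpoint is the first maximal cell in row-major
    order.
    """
    if not seq_a or not seq_b:
        raise DataError("align_pair requires two non-empty sequences")
    a = seq_a.upper()
    b = seq_b.upper()
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    # pointers: 0 stop, 1 diagonal, 2 up, 3 left
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        prow = P[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            best = diag
            ptr = 1
            if up > best:
                best, ptr = up, 2
            if left > best:
                best, ptr = left, 3
            if best <= 0:
                best, ptr = 0, 0
            row[j] = best
            prow[j] = ptr
    end = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(end[0]), int(end[1])
    a_end, b_end = i, j
    cols = matches = 0
    while i > 0 and j > 0 and P[i, j] != 0:
        ptr = P[i, j]
        cols += 1
        if ptr == 1:
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif ptr == 2:
            i -= 1
        else:
            j -= 1
    if cols == 0:
        # no positive-scoring extension; report a 1-column null hit
        return HomoeologHit(a_scaffold, b_scaffold, 1, 0.0, 0, 1, 0, 1)
    return HomoeologHit(
        a_scaffold=a_scaffold,
        b_scaffold=b_scaffold,
        alignment_length=cols,
        identity=matches / cols,
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
    )


def cotarget_regions(
    snps_a: Sequence[VariantSite],
    snps_b: Sequence[VariantSite],
    pairing: dict[str, HomoeologHit],
    window: int = 100,
) -> list[CandidateRegion]:
    """Windows with multiple SNPs in both subgenomes.

    For every A-scaffold SNP taken as anchor, collect A SNPs within +/-
    ``window`` bp of the anchor and B SNPs (on the paired scaffold) within
    the same window mapped through the pairing hit. A candidate requires at
    least two SNPs on each side. Identical SNP sets arising from different
    anchors are de-duplicated; SNPs on unpaired scaffolds are skipped with a
    log entry.
    """
    b_by_scaffold: dict[str, list[VariantSite]] = {}
    for s in snps_b:
        b_by_scaffold.setdefault(s.scaffold_id, []).append(s)
    regions: list[CandidateRegion] = []
    seen: set[tuple] = set()
    for anchor in snps_a:
        hit = pairing.get(anchor.scaffold_id)
        if hit is None:
            logger.info("cotarget_regions: %s unpaired; anchor at %d skipped",
                        anchor.scaffold_id, anchor.position)
            continue
        in_a = [
            s for s in snps_a
            if s.scaffold_id == anchor.scaffold_id
            and abs(s.position - anchor.position) <= window
        ]
        b_center = hit.map_a_to_b(anchor.position)
        in_b = [
            s for s in b_by_scaffold.get(hit.b_scaffold, [])
            if abs(s.position - b_center) <= window
        ]
        if len(in_a) < 2 or len(in_b) < 2:
            continue
        sig = (
            anchor.scaffold_id,
            frozenset(s.position for s in in_a),
            frozenset(s.position for s in in_b),
        )
        if sig in seen:
            continue
        seen.add(sig)
        regions.append(
            CandidateRegion(
                a_scaffold=anchor.scaffold_id,
                b_scaffold=hit.b_scaffold,
                anchor_pos=anchor.position,
                snps_a=sorted(in_a, key=lambda s: s.position),
                snps_b=sorted(in_b, key=lambda s: s.position),
            )
        )
    return regions


@dataclass(frozen=True)
class FlankExtract:
    """A SNP-containing subsequence with the SNP's 0-based local offset."""

    sequence: str
    snp_offset: int
    start: int  # 0-based half-open interval on the source scaffold
    end: int


def extract_flanks(
    ref: SubgenomeSequence, site: VariantSite, flank: int = 1000
) -> FlankExtract:
    """Extract ``flank`` bp up- and downstream of a SNP, clipped at scaffold
    ends. Raises DataError when the position lies outside the scaffold."""
    if not 1 <= site.position <= len(ref):
        raise DataError(
            f"{site.key}: position outside scaffold {ref.scaffold_id} "
            f"(length {len(ref)})"
        )
    pos0 = site.position - 1
    start = max(0, pos0 - flank)
    end = min(len(ref), pos0 + flank + 1)
    return FlankExtract(
        sequence=ref.sequence[start:end],
        snp_offset=pos0 - start,
        start=start,
        end=end,
    )


def consensus_target(seq_a: str, seq_b: str) -> str:
    """IUPAC consensus of two aligned equal-length sequences.

    Matching columns copy the base; mismatching ACGT columns get the two-base
    ambiguity code; a gap column yields the lower-case base of the non-gap
    sequence; anything else (N, shared gaps) yields N. The ambiguity count
    equals the Hamming distance over non-gap columns.
    """
    if len(seq_a) != len(seq_b):
        raise DataError(
            f"consensus requires aligned equal-length inputs "
            f"({len(seq_a)} vs {len(seq_b)})"
        )
    out = []
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == y and x != "-":
            out.append(x)
        elif x == "-" and y != "-":
            out.append(y.lower())
        elif y == "-" and x != "-":
            out.append(x.lower())
        else:
            out.append(IUPAC_2.get(frozenset((x, y)), "N"))
    return "".join(out)


def build_targets(
    regions: Sequence[CandidateRegion],
    a_refs: dict[str, SubgenomeSequence],
    b_refs: dict[str, SubgenomeSequence],
    pairing: dict[str, HomoeologHit],
    len_min: int = 300,
    len_max: int = 450,
    id_prefix: str = "target",
) -> list[TargetRegion]:
    """Turn candidate regions into fixed-size consensus amplicon targets.

    The A-side interval spans the region's SNPs; spans longer than
    ``len_max`` are trimmed to the ``len_max`` window holding the most SNPs
    (leftmost on ties), shorter spans are extended symmetrically to
    ``len_min``, clipping at scaffold ends. The B interval is the constant-
    offset image of the A interval; regions whose final window loses all
    SNPs on either side, or cannot reach ``len_min``, are skipped with a log
    entry.
    """
    targets: list[TargetRegion] = []
    for k, region in enumerate(regions, 1):
        a_ref = a_refs[region.a_scaffold]
        b_ref = b_refs[region.b_scaffold]
        hit = pairing[region.a_scaffold]
        positions = sorted(s.position - 1 for s in region.snps_a)  # 0-based
        lo, hi = positions[0], positions[-1] + 1
        span = hi - lo
        if span > len_max:
            # densest len_max window over the SNP positions, leftmost on ties
            best_start, best_n = lo, 0
            for p in positions:
                n = sum(1 for q in positions if p <= q < p + len_max)
                if n > best_n:
                    best_start, best_n = p, n
            lo, hi = best_start, best_start + len_max
        elif span < len_min:
            pad = len_min - span
            lo = lo - pad // 2
            hi = hi + (pad - pad // 2)
            if lo < 0:
                hi -= lo
                lo = 0
            if hi > len(a_ref):
                lo -= hi - len(a_ref)
                hi = len(a_ref)
                lo = max(0, lo)
        if hi - lo < len_min:
            logger.info("build_targets: region %d too short after clipping; skipped", k)
            continue
        b_lo = hit.map_a_to_b(lo + 1) - 1
        b_hi = b_lo + (hi - lo)
        if b_lo < 0 or b_hi > len(b_ref):
            logger.info("build_targets: region %d B interval out of bounds; skipped", k)
            continue
        snps_a = [s for s in region.snps_a if lo < s.position <= hi]
        snps_b = [
            s for s in region.snps_b if b_lo < s.position <= b_hi
        ]
        if not snps_a or not snps_b:
            logger.info("build_targets: region %d lost its SNPs in trimming; skipped", k)
            continue
        consensus = consensus_target(
            a_ref.sequence[lo:hi], b_ref.sequence[b_lo:b_hi]
        )
        targets.append(
            TargetRegion(
                target_id=f"{id_prefix}{k:03d}",
                a_interval=(region.a_scaffold, lo, hi),
                b_interval=(region.b_scaffold, b_lo, b_hi),
                snps_a=snps_a,
                snps_b=snps_b,
                consensus=consensus,
            )
        )
    return targets


def write_targets_bed(targets: Sequence[TargetRegion], path: str) -> None:
    """BED of both subgenome intervals per target (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\ttarget_id\tsubgenome\n")
        for t in targets:
            for (scaf, start, end), tag in ((t.a_interval, "A"), (t.b_interval, "B")):
                fh.write(f"{scaf}\t{start}\t{end}\t{t.target_id}\t{tag}\n")


def write_targets_tsv(targets: Sequence[TargetRegion], path: str) -> None:
    """Per-target SNP inventory."""
    with open(path, "w") as fh:
        fh.write("target_id\tsubgenome\tscaffold\tposition\tref\talt\n")
        for t in targets:
            for tag, snps in (("A", t.snps_a), ("B", t.snps_b)):
                for s in snps:
                    fh.write(
                        f"{t.target_id}\t{tag}\t{s.scaffold_id}\t{s.position}\t"
                        f"{s.ref_allele}\t{','.join(s.alt_alleles)}\n"
                    )
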