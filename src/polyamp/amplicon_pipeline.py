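"""Self-contained amplicon genotyping: demultiplex -> merge -> align -> call.

Replaces the conventional external tool chain (barcode splitter, read
merger, genome aligner, variant caller) with minimal transparent
equivalents so the allele-balance signal the downstream correction relies on
is fully auditable. Externally produced VCFs can still enter the correction
step directly through :func:`polyamp.core_model.read_vcf`.

Reads are assigned to their accession by barcode prefix (Hamming distance),
merged with their mate by best overlap, semi-globally aligned against every
pooled consensus target (free end gaps on the target; IUPAC ambiguity
positions in the consensus match either underlying base) and piled up
per-position, per-accession. Genotypes are then called with a transparent
frequency caller: alleles at fraction >= ``min_alt_frac`` in a column with
depth >= ``min_depth`` are reported, one passing allele making a homozygote
and two a heterozygote, with AD recorded from the counts.

Alignment uses edlib (edit distance, infix mode); amplicons span their
targets end to end, so semi-global rather than local alignment is
appropriate, and reverse-strand mapping is unnecessary because merged
amplicon reads are oriented by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .core_model import (
    IUPAC_EXPAND,
    AccessionMeta,
    DataError,
    FastqRead,
    GenotypeMatrix,
    SampleCall,
    VariantSite,
    logger,
    revcomp,
)

BASE_ROWS = "ACGTN"
_ROW = {b: i for i, b in enumerate(BASE_ROWS)}

#: edlib equality pairs letting IUPAC codes in a consensus match their bases.
IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_EXPAND.items()
    if len(bases) > 1
    for base in bases
]


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    read_pairs: Sequence[tuple[FastqRead, FastqRead]],
    panel: Sequence[AccessionMeta],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[tuple[FastqRead, FastqRead]]], list[tuple[FastqRead, FastqRead]]]:
    """Assign read pairs to accessions by the R1 barcode prefix.

    A pair is assigned when exactly one panel barcode lies within Hamming
    distance ``max_mismatch`` of the R1 prefix at minimal distance; ambiguous
    (equidistant) or distant prefixes go to the unassigned bin. The barcode
    prefix is stripped from assigned R1 reads. Duplicate or unequal-length
    barcodes are an error at load.
    """
    barcodes = {a.accession_id: a.barcode for a in panel}
    if any(bc is None for bc in barcodes.values()):
        raise DataError("every accession needs a barcode for demultiplexing")
    lengths = {len(bc) for bc in barcodes.values()}
    if len(lengths) != 1:
        raise DataError("barcodes must share one length")
    if len(set(barcodes.values())) != len(barcodes):
        raise DataError("duplicate barcodes in panel")
    bc_len = lengths.pop()
    assigned: dict[str, list[tuple[FastqRead, FastqRead]]] = {
        a.accession_id: [] for a in panel
    }
    unassigned: list[tuple[FastqRead, FastqRead]] = []
    for r1, r2 in read_pairs:
        prefix = r1.sequence[:bc_len]
        best_acc: Optional[str] = None
        best_d = max_mismatch + 1
        ambiguous = False
        for acc, bc in barcodes.items():
            d = _hamming(prefix, bc)
            if d < best_d:
                best_acc, best_d, ambiguous = acc, d, False
            elif d == best_d:
                ambiguous = True
        if best_acc is None or ambiguous or best_d > max_mismatch:
            unassigned.append((r1, r2))
            continue
        stripped = FastqRead(
            read_id=r1.read_id,
            sequence=r1.sequence[bc_len:],
            qualities=r1.qualities[bc_len:],
        )
        assigned[best_acc].append((stripped, r2))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

@dataclass
class MergedRead:
    """A merged forward/reverse pair reconstructing one amplicon fragment."""

    accession_id: str
    sequence: str
    qualities: list[int]
    overlap_len: int


def merge_pairs(
    fwd: FastqRead,
    rev: FastqRead,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
    accession_id: str = "",
) -> Optional[MergedRead]:
    """Merge a read pair by best overlap; None when no overlap qualifies.

    The reverse read is reverse-complemented, then every overlap length from
    ``min_overlap`` up to the shorter read is scored; among overlaps whose
    mismatch rate is <= ``max_mismatch_rate`` the one with the most matching
    bases wins (ties: fewer mismatches, then longer overlap). Conflicting
    overlap bases resolve toward the higher base quality, ties toward the
    forward base; overlap qualities take the higher of the two.
    """
    rc_seq = revcomp(rev.sequence)
    rc_qual = rev.qualities[::-1]
    f = np.frombuffer(fwd.sequence.encode(), dtype=np.uint8)
    r = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
    max_o = min(len(f), len(r))
    best: Optional[tuple[int, int, int]] = None  # (matches, -mismatches, overlap)
    for o in range(min_overlap, max_o + 1):
        eq = f[len(f) - o:] == r[:o]
        matches = int(eq.sum())
        mismatches = o - matches
        if mismatches / o > max_mismatch_rate:
            continue
        cand = (matches, -mismatches, o)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    o = best[2]
    f_tail = fwd.sequence[len(f) - o:]
    fq_tail = fwd.qualities[len(f) - o:]
    overlap_seq = []
    overlap_qual = []
    for k in range(o):
        if f_tail[k] == rc_seq[k]:
            overlap_seq.append(f_tail[k])
        elif rc_qual[k] > fq_tail[k]:
            overlap_seq.append(rc_seq[k])
        else:
            overlap_seq.append(f_tail[k])
        overlap_qual.append(max(fq_tail[k], rc_qual[k]))
    sequence = fwd.sequence[: len(f) - o] + "".join(overlap_seq) + rc_seq[o:]
    qualities = fwd.qualities[: len(f) - o] + overlap_qual + rc_qual[o:]
    return MergedRead(
        accession_id=accession_id,
        sequence=sequence,
        qualities=qualities,
        overlap_len=o,
    )


# ---------------------------------------------------------------------------
# Target assignment and pileup
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    """Per-position base counts for one target, split by accession.

    ``counts[accession]`` is a (length x 5) array over A, C, G, T, N. Reads
    beyond ``depth_cap`` for an accession are not counted (the cap bounds
    per-position depth because every merged amplicon read spans the whole
    target).
    """

    target_id: str
    length: int
    depth_cap: int = 4000
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    n_reads: dict[str, int] = field(default_factory=dict)

    def accession_counts(self, accession: str) -> np.ndarray:
        if accession not in self.counts:
            self.counts[accession] = np.zeros((self.length, 5), dtype=np.int64)
            self.n_reads[accession] = 0
        return self.counts[accession]


def align_to_target(read_seq: str, target_seq: str) -> tuple[int, Optional[dict]]:
    """Edit distance and alignment path of a merged read against one target
    (semi-global: free end gaps on the target; IUPAC codes match either
    base)."""
    res = edlib.align(
        read_seq,
        target_seq.upper(),
        mode="HW",
        task="path",
        additionalEqualities=IUPAC_EQUALITIES,
    )
    return res["editDistance"], res


def _project(read_seq: str, res: dict, counts: np.ndarray) -> None:
    """Accumulate a read's bases onto target columns along the edlib path."""
    t_pos = res["locations"][0][0]
    r_pos = 0
    cigar = res["cigar"]
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for k in range(n):
                counts[t_pos + k, _ROW.get(read_seq[r_pos + k], 4)] += 1
            t_pos += n
            r_pos += n
        elif ch == "I":  # extra read bases: consume read only
            r_pos += n
        elif ch == "D":  # target bases absent from read
            t_pos += n


def assign_and_pileup(
    merged: dict[str, Iterable[MergedRead]],
    targets: dict[str, str],
    depth_cap: int = 4000,
) -> tuple[dict[str, Pileup], int]:
    """Assign each merged read to its best-scoring target and pile up bases.

    Every read is aligned against every target; the unique minimum edit
    distance wins, ties leave the read unassigned (logged). Returns pileups
    keyed by target id and the number of unassigned reads.
    """
    if not targets:
        raise DataError("no targets to align against")
    target_items = sorted(targets.items())
    pileups = {
        tid: Pileup(target_id=tid, length=len(seq), depth_cap=depth_cap)
        for tid, seq in target_items
    }
    n_unassigned = 0
    for accession, reads in merged.items():
        for read in reads:
            best_tid: Optional[str] = None
            best_res: Optional[dict] = None
            best_d = None
            tie = False
            for tid, seq in target_items:
                d, res = align_to_target(read.sequence, seq)
                if best_d is None or d < best_d:
                    best_tid, best_res, best_d, tie = tid, res, d, False
                elif d == best_d:
                    tie = True
            if tie:
                n_unassigned += 1
                continue
            pile = pileups[best_tid]
            if pile.n_reads.get(accession, 0) >= pile.depth_cap:
                continue
            counts = pile.accession_counts(accession)
            _project(read.sequence, best_res, counts)
            pile.n_reads[accession] += 1
    if n_unassigned:
        logger.info("assign_and_pileup: %d reads unassigned (score ties)", n_unassigned)
    return pileups, n_unassigned


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def reference_base(consensus_base: str) -> str:
    """Concrete reference base for a consensus column: the alphabetically
    first expansion of its IUPAC code."""
    return min(IUPAC_EXPAND[consensus_base.upper()])


def call_variants(
    pileups: dict[str, Pileup],
    targets: dict[str, str],
    panel: Sequence[AccessionMeta],
    min_depth: int = 20,
    min_alt_frac: float = 0.05,
) -> GenotypeMatrix:
    """Frequency-based genotype caller over target pileups.

    Per column and accession: the call is missing below ``min_depth``;
    otherwise alleles (ACGT) at fraction >= ``min_alt_frac`` are kept — one
    passing allele gives a homozygote, two a heterozygote, more than two keep
    the two deepest (logged). A site is emitted for every column where any
    accession carries a passing non-reference allele; calls are diploid-style
    regardless of ploidy, matching how co-mapping subgenome reads present.
    """
    acc_ids = [a.accession_id for a in panel]
    sites: list[VariantSite] = []
    for tid in sorted(pileups):
        pile = pileups[tid]
        consensus = targets[tid].upper()
        for pos in range(pile.length):
            ref = reference_base(consensus[pos])
            passing: dict[str, list[str]] = {}
            any_alt = False
            for acc in acc_ids:
                counts = pile.counts.get(acc)
                if counts is None:
                    continue
                col = counts[pos, :4]  # ACGT only; N never becomes an allele
                depth = int(counts[pos].sum())
                if depth < min_depth:
                    continue
                keep = [
                    BASE_ROWS[i]
                    for i in range(4)
                    if col[i] > 0 and col[i] / depth >= min_alt_frac
                ]
                if len(keep) > 2:
                    keep = sorted(keep, key=lambda b: (-col[_ROW[b]], b))[:2]
                    logger.info(
                        "call_variants: %s:%d %s has >2 passing alleles; kept %s",
                        tid, pos + 1, acc, keep,
                    )
                if not keep:
                    continue
                passing[acc] = sorted(keep)
                if any(b != ref for b in keep):
                    any_alt = True
            if not any_alt:
                continue
            depth_totals: dict[str, int] = {}
            for acc in passing:
                col = pile.counts[acc][pos, :4]
                for i, b in enumerate(BASE_ROWS[:4]):
                    if b != ref:
                        depth_totals[b] = depth_totals.get(b, 0) + int(col[i])
            alts = sorted(
                {b for bases in passing.values() for b in bases if b != ref},
                key=lambda b: (-depth_totals.get(b, 0), b),
            )
            alleles = [ref] + alts
            index = {b: i for i, b in enumerate(alleles)}
            per_sample: dict[str, SampleCall] = {}
            for acc in acc_ids:
                counts = pile.counts.get(acc)
                if counts is None or int(counts[pos].sum()) < min_depth:
                    per_sample[acc] = SampleCall()
                    continue
                depths = tuple(int(counts[pos, _ROW[b]]) for b in alleles)
                bases = passing.get(acc)
                if not bases:
                    per_sample[acc] = SampleCall(genotype=None, allele_depths=depths)
                    continue
                if len(bases) == 1:
                    gt = (index[bases[0]], index[bases[0]])
                else:
                    gt = tuple(sorted((index[bases[0]], index[bases[1]])))
                per_sample[acc] = SampleCall(genotype=gt, allele_depths=depths)
            sites.append(
                VariantSite(
                    scaffold_id=tid,
                    position=pos + 1,
                    ref_allele=ref,
                    alt_alleles=alts,
                    per_sample=per_sample,
                )
            )
    return GenotypeMatrix(sites=sites, accessions=list(panel))


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    """Read accounting for one run (totals are conserved: assigned +
    unassigned-barcode + merge-failed + unassigned-target = input pairs)."""

    n_pairs: int
    n_barcode_unassigned: int
    n_merge_failed: int
    n_target_unassigned: int
    n_counted: int
    per_accession: dict[str, int]


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix
    pileups: dict[str, Pileup]
    report: PipelineReport


def run_pipeline(
    r1: Sequence[FastqRead],
    r2: Sequence[FastqRead],
    panel: Sequence[AccessionMeta],
    targets: dict[str, str],
    max_barcode_mismatch: int = 1,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
    depth_cap: int = 4000,
    min_depth: int = 20,
    min_alt_frac: float = 0.05,
) -> PipelineResult:
    """Demultiplex, merge, align and call genotypes for one amplicon run."""
    if len(r1) != len(r2):
        raise DataError(f"R1/R2 pair count mismatch ({len(r1)} vs {len(r2)})")
    pairs = list(zip(r1, r2))
    assigned, unassigned = demultiplex(pairs, panel, max_mismatch=max_barcode_mismatch)
    merged: dict[str, list[MergedRead]] = {}
    n_merge_failed = 0
    for acc, acc_pairs in assigned.items():
        out = []
        for fwd, rev in acc_pairs:
            m = merge_pairs(
                fwd, rev,
                min_overlap=min_overlap,
                max_mismatch_rate=max_mismatch_rate,
                accession_id=acc,
            )
            if m is None:
                n_merge_failed += 1
            else:
                out.append(m)
        merged[acc] = out
    pileups, n_target_unassigned = assign_and_pileup(merged, targets, depth_cap=depth_cap)
    matrix = call_variants(
        pileups, targets, panel, min_depth=min_depth, min_alt_frac=min_alt_frac
    )
    per_acc = {acc: len(reads) for acc, reads in merged.items()}
    n_counted = sum(per_acc.values()) - n_target_unassigned
    report = PipelineReport(
        n_pairs=len(pairs),
        n_barcode_unassigned=len(unassigned),
        n_merge_failed=n_merge_failed,
        n_target_unassigned=n_target_unassigned,
        n_counted=n_counted,
        per_accession=per_acc,
    )
    logger.info(
        "pipeline: %d pairs, %d barcode-unassigned, %d merge-failed, "
        "%d target-unassigned", report.n_pairs, report.n_barcode_unassigned,
        report.n_merge_failed, report.n_target_unassigned,
    )
    return PipelineResult(matrix=matrix, pileups=pileups, report=report)
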