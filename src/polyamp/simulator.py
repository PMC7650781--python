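"""Seeded simulator of allotetraploid amplicon panels with ground truth.

The generator emulates the structure of a targeted amplicon experiment on a
selfed allotetraploid panel:

* each target is an ancestor sequence (uniform ACGT, configurable GC)
  diverged into an A and a B subgenome copy by 4-5 fixed substitutions —
  the near-identical homoeolog regime that makes co-mapping hard;
* a fraction of targets carry paralogous copies of the A sequence
  (37/48 of targets, averaging 3.81 copies per target across the panel),
  each at high identity, optionally heterozygous in some accessions at one
  internal site — the source of 25%/75% allele-balance peaks;
* accessions are selfed lines: diploid A, diploid B (each homozygous at
  every site of their single subgenome) and tetraploids carrying both
  subgenome copies; homologous SNPs are planted per subgenome at a chosen
  minor-allele frequency;
* reads are barcoded 2 x 250 bp overlapping pairs drawn uniformly over an
  accession's haplotypes (two per gene copy), with a substitution-biased
  error model (default G->A 1.38%, A->T 0.84%, 0.1% elsewhere) inflated
  over the final fifth of each read.

Every emitted read has exactly one truth record, and the collapsed truth
genotypes are exposed as a :class:`~polyamp.core_model.GenotypeMatrix` in
consensus-target coordinates, so every pipeline stage can be scored without
external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    AccessionMeta,
    DataError,
    FastqRead,
    GenotypeMatrix,
    SampleCall,
    VariantSite,
    revcomp,
)
from .target_design import consensus_target

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {b: i for i, b in enumerate("ACGT")}

#: Default per-substitution error rates (from-base, to-base) -> fraction.
DEFAULT_ERROR_MATRIX = {("G", "A"): 0.0138, ("A", "T"): 0.0084}
DEFAULT_OTHER_RATE = 0.001


def full_error_matrix(
    overrides: Optional[dict[tuple[str, str], float]] = None,
    other_rate: float = DEFAULT_OTHER_RATE,
) -> dict[tuple[str, str], float]:
    """All 12 ordered substitution rates: defaults plus overrides."""
    mat = {
        (x, y): other_rate for x in "ACGT" for y in "ACGT" if x != y
    }
    mat.update(DEFAULT_ERROR_MATRIX)
    if overrides is not None:
        mat.update(overrides)
    for pair, rate in mat.items():
        if not 0.0 <= rate <= 1.0:
            raise DataError(f"error rate for {pair} outside [0, 1]")
    return mat


def zero_error_matrix() -> dict[tuple[str, str], float]:
    return {(x, y): 0.0 for x in "ACGT" for y in "ACGT" if x != y}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic panel.

    Defaults mirror the experiment the simulator emulates: 48 targets of
    300-450 bp differing by 4-5 fixed substitutions between subgenomes, a 48-
    accession panel (12 diploids, 36 tetraploids), 2 x 250 bp reads, paralogs
    on 37/48 of targets averaging 3.81 copies per target. Depth per
    accession-target (200 read pairs) is a desk-scale choice — deep enough
    that the summed-depth selection filter (> 100) is meaningful.
    """

    seed: int
    n_targets: int = 48
    target_len: tuple[int, int] = (300, 450)
    divergence: tuple[int, int] = (4, 5)
    paralog_fraction: float = 37 / 48
    paralog_mean: float = 3.81
    paralog_identity: float = 0.99
    paralog_het_prob: float = 0.10
    n_diploid_a: int = 6
    n_diploid_b: int = 6
    n_tetraploid: int = 36
    snps_per_subgenome: int = 2
    snp_maf: tuple[float, float] = (0.1, 0.5)
    read_len: int = 250
    reads_per_target_per_accession: int = 200
    error_matrix: dict[tuple[str, str], float] = field(default_factory=full_error_matrix)
    end_error_multiplier: float = 3.0
    end_fraction: float = 0.2
    barcode_len: int = 10
    base_quality: int = 30
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataError("seed is mandatory")
        if self.n_targets < 1:
            raise DataError("n_targets must be >= 1")
        lo, hi = self.target_len
        if not 0 < lo <= hi:
            raise DataError("invalid target_len band")
        if self.divergence[0] > self.divergence[1] or self.divergence[0] < 0:
            raise DataError("invalid divergence range")
        for name in ("paralog_fraction", "paralog_identity", "paralog_het_prob",
                     "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} outside [0, 1]")
        for pair, rate in self.error_matrix.items():
            if not 0.0 <= rate <= 1.0:
                raise DataError(f"error rate {pair} outside [0, 1]")
        if self.read_len < self.barcode_len + 1:
            raise DataError("read_len must exceed barcode_len")
        # merged coverage must span the target: genomic R1 + R2 >= max length
        if 2 * self.read_len - self.barcode_len < self.target_len[1]:
            raise DataError(
                "read pairs cannot span the longest target; reduce target_len "
                "or raise read_len"
            )


@dataclass(frozen=True)
class TruthSNP:
    """A planted homologous SNP on one subgenome copy of a target."""

    target_id: str
    subgenome: str  # "A" | "B"
    position: int  # 1-based on the target/consensus
    ref: str
    alt: str
    maf: float


@dataclass
class ParalogTruth:
    """One paralogous copy of a target's A sequence.

    ``het_position`` (0-based) is the copy's internal variable site;
    ``het_accessions`` lists accessions heterozygous there (one of their two
    paralog haplotypes carries ``het_alt``).
    """

    paralog_id: str
    target_id: str
    sequence: str
    het_position: Optional[int] = None
    het_alt: Optional[str] = None
    het_accessions: frozenset[str] = frozenset()


@dataclass
class TargetTruth:
    target_id: str
    a_seq: str
    b_seq: str
    consensus: str
    fixed_positions: list[tuple[int, str, str]]  # (0-based pos, a_base, b_base)
    snps: list[TruthSNP] = field(default_factory=list)
    paralogs: list[ParalogTruth] = field(default_factory=list)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    accession_id: str
    target_id: str
    hap_kind: str  # "A", "B" or a paralog id
    errors_r1: tuple[int, ...]  # 0-based positions within R1 (incl. barcode)
    errors_r2: tuple[int, ...]


@dataclass
class SimTruth:
    """Everything the simulator knows: sequences, haplotypes, genotypes and
    planted error events."""

    config: SimConfig
    panel: list[AccessionMeta]
    targets: dict[str, TargetTruth]
    haplotypes: dict[tuple[str, str], list[tuple[str, str]]]  # (acc, tid) -> [(kind, seq)]
    genotype_matrix: GenotypeMatrix  # collapsed truth in consensus coordinates
    read_log: list[ReadTruth] = field(default_factory=list)

    @property
    def consensus_targets(self) -> dict[str, str]:
        return {tid: t.consensus for tid, t in self.targets.items()}


@dataclass
class SimResult:
    truth: SimTruth
    r1: list[FastqRead]
    r2: list[FastqRead]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=length, p=p)]).decode()


def _mutate_positions(
    rng: np.random.Generator, seq: str, positions: Sequence[int]
) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def _make_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Unique barcodes at pairwise Hamming distance >= 3, so one sequencing
    error never makes a read ambiguous."""
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 100_000:
            raise DataError("cannot generate enough distinct barcodes; raise barcode_len")
        cand = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
        if all(sum(a != b for a, b in zip(cand, bc)) >= 3 for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def plant_errors(
    seqs: list[str],
    rng: np.random.Generator,
    error_matrix: dict[tuple[str, str], float],
    end_multiplier: float = 1.0,
    end_fraction: float = 0.2,
) -> tuple[list[str], list[tuple[int, ...]]]:
    """Apply the substitution error model to equal-length reads.

    Per position, an error occurs with the summed outgoing rate of the true
    base (scaled by ``end_multiplier`` over the final ``end_fraction`` of the
    read); the observed base is then drawn by relative rate. Returns mutated
    sequences and per-read 0-based error positions.
    """
    if not seqs:
        return [], []
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise DataError("plant_errors requires equal-length reads")
    arr = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    mult = np.ones(length)
    end_start = int(np.ceil(length * (1 - end_fraction)))
    mult[end_start:] = end_multiplier
    total_rate = np.zeros(4)
    cond: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, x in enumerate("ACGT"):
        rates = np.array([error_matrix.get((x, y), 0.0) for y in "ACGT"])
        total_rate[i] = rates.sum()
        if total_rate[i] > 0:
            cond[i] = (np.cumsum(rates / total_rate[i]), _BASES.copy())
    err_positions: list[set[int]] = [set() for _ in seqs]
    u = rng.random(arr.shape)
    draw = rng.random(arr.shape)
    original = arr.copy()  # masks use true bases: one event per position
    for i in range(4):
        if total_rate[i] == 0:
            continue
        mask = (original == _BASES[i]) & (
            u < np.minimum(total_rate[i] * mult, 1.0)[None, :]
        )
        if not mask.any():
            continue
        cum, bases = cond[i]
        idx = np.searchsorted(cum, draw[mask], side="right")
        idx = np.minimum(idx, 3)
        arr[mask] = bases[idx]
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows, cols):
            err_positions[r].add(int(c))
    # a draw can land on the original base only if rates were degenerate;
    # positions are recorded as planted events regardless
    out = [bytes(row).decode() for row in arr]
    return out, [tuple(sorted(p)) for p in err_positions]


def _collapsed_genotypes(
    truth_sites: list[tuple[str, int, str, str]],
    panel: Sequence[AccessionMeta],
    gene_haps: dict[tuple[str, str], list[str]],
) -> list[VariantSite]:
    """Diploid-style truth calls from each accession's gene haplotypes
    (paralogs excluded — they are confounders, not the locus)."""
    sites = []
    for tid, pos, ref, alt in truth_sites:
        per_sample: dict[str, SampleCall] = {}
        for acc in panel:
            haps = gene_haps.get((acc.accession_id, tid))
            if not haps:
                per_sample[acc.accession_id] = SampleCall()
                continue
            bases = {h[pos - 1] for h in haps}
            if bases == {ref}:
                gt = (0, 0)
            elif bases == {alt}:
                gt = (1, 1)
            elif bases == {ref, alt}:
                gt = (0, 1)
            else:  # a planted error-free impossibility
                raise DataError(f"unexpected truth bases {bases} at {tid}:{pos}")
            per_sample[acc.accession_id] = SampleCall(genotype=gt)
        sites.append(
            VariantSite(
                scaffold_id=tid, position=pos, ref_allele=ref,
                alt_alleles=[alt], per_sample=per_sample,
            )
        )
    return sites


def simulate_panel(config: SimConfig) -> SimResult:
    """Generate references, truth genotypes and barcoded read pairs.

    Deterministic for a fixed config (one generator seeded from
    ``config.seed`` drives every draw).
    """
    rng = np.random.default_rng(config.seed)
    n_acc = config.n_diploid_a + config.n_diploid_b + config.n_tetraploid
    barcodes = _make_barcodes(rng, n_acc, config.barcode_len)
    panel: list[AccessionMeta] = []
    k = 0
    for i in range(config.n_diploid_a):
        panel.append(AccessionMeta(f"dipA{i + 1:02d}", "diploid", "A", barcodes[k])); k += 1
    for i in range(config.n_diploid_b):
        panel.append(AccessionMeta(f"dipB{i + 1:02d}", "diploid", "B", barcodes[k])); k += 1
    for i in range(config.n_tetraploid):
        panel.append(AccessionMeta(f"tet{i + 1:02d}", "tetraploid", "AB", barcodes[k])); k += 1

    targets: dict[str, TargetTruth] = {}
    truth_sites: list[tuple[str, int, str, str]] = []
    gene_haps: dict[tuple[str, str], list[str]] = {}
    all_haps: dict[tuple[str, str], list[tuple[str, str]]] = {}

    margin = 20  # keep planted sites away from target ends
    for t in range(config.n_targets):
        tid = f"t{t + 1:03d}"
        length = int(rng.integers(config.target_len[0], config.target_len[1] + 1))
        ancestor = _random_seq(rng, length, config.gc_content)
        n_fixed = int(rng.integers(config.divergence[0], config.divergence[1] + 1))
        n_snps = 2 * config.snps_per_subgenome
        pool = rng.choice(
            np.arange(margin, length - margin), size=n_fixed + n_snps, replace=False
        )
        fixed_pos = sorted(int(p) for p in pool[:n_fixed])
        snp_pos = [int(p) for p in pool[n_fixed:]]
        a_seq = ancestor
        b_seq = _mutate_positions(rng, ancestor, fixed_pos)
        fixed = [(p, a_seq[p], b_seq[p]) for p in fixed_pos]
        consensus = consensus_target(a_seq, b_seq)

        # homologous SNPs: first half on the A copy, second half on B
        snps: list[TruthSNP] = []
        for j, p in enumerate(snp_pos):
            sub = "A" if j < config.snps_per_subgenome else "B"
            ref = (a_seq if sub == "A" else b_seq)[p]
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            maf = float(rng.uniform(*config.snp_maf))
            snps.append(TruthSNP(tid, sub, p + 1, ref, alt, maf))

        # paralogs of the A copy, shared genome-wide
        paralogs: list[ParalogTruth] = []
        if rng.random() < config.paralog_fraction:
            lam = config.paralog_mean / config.paralog_fraction - 1.0
            n_par = 1 + int(rng.poisson(max(lam, 0.0)))
            for j in range(n_par):
                n_mut = max(1, int(round(length * (1 - config.paralog_identity))))
                mut_pos = rng.choice(np.arange(length), size=n_mut, replace=False)
                pseq = _mutate_positions(rng, a_seq, [int(p) for p in mut_pos])
                het_pos = int(rng.integers(margin, length - margin))
                het_alt = "ACGT".replace(pseq[het_pos], "")[rng.integers(3)]
                carriers = frozenset(
                    a.accession_id for a in panel
                    if a.genome_class in ("A", "AB")
                    and rng.random() < config.paralog_het_prob
                )
                paralogs.append(
                    ParalogTruth(
                        paralog_id=f"{tid}_p{j + 1}", target_id=tid, sequence=pseq,
                        het_position=het_pos, het_alt=het_alt,
                        het_accessions=carriers,
                    )
                )

        targets[tid] = TargetTruth(
            target_id=tid, a_seq=a_seq, b_seq=b_seq, consensus=consensus,
            fixed_positions=fixed, snps=snps, paralogs=paralogs,
        )

        # per-accession alt carriers for each SNP (selfed: homozygous)
        carriers: dict[TruthSNP, set[str]] = {}
        for snp in snps:
            eligible = [
                a.accession_id for a in panel
                if a.genome_class == snp.subgenome or a.genome_class == "AB"
            ]
            carriers[snp] = {
                acc for acc in eligible if rng.random() < snp.maf
            }

        def _gene_copy(sub: str, acc_id: str) -> str:
            seq = a_seq if sub == "A" else b_seq
            if not any(
                s.subgenome == sub and acc_id in carriers[s] for s in snps
            ):
                return seq
            out = list(seq)
            for s in snps:
                if s.subgenome == sub and acc_id in carriers[s]:
                    out[s.position - 1] = s.alt
            return "".join(out)

        for acc in panel:
            haps: list[tuple[str, str]] = []
            genes: list[str] = []
            if acc.genome_class in ("A", "AB"):
                copy = _gene_copy("A", acc.accession_id)
                haps += [("A", copy), ("A", copy)]
                genes += [copy, copy]
            if acc.genome_class in ("B", "AB"):
                copy = _gene_copy("B", acc.accession_id)
                haps += [("B", copy), ("B", copy)]
                genes += [copy, copy]
            if acc.genome_class in ("A", "AB"):
                for par in paralogs:
                    h1 = par.sequence
                    if acc.accession_id in par.het_accessions:
                        h2 = (
                            par.sequence[: par.het_position]
                            + par.het_alt
                            + par.sequence[par.het_position + 1:]
                        )
                    else:
                        h2 = par.sequence
                    haps += [(par.paralog_id, h1), (par.paralog_id, h2)]
            gene_haps[(acc.accession_id, tid)] = genes
            all_haps[(acc.accession_id, tid)] = haps

        for snp in snps:
            truth_sites.append((tid, snp.position, snp.ref, snp.alt))
        for p, ab, bb in fixed:
            ref, alt = sorted((ab, bb))
            truth_sites.append((tid, p + 1, ref, alt))

    truth_sites.sort(key=lambda s: (s[0], s[1]))
    matrix = GenotypeMatrix(
        sites=_collapsed_genotypes(truth_sites, panel, gene_haps),
        accessions=panel,
    )

    # ---- reads -----------------------------------------------------------
    r1_reads: list[FastqRead] = []
    r2_reads: list[FastqRead] = []
    read_log: list[ReadTruth] = []
    qual = config.base_quality
    serial = 0
    for acc in panel:
        for tid in targets:
            haps = all_haps[(acc.accession_id, tid)]
            choices = rng.integers(0, len(haps), size=config.reads_per_target_per_accession)
            raw_r1: list[str] = []
            raw_r2: list[str] = []
            kinds: list[str] = []
            for c in choices:
                kind, frag = haps[int(c)]
                r1_seq = (acc.barcode + frag)[: config.read_len]
                r2_seq = revcomp(frag)[: config.read_len]
                raw_r1.append(r1_seq)
                raw_r2.append(r2_seq)
                kinds.append(kind)
            # reads within one target batch share a length, so the error
            # model can run vectorised over the batch
            mut_r1, err1 = plant_errors(
                raw_r1, rng, config.error_matrix,
                config.end_error_multiplier, config.end_fraction,
            )
            mut_r2, err2 = plant_errors(
                raw_r2, rng, config.error_matrix,
                config.end_error_multiplier, config.end_fraction,
            )
            for m1, m2, e1, e2, kind in zip(mut_r1, mut_r2, err1, err2, kinds):
                serial += 1
                rid = f"read{serial:07d}"
                r1_reads.append(FastqRead(rid, m1, [qual] * len(m1)))
                r2_reads.append(FastqRead(rid, m2, [qual] * len(m2)))
                read_log.append(
                    ReadTruth(rid, acc.accession_id, tid, kind, e1, e2)
                )

    truth = SimTruth(
        config=config, panel=panel, targets=targets, haplotypes=all_haps,
        genotype_matrix=matrix, read_log=read_log,
    )
    return SimResult(truth=truth, r1=r1_reads, r2=r2_reads)


# ---------------------------------------------------------------------------
# Analytic expectations and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteExpectation:
    target_id: str
    position: int  # 1-based
    ref: str
    expected_ref_fraction: float
    n_haplotypes: int


def truth_het_fraction(truth: SimTruth, accession: str) -> dict[tuple[str, int], SiteExpectation]:
    """Expected reference-allele read fraction at every truth site for one
    accession, under equal representation of all haplotypes.

    A true het on one gene of two sampled copies gives 0.5; one variant
    haplotype among four co-sampled copies (a het subgenome of a tetraploid,
    or a gene+paralog pair) gives 0.25/0.75; monomorphic configurations give
    0 or 1. Sites covered are the collapsed truth sites plus every paralog's
    internal variable position; the reference base at each is the one the
    pipeline caller uses (the alphabetically first expansion of the consensus
    column).
    """
    from .core_model import IUPAC_EXPAND

    site_keys: list[tuple[str, int, str]] = [
        (s.scaffold_id, s.position, s.ref_allele)
        for s in truth.genotype_matrix.sites
    ]
    for tid, target in truth.targets.items():
        for par in target.paralogs:
            if par.het_position is not None:
                pos = par.het_position + 1
                ref = min(IUPAC_EXPAND[target.consensus[par.het_position].upper()])
                site_keys.append((tid, pos, ref))
    out: dict[tuple[str, int], SiteExpectation] = {}
    for tid, pos, ref in site_keys:
        haps = truth.haplotypes.get((accession, tid))
        if not haps:
            continue
        n_ref = sum(h[pos - 1] == ref for _, h in haps)
        out[(tid, pos)] = SiteExpectation(
            target_id=tid,
            position=pos,
            ref=ref,
            expected_ref_fraction=n_ref / len(haps),
            n_haplotypes=len(haps),
        )
    return out


def concordance_with_truth(
    calls: GenotypeMatrix,
    pileups: dict,
    truth: SimTruth,
    min_depth: int = 20,
) -> tuple[int, int, float]:
    """Score pipeline genotypes against collapsed truth at covered sites.

    A truth site/accession is covered when the accession's pileup depth at
    that column reaches ``min_depth``. An absent call at a covered column
    counts as homozygous reference (the caller only emits columns with a
    non-reference allele). Returns (n_compared, n_matching, percent).
    """
    called = {s.key: s for s in calls.sites}
    n = match = 0
    for site in truth.genotype_matrix.sites:
        pile = pileups.get(site.scaffold_id)
        if pile is None:
            continue
        for acc in truth.genotype_matrix.accession_ids:
            truth_bases = site.called_bases(acc)
            if truth_bases is None:
                continue
            counts = pile.counts.get(acc)
            if counts is None or counts[site.position - 1].sum() < min_depth:
                continue
            csite = called.get(site.key)
            if csite is None:
                obs = frozenset({site.ref_allele})
            else:
                obs = csite.called_bases(acc)
                if obs is None:
                    continue
            n += 1
            match += obs == truth_bases
    return n, match, (100.0 * match / n if n else float("nan"))


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_simulation(result: SimResult, outdir: str) -> None:
    """Write refs.fasta, targets.fasta, truth.vcf, reads, barcodes.tsv,
    truth.tsv and a config echo into ``outdir``."""
    import os

    from .core_model import write_fasta, write_fastq, write_vcf

    os.makedirs(outdir, exist_ok=True)
    truth = result.truth
    refs: dict[str, str] = {}
    for tid, t in truth.targets.items():
        refs[f"{tid}_A"] = t.a_seq
        refs[f"{tid}_B"] = t.b_seq
        for par in t.paralogs:
            refs[par.paralog_id] = par.sequence
    write_fasta(refs, os.path.join(outdir, "refs.fasta"))
    write_fasta(truth.consensus_targets, os.path.join(outdir, "targets.fasta"))
    write_vcf(truth.genotype_matrix, os.path.join(outdir, "truth.vcf"))
    write_fastq(result.r1, os.path.join(outdir, "reads_R1.fastq"))
    write_fastq(result.r2, os.path.join(outdir, "reads_R2.fastq"))
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        fh.write("accession_id\tploidy\tgenome_class\tbarcode\n")
        for a in truth.panel:
            fh.write(f"{a.accession_id}\t{a.ploidy}\t{a.genome_class}\t{a.barcode}\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("read_id\taccession_id\ttarget_id\thap_kind\terrors_r1\terrors_r2\n")
        for r in truth.read_log:
            e1 = ",".join(map(str, r.errors_r1))
            e2 = ",".join(map(str, r.errors_r2))
            fh.write(f"{r.read_id}\t{r.accession_id}\t{r.target_id}\t{r.hap_kind}\t{e1}\t{e2}\n")
    cfg = asdict(truth.config)
    cfg["error_matrix"] = {f"{x}>{y}": v for (x, y), v in truth.config.error_matrix.items()}
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
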