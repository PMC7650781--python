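# Methods

This note documents the models, conventions and open design choices behind
`polyamp`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py` at run time.

## Scope and model

The package treats an allotetraploid locus as a set of co-sampled gene
copies: two haplotypes per subgenome copy of the target gene, plus two per
paralogous copy. Reads from all copies co-map onto one consensus amplicon
target, so a per-call **allele balance** (reference-read fraction from the
VCF AD field) carries the copy-configuration signal: 0.5 for one variant
copy in two, 0.25/0.75 for one in four, 0/1 for none. All genotype calls
are diploid-style (0/0, 0/1, 1/1) regardless of ploidy — that is how
co-mapping subgenome reads present to any caller, and it keeps the
correction rule uniform across ploidies.

## SNP selection filters

* MAF is computed from genotype calls (two allele observations per
  unphased call), not from read depths; the threshold is a strict bound
  (MAF > `maf_min`, default 0.10).
* Summed read depth is the AD total over alleles and accessions, strict
  (> `depth_min`, default 100).
* PIC uses the Botstein (1980) definition
  `1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ²`. The common alternative (expected
  heterozygosity `1 − Σpᵢ²`) is larger everywhere; the term "PIC" in the
  plant-marker literature conventionally means the Botstein form, and the
  0.3 threshold is demanding but attainable for biallelic markers only
  under definitions of this family (biallelic maximum 0.375 at p = 0.5).
  The threshold is inclusive (≥) by default with a `pic_strict` switch,
  since usage alternates between "greater than 30%" and "≥ 0.3".
* Filters are checked in the order indel → MAF → depth → PIC and the
  rejection log records the first failing rule.

## Target design

* Scaffold pairing consumes standard 12-column tabular alignment hits;
  the best hit per A scaffold maximises identity × alignment length among
  hits strictly longer than 350 bp; ties go to the lexicographically
  smaller B scaffold and are flagged.
* B-side coordinates are mapped by constant offset within the best hit's
  aligned span. This matches scaffold-level pairing granularity and is a
  documented limitation for indel-rich homoeolog pairs; per-column gap
  tracking is deliberately out of scope.
* Co-target windows require at least two SNPs on each subgenome within
  ±100 bp (default) of an anchor SNP; identical SNP sets from different
  anchors are de-duplicated. The implementation is checked against an
  exhaustive O(n²) window scan in the tests.
* Region spans longer than the 450 bp band maximum are trimmed to the
  450 bp window containing the most SNPs (leftmost on ties); shorter
  spans are extended symmetrically to 300 bp, clipping at scaffold ends.
  The length band is a published experimental constraint; the trimming
  rule is this package's own choice, since no rule is published.
* The consensus writes matching columns verbatim, two-base IUPAC codes at
  mismatches, and the lower-case surviving base at gap columns; its
  ambiguity count equals the Hamming distance over non-gap columns.
* Flank extraction defaults to 1000 bp each side, clipped at scaffold
  ends, with the SNP's local offset reported. The built-in
  Smith–Waterman (`align_pair`, +1/−1/−2, deterministic
  diagonal-up-left traceback) exists for self-contained test-scale runs;
  production users supply hit files from a dedicated aligner.

## Amplicon pipeline

* Demultiplexing assigns a pair to the unique barcode within Hamming
  distance 1 (default) of the R1 prefix; equidistant prefixes are
  unassigned. The simulator generates barcodes at pairwise distance ≥ 3
  so a single sequencing error can never switch accessions.
* Merging scans all overlaps ≥ 10 bp of the forward read against the
  reverse complement of the mate; among overlaps with mismatch rate
  ≤ 0.25 it keeps the one with the most matches (ties: fewer mismatches,
  then longer overlap). Conflicting bases resolve to the higher quality,
  ties to the forward base.
* Read-to-target alignment is semi-global (free end gaps on the target)
  because merged amplicons span their targets end to end; merged reads
  are orientation-fixed by construction, so no reverse-strand pass is
  needed. Scoring is edit distance via edlib, with IUPAC ambiguity
  columns matching either underlying base; a read tied between two
  targets is left unassigned. A hand-written DP oracle in the tests
  verifies both the distances and the assignments.
* Pileups count A/C/G/T/N per column per accession, capped at 4000 reads
  per accession-target (the depth ceiling used for maximal read
  representation in the experiment this pipeline models).
* The caller is a transparent frequency rule: below 20 reads the call is
  missing; alleles at ≥ 5% of the column depth are kept (one → homozygote,
  two → heterozygote, more than two → the two deepest, logged); AD and DP
  come from the counts. The reference base of a consensus ambiguity
  column is its alphabetically first expansion. Only columns where some
  accession carries a non-reference passing allele are emitted, so
  heterozygosity rates are percentages over emitted (variant) sites.
  Indels are not called.

## Correction and interpretation

* Band model (reference-allele fraction, lower-inclusive): [0, 0.20)
  homozygote-alt, [0.20, 0.30) paralog-low, [0.30, 0.70] true het,
  (0.70, 0.80) paralog-high, [0.80, 1] homozygote-ref. The 30–70% band
  includes both endpoints; published interval notation for the
  surrounding bands is not fully consistent, so the remaining boundaries
  (0.20, 0.80) are resolved lower-inclusive. All five bounds are
  configurable.
* Correction is per call: a heterozygote whose minor-allele read
  fraction is strictly below the cutoff becomes homozygous for the
  major allele. "Minor" is the lower-depth allele of the call (tie kept
  as listed), so a reference allele can be rescored away. Hets without
  usable AD pass through and are logged as unassessable rather than
  guessed. The operation is idempotent, never creates heterozygotes,
  and het counts are non-increasing in the cutoff — all property-tested.
* The expected tetraploid heterozygous-call rate is the arithmetic mean
  of its diploid parents' rates (the co-mapping paralog argument: a
  tetraploid inherits its parents' paralog complements).
* Reported percentages round half away from zero to one decimal.
  Validation-table display truncates one-decimal percentage cells and
  rounds integer cells — the convention of the tables this mirrors —
  while all comparisons use the exact float recomputed from counts.

## Error profiling

Rates are per ordered pair: rate[x→y] = errors/opportunities with
opportunities the positions whose true base is x. Reads are anchored
positionally (no gapped alignment — barcode regions are short and
indel-free by construction); length-mismatched reads are skipped with a
log entry. Ordered pairs are primary because Illumina substitution error
is direction-biased; an unordered pooled view is provided for comparison.
Position-dependent error along the read is simulated but deliberately not
estimated.

## Simulator

The generator's defaults are the study conditions of the experiment it
emulates: 48 targets of 300–450 bp, 4–5 fixed inter-subgenome differences
per target, a 48-accession panel (12 selfed diploids, 36 tetraploids),
2×250 bp barcoded pairs, substitution error G→A 1.38% and A→T 0.84%
(0.1% elsewhere) with a 3× multiplier over the final fifth of each read,
and paralogs on 37/48 of targets averaging 3.81 copies per target. The
paralog count is modelled as Bernoulli(37/48) presence × (1 + Poisson(λ))
copies with λ = 3.81·48/37 − 1, matching both published statistics in
expectation; no count distribution is published. Two homologous SNPs per
subgenome per target are planted at MAF drawn uniformly from [0.1, 0.5].
Depth is 200 read pairs per accession-target by default — a desk-scale
choice that keeps the RD > 100 selection filter meaningful; tests and the
acceptance script state their own sizes explicitly.

Panel classes are diploid-A, diploid-B and tetraploid; the related
K-genome diploid class is representable in the metadata but not
generated. Paralogs derive from the A-subgenome copy and are carried by
all A-genome-bearing accessions; each paralog has one internal variable
site heterozygous in a configurable fraction of accessions — the
mechanism behind 25%/75% balance peaks in selfed material. Ancestor
sequences are uniform over ACGT (GC configurable) with no repeat
structure; repetitive-genome effects enter only through paralogs.
Read qualities are constant (Q30) — quality simulation beyond the
end-region error inflation is out of scope, as are indel errors,
amplification bias and chimeras.

One `numpy` generator seeded from the config drives every draw, so equal
configs give byte-identical outputs.

### What the simulator does and does not show

Passing the pipeline on simulated panels demonstrates the genotyping and
correction logic under the stated error and paralogy model: exact truth
recovery without noise, binomially-calibrated spurious het rates with
noise, and balance convergence to the analytic 0.5/0.25/0.75
expectations. It does not demonstrate robustness to real-data features
the generator omits: indels, PCR chimeras, depth skew across targets
(only a uniform depth is generated), reference bias, or quality-score
miscalibration beyond a constant offset.

## Numerical and testing choices

* Internal coordinates are 0-based half-open; VCF-facing positions are
  1-based and converted exactly once at the I/O boundary.
* Multi-allelic VCF rows are preserved at parse time; operations needing
  biallelic input reduce per call (major vs minor by depth).
* Simulation sizes in the tests (e.g. 8 targets × 12 accessions at 40
  pairs for noise-free recovery; depth 2000 for balance convergence;
  ~5×10⁵ bases for error-rate recovery) are chosen so statistical checks
  have 3σ binomial resolution well below the effect sizes they test.
* Statistical assertions use fixed seeds and 3σ bounds; oracle
  assertions (alignment, window scan, correction change log) are exact.

## Known limitations

* Constant-offset homoeolog coordinate mapping (see above).
* The frequency caller has no genotype likelihoods or quality
  recalibration; a likelihood-based genotyper is explicitly out of scope.
* SAM/BAM input is not parsed; external callers interoperate through VCF.
* Cost modelling is plain itemised arithmetic — no currency handling or
  price databases.
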