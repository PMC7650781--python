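# polyamp

Homoeolog-aware SNP target design, self-contained amplicon genotyping and
allele-balance heterozygote correction for allotetraploid species.

## The problem

Allotetraploids such as cultivated peanut (*Arachis hypogaea*, AABB,
2n = 4x = 40) carry two closely related subgenomes. Reads from the A and B
copies of a locus co-map, so fixed homoeologous differences and paralogous
gene copies masquerade as heterozygous SNP calls — a major reason SNP
validation rates in polyploids are poor. Targeted amplicon resequencing
offers a cheap route to genotyping breeding populations, but only if
targets are chosen where both subgenomes are informative and spurious
heterozygotes can be recognised and corrected afterwards.

`polyamp` is aimed at breeders and genotyping bioinformaticians. It covers
the full desk-side workflow:

* **SNP selection** — filter candidate variants by minor-allele frequency
  (MAF > 0.10), read depth summed across the panel (RD > 100) and
  polymorphic information content (PIC ≥ 0.3);
* **target design** — pair homoeologous A/B scaffolds from tabular
  alignment hits (best hit, alignment length > 350 bp), find windows with
  multiple SNPs in *both* subgenomes (±100 bp), extract ~1000 bp flanks,
  and emit a 300–450 bp IUPAC consensus per target so one primer pair
  amplifies both subgenomes at once;
* **amplicon genotyping** — demultiplex barcoded 2×250 bp pairs, merge
  mates by best overlap, align merged reads semi-globally against the
  pooled consensus targets (ambiguity codes match either base), and call
  genotypes with a transparent frequency caller (AD/DP recorded);
* **interpretation and correction** — classify each call by its allele
  balance and rescore implausible heterozygotes;
* **error profiling** — estimate the 12 ordered substitution error rates
  from reads over a known sequence (barcode regions);
* **simulation** — a seeded generator of synthetic allotetraploid panels
  (diverged subgenomes, paralogs, selfed accessions, biased sequencing
  error) with full ground truth, so every stage is testable offline.

## The statistics at the core

For allele frequencies *p₁ … pₖ* at a site,

```
PIC = 1 − Σᵢ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²        (Botstein et al. 1980)
```

maximal at 0.375 for a biallelic marker, so PIC ≥ 0.3 selects strongly
informative markers.

For one call with allele depths (AD), the **allele balance** is the
reference-read fraction `b = AD_ref / (AD_ref + AD_alt)`. Under equal
representation of gene copies:

| balance | interpretation |
|---|---|
| ≈ 0.50 | true diploid het, or a fixed A/B homoeolog difference in a tetraploid |
| ≈ 0.25 / 0.75 | one variant haplotype among four co-sampled copies (het subgenome, or gene + paralog) |
| ≈ 0 / 1 | homozygote plus sequencing error |

The **heterozygote correction** rescores any heterozygous call whose
minor-allele read fraction is below a cutoff (0.15 / 0.20 / 0.25) as the
major-allele homozygote: selfed lines are nearly fully homozygous, so
low-minor-fraction hets are attributable to sequencing error or skewed
paralog co-mapping, not real heterozygosity.

## Worked example

Simulate a small panel (4 targets, 2+2 diploids, 4 tetraploids, 100 read
pairs per accession-target), genotype it, and correct at the 20% cutoff:

```bash
polyamp simulate --seed 17 --n-targets 4 --n-diploid-a 2 --n-diploid-b 2 \
    --n-tetraploid 4 --reads-per-target 100 --outdir demo
polyamp genotype --r1 demo/reads_R1.fastq --r2 demo/reads_R2.fastq \
    --barcodes demo/barcodes.tsv --targets demo/targets.fasta \
    --out demo/calls.vcf --report demo/run_report.tsv
polyamp correct --vcf demo/calls.vcf --cutoff 0.20 \
    --out demo/corrected.vcf --changes demo/changes.tsv
polyamp hetstats --vcf demo/calls.vcf --per-accession demo/hets_raw.tsv
polyamp hetstats --vcf demo/corrected.vcf --per-accession demo/hets_corrected.tsv
```

The run prints (stderr) `stage=genotype sites=197` and
`stage=correct rescored=550`; the het-rate tables before and after
correction read:

```
accession_id  raw %   corrected %
dipA01        45.7    8.6
dipA02        46.7    9.1
dipB01        16.8    0.0
dipB02        12.2    0.0
tet01         53.8    7.6
tet02         56.3    10.2
tet03         53.8    10.7
tet04         50.3    10.2
```

Rates are percentages of heterozygous calls among the emitted (variant)
sites. Correction removes the error-driven and skew-balance hets; what
survives sits in the credible bands — ~50% balance calls in tetraploids
(fixed A/B homoeolog differences) and ~25%/75% balance calls in the two
A-genome diploids that carry a heterozygous paralog in this simulation.
The B-genome diploids, which have neither, drop to 0.0%.

The same computation is available as a library:

```python
from polyamp import SimConfig, simulate_panel, run_pipeline

sim = simulate_panel(SimConfig(seed=17, n_targets=4, n_diploid_a=2,
                               n_diploid_b=2, n_tetraploid=4,
                               reads_per_target_per_accession=100))
result = run_pipeline(sim.r1, sim.r2, sim.truth.panel, sim.truth.consensus_targets)
```

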