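"""Allele-balance interpretation and heterozygote correction.

In an allotetraploid, reads from the two subgenomes (and from paralogous
copies) co-map onto a shared target, so the fraction of reads carrying the
reference allele at a site — the allele balance — separates call classes:

* ~0.5       true heterozygote in a diploid, or a fixed homoeolog
             difference in a tetraploid (two homozygous subgenome copies);
* ~0.25/0.75 a variant on one of four co-sampled gene copies (one subgenome
             of a tetraploid het, or a gene + paralog pair at equal
             representation);
* near 0/1   homozygote plus sequencing error.

Heterozygous calls whose minor-allele read fraction falls below a cutoff
(0.15 / 0.20 / 0.25 in practice) are rescored as the major-allele
homozygote: selfed lines are expected to be almost fully homozygous, so such
calls are attributed to error or skewed paralog co-mapping rather than real
heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    DataError,
    GenotypeMatrix,
    SampleCall,
    VariantSite,
    logger,
)

UNASSESSABLE = None  # marker for calls without usable allele depths


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (the convention used
    for all reported percentages, avoiding banker's rounding surprises)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BandModel:
    """Reference-allele-fraction bands classifying a call.

    Intervals partition [0, 1]; each boundary belongs to the band on its
    right (lower-inclusive), except 1.0 which belongs to homozygote_ref.
    """

    hom_alt_max: float = 0.20      # [0, 0.20) homozygote for the alternate allele
    true_het_min: float = 0.30     # [0.20, 0.30) paralog_low
    true_het_max: float = 0.70     # [0.30, 0.70] true heterozygote band (both ends in)
    hom_ref_min: float = 0.80      # (0.70, 0.80) paralog_high; [0.80, 1] hom ref

    def classify(self, balance: float) -> str:
        if not 0.0 <= balance <= 1.0:
            raise DataError(f"allele balance {balance} outside [0, 1]")
        if balance < self.hom_alt_max:
            return "homozygote_alt"
        if balance < self.true_het_min:
            return "paralog_low"
        if balance <= self.true_het_max:
            return "true_het"
        if balance < self.hom_ref_min:
            return "paralog_high"
        return "homozygote_ref"


def classify_band(balance: float, model: BandModel = BandModel()) -> str:
    """Band label for one reference-allele fraction."""
    return model.classify(balance)


@dataclass(frozen=True)
class CorrectionConfig:
    """Minor-allele read-fraction cutoff below which a het call is rescored."""

    cutoff: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff < 0.5:
            raise DataError(f"cutoff {self.cutoff} outside [0, 0.5)")


@dataclass(frozen=True)
class CorrectionEvent:
    scaffold_id: str
    position: int
    accession_id: str
    old_genotype: tuple[int, int]
    new_genotype: tuple[int, int]
    minor_fraction: float


def allele_balance(site: VariantSite, accession: str) -> Optional[float]:
    """Reference-allele read fraction for one call, or None if unassessable
    (missing AD or zero total depth)."""
    call = site.per_sample.get(accession)
    if call is None or call.allele_depths is None:
        return UNASSESSABLE
    total = sum(call.allele_depths)
    if total == 0:
        return UNASSESSABLE
    return call.allele_depths[0] / total


def correct_heterozygotes(
    matrix: GenotypeMatrix, config: CorrectionConfig = CorrectionConfig()
) -> tuple[GenotypeMatrix, list[CorrectionEvent]]:
    """Rescore low-minor-fraction heterozygotes as major-allele homozygotes.

    For every heterozygous call with allele depths, the minor allele is the
    lower-depth allele of the genotype (ties resolved toward keeping the
    first-listed allele as major); if its read fraction over the call's total
    depth is strictly below the cutoff, the call becomes homozygous for the
    major allele. All other calls — including hets without AD, which are
    logged and passed through — are unchanged.
    """
    out_sites: list[VariantSite] = []
    changes: list[CorrectionEvent] = []
    n_no_ad = 0
    for site in matrix.sites:
        new_samples: dict[str, SampleCall] = {}
        touched = False
        for acc, call in site.per_sample.items():
            if call.is_het:
                if call.allele_depths is None:
                    n_no_ad += 1
                    new_samples[acc] = call
                    continue
                total = sum(call.allele_depths)
                if total == 0:
                    n_no_ad += 1
                    new_samples[acc] = call
                    continue
                i, j = call.genotype
                di, dj = call.allele_depths[i], call.allele_depths[j]
                major, minor = (i, j) if di >= dj else (j, i)
                minor_frac = call.allele_depths[minor] / total
                if minor_frac < config.cutoff:
                    new_call = SampleCall(
                        genotype=(major, major), allele_depths=call.allele_depths
                    )
                    new_samples[acc] = new_call
                    touched = True
                    changes.append(
                        CorrectionEvent(
                            site.scaffold_id, site.position, acc,
                            call.genotype, (major, major), minor_frac,
                        )
                    )
                    continue
            new_samples[acc] = call
        if touched:
            out_sites.append(replace(site, per_sample=new_samples))
        else:
            out_sites.append(site)
    if n_no_ad:
        logger.info(
            "correct_heterozygotes: %d het calls without usable AD passed through",
            n_no_ad,
        )
    return (
        GenotypeMatrix(sites=out_sites, accessions=list(matrix.accessions)),
        changes,
    )


def het_rate(matrix: GenotypeMatrix, accession: str) -> float:
    """Percentage of heterozygous calls among this accession's non-missing
    calls, rounded half-up to one decimal."""
    n_het = n_called = 0
    for site in matrix.sites:
        call = site.per_sample.get(accession)
        if call is not None and not call.is_missing:
            n_called += 1
            n_het += call.is_het
    if n_called == 0:
        raise DataError(f"{accession}: no non-missing calls")
    return round_half_up(100.0 * n_het / n_called, 1)


def balance_histogram(
    matrix: GenotypeMatrix, accession: str, bins: int = 20
) -> np.ndarray:
    """Counts of reference-allele fractions over equal bins spanning [0, 1].

    Bins are lower-inclusive; a balance of exactly 1.0 falls in the last bin.
    The counts sum to the number of assessable calls.
    """
    balances = [
        b
        for site in matrix.sites
        if (b := allele_balance(site, accession)) is not None
    ]
    if not balances:
        raise DataError(f"{accession}: no assessable calls")
    idx = np.minimum((np.array(balances) * bins).astype(int), bins - 1)
    return np.bincount(idx, minlength=bins)


def expected_tetraploid_het(parent_rates: Sequence[float]) -> float:
    """Expected tetraploid heterozygous-call percentage as the arithmetic
    mean of its parents' diploid rates, to one decimal.

    If spurious heterozygosity comes from co-mapping paralogs, a tetraploid
    derived from known diploid parents should show roughly the average of the
    parental rates.
    """
    if len(parent_rates) == 0:
        raise DataError("no parental rates given")
    for r in parent_rates:
        if not 0.0 <= r <= 100.0:
            raise DataError(f"rate {r} outside [0, 100]")
    return round_half_up(sum(parent_rates) / len(parent_rates), 1)
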