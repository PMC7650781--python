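"""SNP-selection filters: minor-allele frequency, summed read depth,
polymorphic information content (PIC) and InDel removal.

Allele frequencies are computed from genotype calls, not read depths: each
unphased diploid-style call contributes two allele observations (tetraploid
accessions are called diploid-style per subgenome-mapped site by the upstream
caller, so they likewise contribute two).

PIC follows Botstein et al. (1980), the conventional definition for plant
marker informativeness:

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

For a biallelic marker the maximum is 0.375 at p = (0.5, 0.5), so the usual
0.3 selection threshold is attainable but demanding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import DataError, GenotypeMatrix, VariantSite, logger


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site selection.

    maf_min and depth_min are strict lower bounds ("more than 10%", "greater
    than 100"); pic_min is inclusive ("greater than or equal to 0.3").
    ``pic_strict`` flips the PIC rule to a strict bound for users following
    the stricter wording.
    """

    maf_min: float = 0.10
    depth_min: int = 100
    pic_min: float = 0.30
    drop_indels: bool = True
    pic_strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise DataError(f"maf_min {self.maf_min} outside [0, 0.5]")
        if self.depth_min < 0:
            raise DataError("depth_min must be >= 0")
        if not 0.0 <= self.pic_min < 1.0:
            raise DataError(f"pic_min {self.pic_min} outside [0, 1)")


@dataclass(frozen=True)
class Rejection:
    """First failing rule for one rejected site."""

    scaffold_id: str
    position: int
    rule: str  # "indel" | "maf" | "depth" | "pic"
    value: Optional[float]


def allele_frequencies(site: VariantSite) -> np.ndarray:
    """Allele frequencies over [ref] + alts from genotype calls.

    Each non-missing call contributes two allele observations. Raises
    DataError when every call is missing.
    """
    counts = np.zeros(1 + len(site.alt_alleles), dtype=float)
    for call in site.per_sample.values():
        if call.genotype is not None:
            counts[call.genotype[0]] += 1
            counts[call.genotype[1]] += 1
    total = counts.sum()
    if total == 0:
        raise DataError(f"site {site.key}: no data (all genotype calls missing)")
    return counts / total


def minor_allele_frequency(freqs: np.ndarray) -> float:
    """Frequency of the second most common allele (0.0 for monomorphic input)."""
    if len(freqs) < 2:
        return 0.0
    return float(np.sort(freqs)[-2])


def pic(freqs) -> float:
    """Polymorphic information content of an allele-frequency vector.

    Symmetric in its arguments; 0 for a monomorphic site; < 1 always.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0):
        raise DataError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DataError(f"allele frequencies sum to {p.sum()}, not 1")
    sq = p**2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p_i^2)^2 - sum p_i^4
    cross = sq.sum() ** 2 - (p**4).sum()
    return float(1.0 - sq.sum() - cross)


def filter_sites(
    matrix: GenotypeMatrix, config: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, list[Rejection]]:
    """Apply the selection filters; return retained sites and a rejection log.

    Rules are checked in the order indel, MAF, depth, PIC and the log records
    the first rule a rejected site fails. Sites where all calls are missing
    are rejected under the MAF rule with value None.
    """
    kept: list[VariantSite] = []
    rejects: list[Rejection] = []
    for site in matrix.sites:
        if config.drop_indels and site.is_indel:
            rejects.append(Rejection(*site.key, "indel", None))
            continue
        try:
            freqs = allele_frequencies(site)
        except DataError:
            rejects.append(Rejection(*site.key, "maf", None))
            continue
        maf = minor_allele_frequency(freqs)
        if not maf > config.maf_min:
            rejects.append(Rejection(*site.key, "maf", maf))
            continue
        depth = site.summed_depth
        if not depth > config.depth_min:
            rejects.append(Rejection(*site.key, "depth", float(depth)))
            continue
        p = pic(freqs)
        pic_ok = p > config.pic_min if config.pic_strict else p >= config.pic_min
        if not pic_ok:
            rejects.append(Rejection(*site.key, "pic", p))
            continue
        kept.append(site)
    logger.info(
        "filter_sites: kept %d of %d sites (%d rejected)",
        len(kept), len(matrix.sites), len(rejects),
    )
    return GenotypeMatrix(sites=kept, accessions=list(matrix.accessions)), rejects
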