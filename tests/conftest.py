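"""Shared fixtures: small synthetic panels and hand-built matrices."""

import pytest

from polyamp import (
    AccessionMeta,
    GenotypeMatrix,
    SampleCall,
    SimConfig,
    VariantSite,
    run_pipeline,
    simulate_panel,
    zero_error_matrix,
)


def make_site(scaffold="chr1", position=100, ref="A", alts=("G",), calls=None):
    """Convenience VariantSite builder; calls maps accession -> (gt, ad)."""
    per_sample = {}
    for acc, (gt, ad) in (calls or {}).items():
        per_sample[acc] = SampleCall(
            genotype=gt, allele_depths=tuple(ad) if ad is not None else None
        )
    return VariantSite(
        scaffold_id=scaffold,
        position=position,
        ref_allele=ref,
        alt_alleles=list(alts),
        per_sample=per_sample,
    )


def make_matrix(sites, accession_ids):
    return GenotypeMatrix(
        sites=sites,
        accessions=[AccessionMeta(accession_id=a) for a in accession_ids],
    )


@pytest.fixture(scope="session")
def noise_free_sim():
    """8 targets x 12 accessions, no sequencing error, no paralogs."""
    config = SimConfig(
        seed=11,
        n_targets=8,
        n_diploid_a=3,
        n_diploid_b=3,
        n_tetraploid=6,
        reads_per_target_per_accession=40,
        error_matrix=zero_error_matrix(),
        paralog_fraction=0.0,
    )
    return simulate_panel(config)


@pytest.fixture(scope="session")
def noise_free_pipeline(noise_free_sim):
    sim = noise_free_sim
    return run_pipeline(sim.r1, sim.r2, sim.truth.panel, sim.truth.consensus_targets)


@pytest.fixture(scope="session")
def noisy_sim():
    """Small panel with the default error profile and paralogs enabled."""
    config = SimConfig(
        seed=23,
        n_targets=4,
        n_diploid_a=2,
        n_diploid_b=2,
        n_tetraploid=4,
        reads_per_target_per_accession=60,
    )
    return simulate_panel(config)


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_sim):
    sim = noisy_sim
    return run_pipeline(sim.r1, sim.r2, sim.truth.panel, sim.truth.consensus_targets)
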