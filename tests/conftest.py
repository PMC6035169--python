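import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosaicpath import synthio, wgp_anchor as wa
from mosaicpath.config import SimConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class PipelineFixture:
    """A small end-to-end synthetic run shared across test modules."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.reference = synthio.generate_reference(config)
        self.ancestral = synthio.generate_ancestral_genomes(self.reference, config)
        self.library = synthio.generate_bac_library(self.ancestral, config)
        self.kept_tags, self.n_discarded = wa.deduplicate_tags(self.library.tags)
        self.placements = wa.place_tags(
            self.kept_tags, guide=self.reference.sequences
        )
        params = wa.AnchorParams()
        self.anchored = wa.rescue_multi_tags(
            wa.anchor_all(self.placements, params), self.placements, params
        )
        self.mtp = wa.select_mtp(self.anchored, self.reference.genes)
        self.gene_maps = synthio.bac_gene_maps(
            self.library, self.ancestral, self.reference
        )
        self.bac_lengths = {b: len(s) for b, s in self.library.sequences.items()}
        self.truth = dict(zip(self.library.bacs.bac_id, self.library.bacs.species))


@pytest.fixture(scope="session")
def dense_pipeline() -> PipelineFixture:
    """Gene-dense run at zero divergence: BACs overlap, genes are shared."""
    config = SimConfig(
        n_chromosomes=3,
        chrom_length=150_000,
        n_genes_per_chrom=25,
        gene_length=2_000,
        n_bacs=60,
        bac_insert_mean=30_000,
        bac_insert_sd=4_000,
        divergence_subs_per_site=0.0,
        seed=11,
    )
    return PipelineFixture(config)


@pytest.fixture(scope="session")
def mosaic_config() -> SimConfig:
    """Diverged two-species mosaic used for ancestry recovery tests."""
    return SimConfig(
        n_chromosomes=10,
        chrom_length=300_000,
        n_bacs=80,
        bac_insert_mean=40_000,
        bac_insert_sd=6_000,
        divergence_subs_per_site=0.02,
        wgs_depth=20.0,
        seed=3,
    )
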