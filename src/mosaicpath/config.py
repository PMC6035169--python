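"""Simulation configuration.

:class:`SimConfig` fixes the study conditions under which the synthetic
inputs are generated: a 10-chromosome guide genome, two ancestral genome
sets separated by a stated substitution divergence with an arm-fusion
rearrangement reducing the basic chromosome number from x=10 to x=8, a BAC
library fingerprinted by 50-bp restriction-site tags, a selfing progeny
segregating 3:1 for single-dose markers, and a species diagnostic panel.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class Fusion:
    """One whole-donor chromosome rearrangement.

    The donor chromosome is split at ``split_frac`` of its length and its
    left/right arms are appended to two recipient chromosomes.  Each fusion
    therefore reduces the chromosome count of the rearranged genome by one.
    """

    donor: str
    left_recipient: str
    right_recipient: str
    split_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.split_frac < 1.0:
            raise ValueError("split_frac must be in (0, 1)")


def default_rearrangements(n_chromosomes: int) -> Tuple[Fusion, ...]:
    """Two fusions turning an x=10 karyotype into x=8.

    Mirrors the structure seen between the two ancestral species: one
    chromosome split between the homologues of chromosomes 2 and 9, and a
    second between those of chromosomes 6 and 7.
    """
    if n_chromosomes == 10:
        return (
            Fusion("chr08", "chr02", "chr09"),
            Fusion("chr05", "chr06", "chr07"),
        )
    return ()


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic data generator.

    All coordinates produced under this configuration are 0-based
    half-open internally; 1-based inclusive coordinates appear only at the
    GFF3/AGP interfaces.
    """

    n_chromosomes: int = 10
    chrom_length: int = 1_000_000
    n_genes_per_chrom: int = 40
    gene_length: int = 3_000
    #: substitutions/site separating the two ancestral genomes (each is
    #: mutated away from their common ancestor at half this rate).
    divergence_subs_per_site: float = 0.02
    rearrangement_spec: Tuple[Fusion, ...] | None = None
    bac_insert_mean: int = 100_000
    bac_insert_sd: int = 10_000
    n_bacs: int = 200
    #: fraction of BAC clones drawn from species A (officinarum-like);
    #: the remainder come from species B (spontaneum-like).
    frac_species_a: float = 0.78
    enzyme_motif: str = "CTGCAG"  # PstI
    tag_length: int = 50
    n_individuals: int = 186
    n_markers: int = 200
    #: sequencing depth for progeny/panel genotyping reads.
    depth_mean: float = 60.0
    #: per-base sequencing error probability.
    seq_error: float = 0.001
    #: homologous copies carrying each locus in the cultivar; a dose-1
    #: allele is read at frequency 1/ploidy.
    ploidy: int = 12
    #: whole-genome shotgun conditions used for ancestry depth tracks.
    wgs_depth: float = 20.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_genes_per_chrom": self.n_genes_per_chrom,
            "gene_length": self.gene_length,
            "bac_insert_mean": self.bac_insert_mean,
            "bac_insert_sd": self.bac_insert_sd,
            "n_bacs": self.n_bacs,
            "n_individuals": self.n_individuals,
            "n_markers": self.n_markers,
            "ploidy": self.ploidy,
            "read_length": self.read_length,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.divergence_subs_per_site < 1.0:
            raise ValueError("divergence_subs_per_site must be in [0, 1)")
        if self.tag_length <= 0:
            raise ValueError("tag_length must be > 0")
        if not 0.0 <= self.frac_species_a <= 1.0:
            raise ValueError("frac_species_a must be in [0, 1]")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must be in [0, 1)")
        if len(self.enzyme_motif) < 4:
            raise ValueError("enzyme_motif must be at least 4 bp")
        if self.rearrangement_spec is None:
            object.__setattr__(
                self,
                "rearrangement_spec",
                default_rearrangements(self.n_chromosomes),
            )
        else:
            object.__setattr__(
                self, "rearrangement_spec", tuple(self.rearrangement_spec)
            )

    @property
    def chromosome_names(self) -> Tuple[str, ...]:
        return tuple(f"chr{i + 1:02d}" for i in range(self.n_chromosomes))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rearrangement_spec"] = [asdict(f) for f in self.rearrangement_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        spec = d.get("rearrangement_spec")
        if spec is not None:
            d["rearrangement_spec"] = tuple(Fusion(**f) for f in spec)
        return cls(**d)
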