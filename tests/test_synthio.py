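"""Synthetic-data generator: determinism, truth structure, segregation."""
import numpy as np
import pandas as pd
import pytest

from mosaicpath import io as mio, synthio
from mosaicpath.config import Fusion, SimConfig


def small_config(**kw) -> SimConfig:
    base = dict(
        n_chromosomes=4,
        chrom_length=60_000,
        n_genes_per_chrom=8,
        gene_length=1_500,
        n_bacs=20,
        bac_insert_mean=12_000,
        bac_insert_sd=1_500,
        rearrangement_spec=(),
        n_markers=10,
        n_individuals=40,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestReference:
    def test_chromosome_count_and_lengths(self):
        ref = synthio.generate_reference(small_config())
        assert len(ref.sequences) == 4
        assert all(len(s) == 60_000 for s in ref.sequences.values())

    def test_genes_nonoverlapping_and_stranded(self):
        ref = synthio.generate_reference(small_config())
        for _, g in ref.genes.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].values[1:] >= g["end"].values[:-1]).all()
        assert set(ref.genes["strand"]) <= {"+", "-"}

    def test_zero_genes_gives_empty_valid_annotation(self, tmp_path):
        ref = synthio.generate_reference(small_config(n_genes_per_chrom=0))
        assert ref.genes.empty
        path = tmp_path / "genes.gff3"
        mio.write_gff3(ref.genes, path)
        assert mio.read_gff3(path).empty

    def test_gene_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            synthio.generate_reference(
                small_config(n_genes_per_chrom=50, gene_length=2_000)
            )

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        files = []
        for name in ("a.fasta", "b.fasta"):
            ref = synthio.generate_reference(small_config())
            mio.write_fasta(ref.sequences, tmp_path / name)
            files.append((tmp_path / name).read_bytes())
        assert files[0] == files[1]


class TestAncestralGenomes:
    def test_zero_divergence_no_rearrangement_identical(self):
        cfg = small_config(divergence_subs_per_site=0.0)
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        assert anc.species_a == ref.sequences
        assert anc.species_b == ref.sequences

    def test_fusion_reduces_chromosome_count(self):
        cfg = small_config(
            rearrangement_spec=(Fusion("chr04", "chr01", "chr02"),)
        )
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        assert len(anc.species_b) == cfg.n_chromosomes - 1
        assert "chr04" not in anc.species_b
        # arms land on the recipients, sequence conserved at divergence 0
        assert len(anc.species_b["chr01"]) == 60_000 + 30_000

    def test_fusion_missing_chromosome_raises(self):
        cfg = small_config(rearrangement_spec=(Fusion("chr09", "chr01", "chr02"),))
        ref = synthio.generate_reference(cfg)
        with pytest.raises(ValueError, match="chr09"):
            synthio.generate_ancestral_genomes(ref, cfg)

    def test_divergence_matches_binomial_expectation(self):
        # divergence 0.02 => each species is Binomial(L, 0.01) away from the guide
        cfg = small_config(divergence_subs_per_site=0.02, chrom_length=250_000)
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        L = sum(len(s) for s in ref.sequences.values())
        mism = sum(
            sum(a != b for a, b in zip(ref.sequences[c], anc.species_a[c]))
            for c in ref.sequences
        )
        expected = L * 0.01
        sd = np.sqrt(L * 0.01 * 0.99)
        assert abs(mism - expected) <= 3 * sd

    def test_segment_map_covers_every_base_once(self):
        cfg = small_config(rearrangement_spec=None, n_chromosomes=10)
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        for sp, seqs in (("A", anc.species_a), ("B", anc.species_b)):
            sub = anc.segment_map[anc.segment_map["species"] == sp]
            for chrom, seq in seqs.items():
                rows = sub[sub["chrom"] == chrom].sort_values("start")
                assert rows["start"].iloc[0] == 0
                assert rows["end"].iloc[-1] == len(seq)
                assert (rows["end"].values[:-1] == rows["start"].values[1:]).all()

    def test_coordinate_round_trip_through_ref(self):
        cfg = small_config(rearrangement_spec=None, n_chromosomes=10)
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        # an interval spanning a fusion junction maps to two guide pieces
        fused = cfg.rearrangement_spec[0].left_recipient
        junction = 60_000
        segs = anc.to_ref("B", fused, junction - 100, junction + 100)
        assert len(segs) == 2
        assert sum(e - s for _, s, e in segs) == 200
        back = [
            loc
            for rc, rs, re_ in segs
            for loc in anc.from_ref("B", rc, rs, re_)
        ]
        assert back[0][0] == fused and back[-1][0] == fused


class TestBacLibrary:
    def test_tag_extraction_counts_planted_motifs(self):
        seq = "A" * 200 + "CTGCAG" + "C" * 200 + "CTGCAG" + "G" * 200
        tags = synthio.extract_tags(seq, "CTGCAG", 50)
        assert len(tags) == 2
        assert all(t.startswith("CTGCAG") for t in tags)

    def test_no_motif_no_tags(self):
        assert synthio.extract_tags("AT" * 100, "CTGCAG", 50) == []

    def test_tag_near_end_not_extracted(self):
        seq = "A" * 100 + "CTGCAG" + "A" * 10  # only 16 bp after motif start
        assert synthio.extract_tags(seq, "CTGCAG", 50) == []

    def test_shared_tag_maps_to_both_bacs(self, dense_pipeline):
        tags = dense_pipeline.library.tags
        per_tag = tags.groupby("tag_id")["bac_id"].nunique()
        assert (per_tag > 1).any(), "dense library should share some tags"

    def test_every_bac_has_exactly_one_truth_label(self, dense_pipeline):
        lib = dense_pipeline.library
        assert set(lib.truth["bac_id"]) == set(lib.bacs["bac_id"])
        assert set(lib.bacs["species"]) <= {"A", "B"}

    def test_bac_sequence_matches_truth_coordinates(self, dense_pipeline):
        lib = dense_pipeline.library
        anc = dense_pipeline.ancestral
        row = lib.bacs.iloc[0]
        seq = anc.sequences(row.species)[row.chrom][row.start: row.end]
        if row.orient == "-":
            seq = synthio.revcomp(seq)
        assert seq == lib.sequences[row.bac_id]

    def test_insert_longer_than_chromosome_raises(self):
        cfg = small_config(bac_insert_mean=100_000, bac_insert_sd=1)
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            synthio.generate_bac_library(anc, cfg)


class TestSelfingProgeny:
    def test_carrier_fraction_near_three_quarters(self):
        cfg = small_config(n_individuals=10_000, n_markers=1)
        prog = synthio.generate_selfing_progeny(cfg)
        frac = prog.carrier.mean()
        sd = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(frac - 0.75) <= 3 * sd

    def test_error_free_reads_separate_carriers(self):
        cfg = small_config(
            seq_error=0.0, depth_mean=100.0, ploidy=4, n_markers=5, n_individuals=60
        )
        prog = synthio.generate_selfing_progeny(cfg)
        assert (prog.alt_counts[prog.carrier] > 0).all()
        assert (prog.alt_counts[~prog.carrier] == 0).all()

    def test_zero_markers_yield_empty_table_with_header(self, tmp_path):
        cfg = small_config(n_markers=0)
        prog = synthio.generate_selfing_progeny(cfg)
        path = tmp_path / "counts.tsv"
        mio.write_allele_counts(
            prog.meta, prog.ref_counts, prog.alt_counts, prog.samples, path
        )
        meta, ref, alt, samples = mio.read_allele_counts(path)
        assert len(meta) == 0 and len(samples) == cfg.n_individuals

    def test_linkage_map_markov_marginal_is_single_dose(self):
        cfg = small_config(n_markers=40, n_individuals=4_000)
        lmap = synthio.default_linkage_map(cfg, rf=0.1)
        prog = synthio.generate_selfing_progeny(cfg, linkage_map=lmap)
        fracs = prog.carrier.mean(axis=1)
        sd = np.sqrt(0.75 * 0.25 / 4_000)
        assert (np.abs(fracs - 0.75) <= 4 * sd).all()


class TestPanel:
    def test_panel_has_34_sample_columns(self):
        panel = synthio.generate_panel(small_config(), n_off=12, n_rob=9, n_spont=13)
        assert len(panel.samples) == 34

    def test_planted_diagnostic_snp_is_group_exclusive(self):
        cfg = small_config(n_markers=20, seq_error=0.0, depth_mean=150.0, ploidy=4)
        panel = synthio.generate_panel(cfg, n_diag=10)
        is_a = np.array([s.startswith(("off", "rob")) for s in panel.samples])
        for j, origin in enumerate(panel.truth["origin"]):
            carriers = panel.alt_counts[j] > 0
            if origin == "officinarum":
                assert carriers[is_a].all() and not carriers[~is_a].any()
            elif origin == "spontaneum":
                assert carriers[~is_a].all() and not carriers[is_a].any()

    def test_zero_diagnostic_markers(self):
        panel = synthio.generate_panel(small_config(n_markers=6), n_diag=0)
        assert (panel.truth["origin"] == "shared").all()


class TestDepthSimulation:
    def test_same_species_depth_near_target(self, mosaic_config):
        cfg = mosaic_config
        ref = synthio.generate_reference(cfg)
        anc = synthio.generate_ancestral_genomes(ref, cfg)
        lib = synthio.generate_bac_library(anc, cfg)
        da, db = synthio.simulate_read_depth(lib, anc, cfg)
        row = lib.bacs.iloc[0]
        own = da[row.bac_id] if row.species == "A" else db[row.bac_id]
        other = db[row.bac_id] if row.species == "A" else da[row.bac_id]
        # interior mean depth close to the configured 20x for own reads,
        # heavily suppressed for the diverged species
        assert own[500:-500].mean() > 0.6 * cfg.wgs_depth
        assert other[500:-500].mean() < 0.5 * own[500:-500].mean()

    def test_bedgraph_round_trip(self, tmp_path):
        depths = {"c1": np.array([0, 0, 5, 5, 5, 2], dtype=float)}
        path = tmp_path / "d.bedgraph"
        mio.write_bedgraph(depths, path)
        back = mio.read_bedgraph(path, {"c1": 6})
        np.testing.assert_array_equal(back["c1"], depths["c1"])
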