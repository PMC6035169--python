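"""Genotype calling, 3:1 segregation, linkage grouping and CG annotation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mosaicpath import singledose as sd, synthio
from mosaicpath.config import SimConfig
from mosaicpath.singledose import HET, HOM_ALT, HOM_REF, MISSING


class TestGenotypeCalling:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (50, 5, HET),  # depth 55, minor 5/55 = 0.091, >= 2 reads
            (100, 2, MISSING),  # 2/102 = 0.0196 in the ambiguous band
            (200, 1, HOM_REF),  # 1/201 = 0.005 < 1% error floor
            (20, 9, MISSING),  # depth 29 < 30
            (1, 200, HOM_ALT),  # mirrored error-floor call
            (400, 300, HET),  # near-balanced high depth
            (700, 100, HET),
            (1200, 0, MISSING),  # depth 1200 > 1000
            (96, 4, HET),  # boundary: minor freq exactly 4%
            (99, 1, MISSING),  # boundary: exactly 1% -> ambiguous band
        ],
    )
    def test_threshold_rules(self, ref, alt, expected):
        assert sd.call_genotype(ref, alt) == expected

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            sd.call_genotype(-1, 10)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 200, size=(30, 8))
        alt = rng.integers(0, 200, size=(30, 8))
        states = sd.call_matrix(ref, alt)
        for i in range(30):
            for j in range(8):
                assert states[i, j] == sd.call_genotype(int(ref[i, j]), int(alt[i, j]))


class TestSegregation:
    def test_worked_three_to_one(self):
        states = np.array([HET] * 140 + [HOM_REF] * 46)
        r = sd.test_single_dose(states, "m1")
        assert r.chi2 == pytest.approx(0.0072, abs=2e-4)
        assert r.p == pytest.approx(0.93, abs=0.01)
        assert r.single_dose

    def test_worked_rejection(self):
        states = np.array([HET] * 120 + [HOM_REF] * 66)
        r = sd.test_single_dose(states, "m2")
        assert r.chi2 == pytest.approx(10.9, abs=0.1)
        assert not r.single_dose

    def test_excess_missing_rejected_regardless_of_ratio(self):
        states = np.array([HET] * 111 + [HOM_REF] * 37 + [MISSING] * 38)
        r = sd.test_single_dose(states, "m3")
        assert r.n_missing == 38
        assert not r.single_dose
        assert "missing" in r.reason

    def test_all_missing_has_reason(self):
        r = sd.test_single_dose(np.array([MISSING] * 10), "m4")
        assert not r.single_dose and r.reason == "no non-missing calls"

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        reps = 2_000
        rejected = 0
        for carriers in rng.binomial(186, 0.75, size=reps):
            states = np.array([HET] * carriers + [HOM_REF] * (186 - carriers))
            if not sd.test_single_dose(states).single_dose:
                rejected += 1
        rate = rejected / reps
        sd_band = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= sd_band + 0.01  # chi2 discreteness slack

    def test_one_to_one_rejected_with_high_power(self):
        rng = np.random.default_rng(8)
        reps = 500
        rejected = sum(
            not sd.test_single_dose(
                np.array([HET] * c + [HOM_REF] * (186 - c))
            ).single_dose
            for c in rng.binomial(186, 0.5, size=reps)
        )
        assert rejected / reps >= 0.99


class TestTwoPointLinkage:
    def test_identical_vectors_rf_zero_high_lod(self):
        rng = np.random.default_rng(0)
        p = (rng.random(186) < 0.75).astype(float)
        rf, lod = sd.two_point_linkage(p, p)
        assert rf == 0.0
        assert lod > 10

    def test_self_pair_rf_zero(self):
        p = np.array([1.0, 0.0] * 30)
        rf, _ = sd.two_point_linkage(p, p)
        assert rf == 0.0

    def test_independent_markers_low_lod(self):
        rng = np.random.default_rng(1)
        lods = []
        for _ in range(100):
            a = (rng.random(186) < 0.75).astype(float)
            b = (rng.random(186) < 0.75).astype(float)
            lods.append(sd.two_point_linkage(a, b)[1])
        assert np.median(lods) < 1.0

    def test_monomorphic_marker_degenerate(self):
        a = np.ones(100)
        b = (np.arange(100) % 4 > 0).astype(float)
        assert sd.two_point_linkage(a, b) == (0.5, 0.0)

    def test_too_few_shared_individuals(self):
        a = np.array([1.0] * 5 + [np.nan] * 50)
        b = np.array([1.0] * 5 + [np.nan] * 50)
        assert sd.two_point_linkage(a, b) == (0.5, 0.0)

    def test_rf_estimate_tracks_simulated_rf(self):
        cfg = SimConfig(n_markers=2, n_individuals=2_000, seed=9)
        lmap = pd.DataFrame(
            {"marker_id": ["x", "y"], "chrom": ["c", "c"], "rf_prev": [0.5, 0.2]}
        )
        prog = synthio.generate_selfing_progeny(cfg, linkage_map=lmap)
        pres = prog.carrier.astype(float)
        rf, lod = sd.two_point_linkage(pres[0], pres[1])
        assert rf == pytest.approx(0.2, abs=0.05)
        assert lod > 10


class TestGrouping:
    def linkage_frame(self, edges, ids):
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                lod, rf = edges.get((ids[i], ids[j]), (0.0, 0.5))
                rows.append(
                    {"marker_i": ids[i], "marker_j": ids[j], "rf": rf, "lod": lod}
                )
        return pd.DataFrame(rows)

    def test_six_linked_markers_one_group(self):
        ids = [f"m{i}" for i in range(6)]
        edges = {
            (ids[i], ids[j]): (20.0, 0.1)
            for i in range(6)
            for j in range(i + 1, 6)
        }
        groups, dropped = sd.group_markers(self.linkage_frame(edges, ids), ids)
        assert len(groups) == 1 and groups[0].size == 6 and dropped == 0

    def test_four_markers_below_minimum_discarded(self):
        ids = [f"m{i}" for i in range(4)]
        edges = {
            (ids[i], ids[j]): (20.0, 0.1)
            for i in range(4)
            for j in range(i + 1, 4)
        }
        groups, dropped = sd.group_markers(self.linkage_frame(edges, ids), ids)
        assert groups == [] and dropped == 1

    def test_two_separate_clusters(self):
        ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        edges = {}
        for block in (ids[:10], ids[10:]):
            for i in range(10):
                for j in range(i + 1, 10):
                    edges[(block[i], block[j])] = (15.0, 0.2)
        groups, _ = sd.group_markers(self.linkage_frame(edges, ids), ids)
        assert len(groups) == 2
        assert {g.size for g in groups} == {10}

    def test_recovery_same_chromosome_cogrouped(self):
        """Markers at rf <= 0.2 on one chromosome group together; markers on
        different chromosomes never do (n = 186 individuals)."""
        cfg = SimConfig(
            n_chromosomes=2, n_markers=12, n_individuals=186, seed=21
        )
        lmap = synthio.default_linkage_map(cfg, rf=0.1)
        prog = synthio.generate_selfing_progeny(cfg, linkage_map=lmap)
        pres = prog.carrier.astype(float)
        ids = list(lmap["marker_id"])
        linkage = sd.pairwise_linkage(pres, ids)
        groups, _ = sd.group_markers(linkage, ids)
        chrom_of = dict(zip(lmap["marker_id"], lmap["chrom"]))
        for g in groups:
            assert len({chrom_of[m] for m in g.marker_ids}) == 1


class TestOrigin:
    def states(self, carriers_a, carriers_b, n_a=21, n_b=13):
        row = (
            [HET] * carriers_a
            + [HOM_REF] * (n_a - carriers_a)
            + [HET] * carriers_b
            + [HOM_REF] * (n_b - carriers_b)
        )
        return np.array([row], dtype=np.int8)

    samples = [f"off{i}" for i in range(12)] + [f"rob{i}" for i in range(9)] + [
        f"spont{i}" for i in range(13)
    ]
    group_a = samples[:21]
    group_b = samples[21:]

    @pytest.mark.parametrize(
        "ca,cb,expected",
        [
            (2, 0, "officinarum"),
            (1, 0, "unassigned"),
            (2, 1, "unassigned"),
            (0, 2, "spontaneum"),
            (0, 0, "unassigned"),
        ],
    )
    def test_diagnostic_rule(self, ca, cb, expected):
        origin = sd.classify_snp_origin(
            self.states(ca, cb), self.samples, self.group_a, self.group_b, ["m"]
        )
        assert origin["m"] == expected

    def test_strict_mode_blocks_on_missing(self):
        st_ = self.states(3, 0)
        st_[0, -1] = MISSING  # a spontaneum call missing
        relaxed = sd.classify_snp_origin(
            st_, self.samples, self.group_a, self.group_b, ["m"]
        )
        strict = sd.classify_snp_origin(
            st_, self.samples, self.group_a, self.group_b, ["m"], strict=True
        )
        assert relaxed["m"] == "officinarum"
        assert strict["m"] == "unassigned"

    def test_never_both_species(self):
        rng = np.random.default_rng(5)
        st_ = rng.choice([HOM_REF, HET, MISSING], size=(200, 34)).astype(np.int8)
        origin = sd.classify_snp_origin(
            st_, self.samples, self.group_a, self.group_b,
            [f"m{i}" for i in range(200)],
        )
        assert set(origin.unique()) <= {"officinarum", "spontaneum", "unassigned"}


class TestCgAnnotation:
    @pytest.mark.parametrize(
        "origins,expected",
        [
            (["officinarum"] * 20, "officinarum"),
            (["officinarum"] * 10 + ["spontaneum"] * 10, "recombinant"),
            ([], "unassigned"),
            (["unassigned"] * 5, "unassigned"),
            (["spontaneum"] * 19 + ["officinarum"], "spontaneum"),  # 95% >= 90%
            (["officinarum"] * 8 + ["spontaneum"] * 2, "recombinant"),
        ],
    )
    def test_cg_origin(self, origins, expected):
        assert sd.assign_cg_origin(origins) == expected

    @pytest.mark.parametrize(
        "chroms,expected",
        [
            (["chr03"] * 88 + ["chr01"] * 4 + [None] * 8, ["chr03"]),
            (["chr02"] * 50 + ["chr08"] * 40 + ["chr01", "chr03"] * 5, ["chr02", "chr08"]),
            (["chr05"] * 4 + ["chr06"] * 40, ["chr06"]),  # 4 markers < 5 floor
            ([None, None], []),
        ],
    )
    def test_cg_orthology(self, chroms, expected):
        assert sd.assign_cg_orthology(chroms) == expected

    def test_orthology_fraction_floor(self):
        # 6 markers on chr09 but only 6% of 100 aligned markers: excluded
        chroms = ["chr01"] * 94 + ["chr09"] * 6
        assert sd.assign_cg_orthology(chroms) == ["chr01"]
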