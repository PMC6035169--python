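"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the data layers behind a BAC-based monoploid
assembly of a mosaic interspecific polyploid:

* a guide genome with non-overlapping annotated genes,
* two ancestral genomes diverged from it by a stated substitution rate,
  the second carrying whole-arm fusions (x=10 -> x=8),
* a BAC library sampled mosaically from the two ancestral genomes and
  fingerprinted by restriction-site sequence tags,
* per-base read-depth tracks of each ancestral accession over each BAC,
  produced by a toy exact-match read placer,
* a selfing progeny with 3:1 single-dose segregation read through a
  depth/error model, and a species diagnostic SNP panel.

Every operation is deterministic given the :class:`~mosaicpath.config.SimConfig`
seed: identical configurations yield byte-identical output files.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .config import Fusion, SimConfig

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# fixed substreams so that each generator is independent of the others
_STREAMS = {
    "reference": 0,
    "ancestral": 1,
    "bacs": 2,
    "progeny": 3,
    "panel": 4,
    "depth": 5,
    "codon": 6,
}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _NT[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site independently with probability ``rate``,
    uniformly over the three alternative nucleotides (Jukes-Cantor-like)."""
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = {c: i for i, c in enumerate(_NT)}
    num = np.array([idx.get(c, 0) for c in range(256)], dtype=np.uint8)[codes]
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
    num[hit] = (num[hit] + shift) % 4
    return _NT[num].tobytes().decode("ascii")


# ----------------------------------------------------------- reference


@dataclass
class Reference:
    sequences: Dict[str, str]
    genes: pd.DataFrame  # chrom, start, end, strand, gene_id (0-based half-open)


def generate_reference(config: SimConfig) -> Reference:
    """Guide genome plus non-overlapping, strand-labelled gene annotation.

    Genes are laid out one per equal-width slot with a random in-slot
    offset, so they never overlap.  Raises :class:`ValueError` when the
    requested gene content does not fit on a chromosome.
    """
    rng = _rng(config, "reference")
    n_genes = config.n_genes_per_chrom
    if n_genes > 0:
        slot = config.chrom_length // n_genes
        if config.gene_length > slot:
            raise ValueError(
                f"gene capacity exceeded: {n_genes} genes of "
                f"{config.gene_length} bp do not fit in {config.chrom_length} bp"
            )
    sequences: Dict[str, str] = {}
    rows = []
    for chrom in config.chromosome_names:
        sequences[chrom] = _random_sequence(rng, config.chrom_length)
        for i in range(n_genes):
            slot = config.chrom_length // n_genes
            offset = int(rng.integers(0, slot - config.gene_length + 1))
            start = i * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.gene_length,
                    "strand": strand,
                    "gene_id": f"{chrom}g{i + 1:04d}",
                }
            )
    genes = pd.DataFrame(rows, columns=mio.GFF3_COLUMNS)
    return Reference(sequences=sequences, genes=genes)


# ------------------------------------------------- ancestral genomes


@dataclass
class AncestralGenomes:
    """Two genomes diverged from the guide, species B rearranged.

    ``segment_map`` covers every base of both genomes exactly once with
    rows (species, chrom, start, end, ref_chrom, ref_start, ref_end); it is
    the truth table linking ancestral coordinates to guide coordinates.
    """

    species_a: Dict[str, str]
    species_b: Dict[str, str]
    segment_map: pd.DataFrame
    rearranged_chrom_map: Dict[str, Tuple[str, str, int]]

    def sequences(self, species: str) -> Dict[str, str]:
        return self.species_a if species == "A" else self.species_b

    def _rows(self, species: str) -> pd.DataFrame:
        return self.segment_map[self.segment_map["species"] == species]

    def to_ref(
        self, species: str, chrom: str, start: int, end: int
    ) -> List[Tuple[str, int, int]]:
        """Map a species-local interval to guide intervals, in order."""
        out = []
        rows = self._rows(species)
        rows = rows[rows["chrom"] == chrom].sort_values("start")
        for row in rows.itertuples(index=False):
            lo, hi = max(start, row.start), min(end, row.end)
            if lo < hi:
                off = row.ref_start - row.start
                out.append((row.ref_chrom, lo + off, hi + off))
        return out

    def from_ref(
        self, species: str, ref_chrom: str, start: int, end: int
    ) -> List[Tuple[str, int, int]]:
        """Map a guide interval into a species' coordinates, in ref order."""
        out = []
        rows = self._rows(species)
        rows = rows[rows["ref_chrom"] == ref_chrom].sort_values("ref_start")
        for row in rows.itertuples(index=False):
            lo, hi = max(start, row.ref_start), min(end, row.ref_end)
            if lo < hi:
                off = row.start - row.ref_start
                out.append((row.chrom, lo + off, hi + off))
        return out


def generate_ancestral_genomes(
    reference: Reference, config: SimConfig
) -> AncestralGenomes:
    """Mutate the guide into species A and B, then rearrange B.

    Each species accumulates ``divergence/2`` substitutions per site away
    from the guide, so A and B differ by approximately ``divergence``
    (minus back/parallel substitutions).  Fusions in
    ``config.rearrangement_spec`` then split each donor chromosome of B
    and append its arms to two recipients.
    """
    rng = _rng(config, "ancestral")
    half = config.divergence_subs_per_site / 2.0
    species_a = {c: _mutate(rng, s, half) for c, s in reference.sequences.items()}
    species_b_flat = {c: _mutate(rng, s, half) for c, s in reference.sequences.items()}

    for fusion in config.rearrangement_spec:
        for name in (fusion.donor, fusion.left_recipient, fusion.right_recipient):
            if name not in species_b_flat:
                raise ValueError(f"fusion references missing chromosome {name!r}")

    rows = []
    for chrom, seq in species_a.items():
        rows.append(("A", chrom, 0, len(seq), chrom, 0, len(seq)))

    # apply fusions to species B; record (chrom, start..end) -> ref intervals
    b_segments: Dict[str, List[Tuple[str, int, int]]] = {
        c: [(c, 0, len(s))] for c, s in species_b_flat.items()
    }
    b_seqs: Dict[str, str] = dict(species_b_flat)
    rearranged: Dict[str, Tuple[str, str, int]] = {}
    for fusion in config.rearrangement_spec:
        donor_seq = b_seqs.pop(fusion.donor)
        donor_segs = b_segments.pop(fusion.donor)
        if len(donor_segs) != 1:
            raise ValueError(f"chromosome {fusion.donor!r} already rearranged")
        split = int(len(donor_seq) * fusion.split_frac)
        rc, rs, _ = donor_segs[0]
        b_seqs[fusion.left_recipient] += donor_seq[:split]
        b_segments[fusion.left_recipient].append((rc, rs, rs + split))
        b_seqs[fusion.right_recipient] += donor_seq[split:]
        b_segments[fusion.right_recipient].append((rc, rs + split, rs + len(donor_seq)))
        rearranged[fusion.donor] = (
            fusion.left_recipient,
            fusion.right_recipient,
            split,
        )

    for chrom, segs in b_segments.items():
        offset = 0
        for rc, rs, re_ in segs:
            rows.append(("B", chrom, offset, offset + (re_ - rs), rc, rs, re_))
            offset += re_ - rs

    segment_map = pd.DataFrame(
        rows,
        columns=["species", "chrom", "start", "end", "ref_chrom", "ref_start", "ref_end"],
    )
    return AncestralGenomes(
        species_a=species_a,
        species_b=b_seqs,
        segment_map=segment_map,
        rearranged_chrom_map=rearranged,
    )


# ------------------------------------------------------- BAC library


@dataclass
class BacLibrary:
    """Mosaic BAC clones with their restriction-site sequence tags.

    ``bacs`` columns: bac_id, species, chrom, start, end, orient, length.
    ``tags`` is the tag->BAC multimap (tag_id, bac_id, tag_seq); a tag
    sequence occurring in several BACs appears once per BAC.
    ``truth`` gives each BAC's guide-coordinate segments.
    """

    bacs: pd.DataFrame
    sequences: Dict[str, str]
    tags: pd.DataFrame
    truth: pd.DataFrame


def generate_bac_library(
    ancestral: AncestralGenomes, config: SimConfig
) -> BacLibrary:
    rng = _rng(config, "bacs")
    bac_rows, truth_rows, tag_rows = [], [], []
    sequences: Dict[str, str] = {}
    chroms = {sp: sorted(ancestral.sequences(sp)) for sp in ("A", "B")}
    for i in range(config.n_bacs):
        bac_id = f"bac{i + 1:05d}"
        species = "A" if rng.random() < config.frac_species_a else "B"
        chrom = chroms[species][int(rng.integers(0, len(chroms[species])))]
        chrom_seq = ancestral.sequences(species)[chrom]
        length = int(
            np.clip(
                rng.normal(config.bac_insert_mean, config.bac_insert_sd),
                2 * config.tag_length,
                None,
            )
        )
        if length > len(chrom_seq):
            raise ValueError(
                f"BAC insert of {length} bp exceeds chromosome {chrom} "
                f"({len(chrom_seq)} bp)"
            )
        start = int(rng.integers(0, len(chrom_seq) - length + 1))
        orient = "+" if rng.random() < 0.5 else "-"
        seq = chrom_seq[start: start + length]
        if orient == "-":
            seq = revcomp(seq)
        sequences[bac_id] = seq
        bac_rows.append(
            {
                "bac_id": bac_id,
                "species": species,
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "orient": orient,
                "length": length,
            }
        )
        for k, (rc, rs, re_) in enumerate(
            ancestral.to_ref(species, chrom, start, start + length)
        ):
            truth_rows.append(
                {
                    "bac_id": bac_id,
                    "segment": k,
                    "species": species,
                    "ref_chrom": rc,
                    "ref_start": rs,
                    "ref_end": re_,
                }
            )
        for tag_seq in extract_tags(seq, config.enzyme_motif, config.tag_length):
            tag_rows.append({"bac_id": bac_id, "tag_seq": tag_seq})

    tags = pd.DataFrame(tag_rows, columns=["bac_id", "tag_seq"])
    # stable tag ids keyed by sequence
    uniq = sorted(tags["tag_seq"].unique()) if len(tags) else []
    ids = {s: f"tag{i + 1:06d}" for i, s in enumerate(uniq)}
    tags.insert(0, "tag_id", tags["tag_seq"].map(ids) if len(tags) else [])
    tags = tags.drop_duplicates(["tag_id", "bac_id"]).reset_index(drop=True)
    return BacLibrary(
        bacs=pd.DataFrame(
            bac_rows,
            columns=["bac_id", "species", "chrom", "start", "end", "orient", "length"],
        ),
        sequences=sequences,
        tags=tags,
        truth=pd.DataFrame(
            truth_rows,
            columns=["bac_id", "segment", "species", "ref_chrom", "ref_start", "ref_end"],
        ),
    )


def extract_tags(seq: str, motif: str, tag_length: int) -> List[str]:
    """Tag sequences starting at each motif occurrence that fits in ``seq``."""
    if len(motif) < 4:
        raise ValueError("enzyme motif must be at least 4 bp")
    out = []
    for m in re.finditer(f"(?={re.escape(motif)})", seq):
        p = m.start()
        if p + tag_length <= len(seq):
            out.append(seq[p: p + tag_length])
    return out


# ------------------------------------------------- gene maps per BAC


def bac_gene_maps(library: BacLibrary, ancestral: AncestralGenomes, reference: Reference):
    """Derive per-BAC gene placements from the simulation truth.

    Stands in for the external mRNA-to-BAC alignment step: each guide gene
    fully contained in a BAC's guide-coordinate span is reported with its
    BAC-local interval and alignment orientation.  Returns a dict
    ``bac_id -> BacGeneMap`` (see :mod:`mosaicpath.stp_build`).
    """
    from .stp_build import BacGeneMap, GenePlacement

    genes = reference.genes
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    maps: Dict[str, "BacGeneMap"] = {}
    for bac in library.bacs.itertuples(index=False):
        L = bac.length
        placements: List[GenePlacement] = []
        offset = 0
        for rc, rs, re_ in ancestral.to_ref(bac.species, bac.chrom, bac.start, bac.end):
            g = by_chrom.get(rc)
            if g is not None:
                inside = g[(g["start"] >= rs) & (g["end"] <= re_)]
                for row in inside.itertuples(index=False):
                    s = offset + (row.start - rs)
                    e = offset + (row.end - rs)
                    if bac.orient == "-":
                        s, e = L - e, L - s
                    placements.append(
                        GenePlacement(
                            gene_id=row.gene_id,
                            bac_start=s,
                            bac_end=e,
                            guide_chrom=rc,
                            guide_start=row.start,
                            guide_end=row.end,
                            orientation=bac.orient,
                        )
                    )
            offset += re_ - rs
        placements.sort(key=lambda p: (p.guide_chrom, p.guide_start))
        maps[bac.bac_id] = BacGeneMap(bac_id=bac.bac_id, genes=placements)
    return maps


# ------------------------------------------------- WGS depth tracks


def simulate_read_depth(
    library: BacLibrary,
    ancestral: AncestralGenomes,
    config: SimConfig,
    max_mismatch: int = 0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Per-base depth of species A and B reads over each BAC contig.

    A toy exact-match placer: reads of ``config.read_length`` are drawn
    uniformly from the homologous interval of each ancestral genome,
    sequencing errors added at ``config.seq_error`` per base, and a read is
    placed iff its mismatch count against the BAC sequence is at most
    ``max_mismatch``.  Same-species reads differ only by errors; the other
    species' reads carry the full interspecies divergence, so their
    acceptance rate decays with divergence — the signal the coverage
    classifier consumes.
    """
    rng = _rng(config, "depth")
    rl = config.read_length
    depth_a: Dict[str, np.ndarray] = {}
    depth_b: Dict[str, np.ndarray] = {}
    for bac in library.bacs.itertuples(index=False):
        seq = library.sequences[bac.bac_id]
        L = len(seq)
        seq_codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for sp, store in (("A", depth_a), ("B", depth_b)):
            if sp == bac.species:
                mism = np.zeros(L, dtype=np.int32)
            else:
                pieces = []
                for rc, rs, re_ in ancestral.to_ref(
                    bac.species, bac.chrom, bac.start, bac.end
                ):
                    for c2, s2, e2 in ancestral.from_ref(sp, rc, rs, re_):
                        pieces.append(ancestral.sequences(sp)[c2][s2:e2])
                hom = "".join(pieces)
                if bac.orient == "-":
                    hom = revcomp(hom)
                hom_codes = np.frombuffer(hom.encode("ascii"), dtype=np.uint8)
                mism = (seq_codes != hom_codes).astype(np.int32)
            eff_rl = min(rl, L)
            cum = np.concatenate([[0], np.cumsum(mism)])
            win = cum[eff_rl:] - cum[:-eff_rl]  # length L - eff_rl + 1
            n_reads = int(rng.poisson(L * config.wgs_depth / eff_rl))
            starts = rng.integers(0, L - eff_rl + 1, size=n_reads)
            errs = rng.binomial(eff_rl, config.seq_error, size=n_reads)
            ok = win[starts] + errs <= max_mismatch
            diff = np.zeros(L + 1, dtype=np.int64)
            np.add.at(diff, starts[ok], 1)
            np.add.at(diff, starts[ok] + eff_rl, -1)
            store[bac.bac_id] = np.cumsum(diff[:-1]).astype(float)
    return depth_a, depth_b


# ------------------------------------------------- selfing progeny


@dataclass
class ProgenyData:
    meta: pd.DataFrame  # chrom, pos, ref, alt, marker_id
    ref_counts: np.ndarray  # markers x individuals
    alt_counts: np.ndarray
    samples: List[str]
    carrier: np.ndarray  # bool truth, markers x individuals
    dose: np.ndarray  # 0/1/2 truth


def default_linkage_map(config: SimConfig, rf: float = 0.05) -> pd.DataFrame:
    """Markers spread evenly over the chromosomes at a fixed adjacent
    recombination fraction; a convenience for grouping experiments."""
    per = max(1, config.n_markers // config.n_chromosomes)
    rows = []
    k = 0
    for chrom in config.chromosome_names:
        for j in range(per):
            if k >= config.n_markers:
                break
            rows.append(
                {
                    "marker_id": f"m{k + 1:05d}",
                    "chrom": chrom,
                    "rf_prev": 0.5 if j == 0 else rf,
                }
            )
            k += 1
    while k < config.n_markers:
        rows.append(
            {"marker_id": f"m{k + 1:05d}", "chrom": config.chromosome_names[-1],
             "rf_prev": rf}
        )
        k += 1
    return pd.DataFrame(rows)


def generate_selfing_progeny(
    config: SimConfig, linkage_map: Optional[pd.DataFrame] = None
) -> ProgenyData:
    """Allele counts for a selfing progeny of single-dose markers.

    Each marker sits on one homolog of a simplex parent: a selfed
    offspring carries 0, 1 or 2 doses with probabilities 1/4, 1/2, 1/4, so
    carriers (dose >= 1) appear at the 3:1 rate.  With ``linkage_map``,
    gametes follow a Markov crossover process along each chromosome at the
    stated adjacent recombination fractions; without it, markers segregate
    independently.  Read counts come from a Poisson depth model with alt
    read fraction dose/ploidy perturbed by the per-base error rate.
    """
    if config.n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    rng = _rng(config, "progeny")
    n, m = config.n_individuals, config.n_markers

    if linkage_map is not None:
        if len(linkage_map) != m:
            raise ValueError("linkage_map must have n_markers rows")
        order = linkage_map.reset_index(drop=True)
        gametes = np.zeros((2, n, m), dtype=bool)
        for g in range(2):
            prev_chrom = None
            state = np.zeros(n, dtype=bool)
            for j, row in enumerate(order.itertuples(index=False)):
                if row.chrom != prev_chrom:
                    state = rng.random(n) < 0.5
                    prev_chrom = row.chrom
                else:
                    flip = rng.random(n) < row.rf_prev
                    state = state ^ flip
                gametes[g, :, j] = state
        dose = gametes.sum(axis=0).T.astype(np.int8)  # markers x individuals
        marker_ids = list(order["marker_id"])
        chroms = list(order["chrom"])
    else:
        dose = rng.binomial(2, 0.5, size=(m, n)).astype(np.int8)
        marker_ids = [f"m{j + 1:05d}" for j in range(m)]
        chroms = ["pseudo"] * m

    depth = rng.poisson(config.depth_mean, size=(m, n))
    f = dose.astype(float) / config.ploidy
    p_alt = f * (1 - config.seq_error) + (1 - f) * config.seq_error / 3.0
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt

    ref_nt = _NT[rng.integers(0, 4, size=m)]
    alt_shift = rng.integers(1, 4, size=m)
    alt_nt = _NT[(np.searchsorted(_NT, ref_nt) + alt_shift) % 4]
    meta = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(m) * 1000,
            "ref": [chr(c) for c in ref_nt],
            "alt": [chr(c) for c in alt_nt],
            "marker_id": marker_ids,
        }
    )
    samples = [f"ind{i + 1:04d}" for i in range(n)]
    return ProgenyData(
        meta=meta,
        ref_counts=ref.astype(np.int64),
        alt_counts=alt.astype(np.int64),
        samples=samples,
        carrier=dose > 0,
        dose=dose,
    )


# ------------------------------------------------------ species panel


@dataclass
class PanelData:
    meta: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    samples: List[str]
    groups: Dict[str, List[str]]  # officinarum / robustum / spontaneum
    truth: pd.DataFrame  # marker_id, origin in {officinarum, spontaneum, shared}


def generate_panel(
    config: SimConfig,
    n_off: int = 12,
    n_rob: int = 9,
    n_spont: int = 13,
    n_diag: Optional[int] = None,
) -> PanelData:
    """Allele counts for a species panel with planted diagnostic SNPs.

    ``n_diag`` markers (default 40% of ``n_markers``, split evenly between
    the two species) are fixed-present in one species group and absent
    from the other; the remaining markers are shared at random.  The
    officinarum-side group comprises the officinarum and robustum
    accessions, mirroring how diagnostic SNPs are defined downstream.
    """
    if min(n_off, n_rob, n_spont) < 0:
        raise ValueError("group sizes must be >= 0")
    rng = _rng(config, "panel")
    m = config.n_markers
    if n_diag is None:
        n_diag = int(round(0.4 * m))
    if n_diag > m:
        raise ValueError("n_diag cannot exceed n_markers")
    off = [f"off{i + 1:02d}" for i in range(n_off)]
    rob = [f"rob{i + 1:02d}" for i in range(n_rob)]
    spont = [f"spont{i + 1:02d}" for i in range(n_spont)]
    samples = off + rob + spont
    n = len(samples)
    is_a_side = np.array([s.startswith(("off", "rob")) for s in samples])

    n_diag_a = n_diag // 2 + n_diag % 2
    origin = np.array(
        ["officinarum"] * n_diag_a
        + ["spontaneum"] * (n_diag - n_diag_a)
        + ["shared"] * (m - n_diag)
    )
    dose = np.zeros((m, n), dtype=np.int8)
    for j in range(m):
        if origin[j] == "officinarum":
            dose[j, is_a_side] = 1
        elif origin[j] == "spontaneum":
            dose[j, ~is_a_side] = 1
        else:
            dose[j] = (rng.random(n) < 0.5).astype(np.int8)

    depth = rng.poisson(config.depth_mean, size=(m, n))
    f = dose.astype(float) / config.ploidy
    p_alt = f * (1 - config.seq_error) + (1 - f) * config.seq_error / 3.0
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt

    ref_nt = _NT[rng.integers(0, 4, size=m)]
    alt_nt = _NT[(np.searchsorted(_NT, ref_nt) + rng.integers(1, 4, size=m)) % 4]
    marker_ids = [f"p{j + 1:05d}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": ["panel"] * m,
            "pos": np.arange(m) * 1000,
            "ref": [chr(c) for c in ref_nt],
            "alt": [chr(c) for c in alt_nt],
            "marker_id": marker_ids,
        }
    )
    return PanelData(
        meta=meta,
        ref_counts=ref.astype(np.int64),
        alt_counts=alt.astype(np.int64),
        samples=samples,
        groups={"officinarum": off, "robustum": rob, "spontaneum": spont},
        truth=pd.DataFrame({"marker_id": marker_ids, "origin": origin}),
    )


# ------------------------------------------------- codon alignments


def simulate_codon_alignment(
    n_codons: int, divergence: float, seed: int = 0
) -> Tuple[str, str]:
    """A toy pair of gap-free coding sequences for substitution-rate work.

    The first sequence is built from random non-stop codons; the second is
    mutated from it at ``divergence`` substitutions/site, re-drawing any
    codon that would become a stop.
    """
    from .comparer import STOP_CODONS

    rng = np.random.default_rng([seed, _STREAMS["codon"]])
    codons = []
    while len(codons) < n_codons:
        c = _NT[rng.integers(0, 4, size=3)].tobytes().decode("ascii")
        if c not in STOP_CODONS:
            codons.append(c)
    s1 = "".join(codons)
    while True:
        s2 = _mutate(rng, s1, divergence)
        bad = any(
            s2[i: i + 3] in STOP_CODONS for i in range(0, len(s2), 3)
        )
        if not bad:
            return s1, s2


# ------------------------------------------------------- full bundle


def simulate_all(config: SimConfig, outdir: str | Path) -> None:
    """Generate and write every input the downstream stages consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    mio.write_fasta(reference.sequences, out / "guide.fasta")
    mio.write_gff3(reference.genes, out / "genes.gff3")

    ancestral = generate_ancestral_genomes(reference, config)
    mio.write_fasta(ancestral.species_a, out / "species_a.fasta")
    mio.write_fasta(ancestral.species_b, out / "species_b.fasta")
    mio.write_tsv(ancestral.segment_map, out / "segment_map.tsv")

    library = generate_bac_library(ancestral, config)
    mio.write_fasta(library.sequences, out / "bacs.fasta")
    mio.write_tsv(library.bacs, out / "bacs.tsv")
    mio.write_tsv(library.truth, out / "bac_truth.tsv")
    mio.write_tag_map(library.tags, out / "tags.tsv")

    maps = bac_gene_maps(library, ancestral, reference)
    from .stp_build import gene_maps_to_frame

    mio.write_tsv(gene_maps_to_frame(maps), out / "bac_gene_map.tsv")

    depth_a, depth_b = simulate_read_depth(library, ancestral, config)
    mio.write_bedgraph(depth_a, out / "depth_species_a.bedgraph")
    mio.write_bedgraph(depth_b, out / "depth_species_b.bedgraph")

    progeny = generate_selfing_progeny(config)
    mio.write_allele_counts(
        progeny.meta, progeny.ref_counts, progeny.alt_counts, progeny.samples,
        out / "progeny_counts.tsv",
    )
    carrier = pd.DataFrame(
        progeny.carrier.astype(int),
        index=progeny.meta["marker_id"],
        columns=progeny.samples,
    )
    carrier.reset_index().to_csv(out / "progeny_truth.tsv", sep="\t", index=False)

    panel = generate_panel(config)
    mio.write_allele_counts(
        panel.meta, panel.ref_counts, panel.alt_counts, panel.samples,
        out / "panel_counts.tsv",
    )
    mio.write_tsv(panel.truth, out / "panel_truth.tsv")
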