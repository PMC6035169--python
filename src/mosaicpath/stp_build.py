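"""Single tiling path construction and super-scaffolding.

The minimum tiling path still contains sequence overlaps between adjacent
BACs.  BAC pairs sharing at least two guide genes are treated as redundant
overlapping regions; each overlap is trimmed from the BAC that loses fewer
genes (then fewer bp), so every shared gene is retained exactly once.  The
trimmed segments are then ordered and oriented by their guide gene
positions and joined with fixed-size N gaps into one super-scaffold per
guide chromosome, described by an AGP v2.1 file.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .synthio import revcomp


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    bac_start: int  # BAC-local, 0-based half-open
    bac_end: int
    guide_chrom: str
    guide_start: int
    guide_end: int
    orientation: str  # '+'/'-' alignment orientation of the BAC copy vs guide


@dataclass
class BacGeneMap:
    bac_id: str
    genes: List[GenePlacement]  # sorted by guide position

    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class StpSegment:
    bac_id: str
    start: int  # kept BAC-local interval
    end: int
    genes: List[GenePlacement]  # retained genes
    chrom: Optional[str]  # guide placement
    guide_start: Optional[int] = None
    guide_end: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def segment_id(self) -> str:
        return f"{self.bac_id}:{self.start}-{self.end}"

    def median_guide_pos(self) -> Optional[float]:
        if not self.genes:
            return None
        mids = [(g.guide_start + g.guide_end) / 2 for g in self.genes]
        return float(np.median(mids))

    def majority_reverse(self) -> bool:
        if not self.genes:
            return False
        n_rev = sum(1 for g in self.genes if g.orientation == "-")
        return n_rev * 2 > len(self.genes)  # tie -> forward


@dataclass(frozen=True)
class OverlapPair:
    bac_a: str
    bac_b: str
    shared_genes: Tuple[str, ...]


# --------------------------------------------------- overlap detection


def detect_redundant_overlaps(
    gene_maps: Dict[str, BacGeneMap], min_shared_genes: int = 2
) -> List[OverlapPair]:
    """BAC pairs sharing at least ``min_shared_genes`` guide genes."""
    by_gene: Dict[str, List[str]] = {}
    for bac_id in sorted(gene_maps):
        for gid in gene_maps[bac_id].gene_ids():
            by_gene.setdefault(gid, []).append(bac_id)
    shared: Dict[Tuple[str, str], List[str]] = {}
    for gid, bacs in by_gene.items():
        for i in range(len(bacs)):
            for j in range(i + 1, len(bacs)):
                key = tuple(sorted((bacs[i], bacs[j])))
                shared.setdefault(key, []).append(gid)
    return [
        OverlapPair(a, b, tuple(sorted(gids)))
        for (a, b), gids in sorted(shared.items())
        if len(gids) >= min_shared_genes
    ]


# ------------------------------------------------------------ collapse


def _trim_option(
    genes: List[GenePlacement], shared: set, bac_len: int, side: str
) -> Tuple[int, int, int]:
    """Cost of removing the shared genes from one BAC.

    ``side`` is 'left' when the shared genes sit at the start of this BAC
    (overlap with the previous segment) and 'right' when at its end.
    Returns (genes_lost_beyond_shared, bp_trimmed, boundary), with the trim
    boundary at the midpoint between the last removed and the first kept
    gene.
    """
    order = sorted(genes, key=lambda g: g.bac_start)
    if side == "left":
        idx = max(i for i, g in enumerate(order) if g.gene_id in shared)
        removed, kept = order[: idx + 1], order[idx + 1:]
        last_removed_end = removed[-1].bac_end
        boundary = (
            (last_removed_end + kept[0].bac_start) // 2 if kept else bac_len
        )
        bp = boundary
        extra = sum(1 for g in removed if g.gene_id not in shared)
    else:
        idx = min(i for i, g in enumerate(order) if g.gene_id in shared)
        kept, removed = order[:idx], order[idx:]
        first_removed_start = removed[0].bac_start
        boundary = (
            (kept[-1].bac_end + first_removed_start) // 2 if kept else 0
        )
        bp = bac_len - boundary
        extra = sum(1 for g in removed if g.gene_id not in shared)
    return extra, bp, boundary


def collapse_to_stp(
    mtp: pd.DataFrame,
    gene_maps: Dict[str, BacGeneMap],
    bac_lengths: Dict[str, int],
    min_shared_genes: int = 2,
) -> List[StpSegment]:
    """Collapse MTP overlaps into a single tiling path.

    Walks each chromosome's MTP in order.  For each consecutive pair
    sharing >= ``min_shared_genes`` genes, both trim choices are costed
    (genes lost from the union first, then bp removed) and the cheaper
    side is trimmed at the midpoint between the last kept and first
    removed gene.  Genes shared with any earlier, non-adjacent segment
    (three-way overlap) stay with the leftmost segment, with a warning.
    A gene shared by a pair below the redundancy threshold is likewise
    retained only in the leftmost segment (no sequence is trimmed), so no
    guide gene ever appears in two segments.
    """
    segments: List[StpSegment] = []
    for chrom in mtp["chromosome"].unique():
        order = mtp[mtp["chromosome"] == chrom].sort_values("order")
        chrom_segments: List[StpSegment] = []
        retained_earlier: set = set()
        for row in order.itertuples(index=False):
            bac_id = row.bac_id
            gmap = gene_maps.get(bac_id, BacGeneMap(bac_id, []))
            length = bac_lengths[bac_id]
            seg = StpSegment(
                bac_id=bac_id,
                start=0,
                end=length,
                genes=list(gmap.genes),
                chrom=chrom,
            )
            if chrom_segments:
                prev = chrom_segments[-1]
                prev_ids = {g.gene_id for g in prev.genes}
                cur_ids = {g.gene_id for g in seg.genes}
                shared = prev_ids & cur_ids
                earlier = (cur_ids - shared) & retained_earlier
                if earlier:
                    warnings.warn(
                        f"genes {sorted(earlier)} overlap non-adjacent segments; "
                        f"kept in the leftmost segment",
                        stacklevel=2,
                    )
                    seg.genes = [g for g in seg.genes if g.gene_id not in earlier]
                if len(shared) >= min_shared_genes:
                    cost_cur = _trim_option(seg.genes, shared, seg.length, "left")
                    cost_prev = _trim_option(prev.genes, shared, prev.length, "right")
                    if (cost_cur[0], cost_cur[1]) <= (cost_prev[0], cost_prev[1]):
                        extra, _, boundary = cost_cur
                        drop = shared | {
                            g.gene_id
                            for g in seg.genes
                            if g.bac_end <= boundary and g.gene_id not in shared
                        }
                        seg.start = boundary
                        seg.genes = [g for g in seg.genes if g.gene_id not in drop]
                    else:
                        extra, _, boundary = cost_prev
                        drop = shared | {
                            g.gene_id
                            for g in prev.genes
                            if g.bac_start >= boundary and g.gene_id not in shared
                        }
                        prev.end = min(prev.end, boundary)
                        prev.genes = [g for g in prev.genes if g.gene_id not in drop]
                elif shared:
                    # below the redundancy threshold: keep the gene copy in
                    # the leftmost segment only; no sequence trimming
                    seg.genes = [g for g in seg.genes if g.gene_id not in shared]
            chrom_segments.append(seg)
            retained_earlier.update(g.gene_id for g in seg.genes)
        segments.extend(chrom_segments)
    for seg in segments:
        if seg.genes:
            seg.guide_start = min(g.guide_start for g in seg.genes)
            seg.guide_end = max(g.guide_end for g in seg.genes)
    return segments


# ------------------------------------------------------ super-scaffolds


@dataclass
class SuperScaffold:
    chromosome: str
    segments: List[StpSegment]
    gap_size: int
    sequence: str


def build_superscaffolds(
    segments: Sequence[StpSegment],
    sequences: Dict[str, str],
    anchors: Optional[Dict[str, Tuple[str, int]]] = None,
    gap_size: int = 10_000,
) -> Tuple[Dict[str, SuperScaffold], pd.DataFrame, Dict[str, str]]:
    """Order, orient and join STP segments into per-chromosome scaffolds.

    Segments are sorted by the median guide position of their retained
    genes; a segment whose genes mostly align in reverse orientation is
    reverse-complemented.  Segments without gene evidence follow the genic
    ones, ordered by their anchor midpoint when ``anchors`` (bac_id ->
    (chromosome, midpoint)) is given; segments with neither genes nor an
    anchor go to an ``unplaced`` bin.  Returns (scaffolds, AGP frame,
    component sequences).
    """
    by_chrom: Dict[str, List[Tuple[float, int, StpSegment]]] = {}
    for k, seg in enumerate(segments):
        med = seg.median_guide_pos()
        if med is not None:
            chrom = seg.genes[0].guide_chrom
            by_chrom.setdefault(chrom, []).append((0, med, k, seg))
        elif anchors is not None and seg.bac_id in anchors:
            chrom, mid = anchors[seg.bac_id]
            by_chrom.setdefault(chrom, []).append((1, float(mid), k, seg))
        else:
            by_chrom.setdefault("unplaced", []).append((1, 0.0, k, seg))

    scaffolds: Dict[str, SuperScaffold] = {}
    agp_rows = []
    components: Dict[str, str] = {}
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1], t[3].bac_id))
        parts: List[str] = []
        pos = 0
        part_no = 0
        ordered: List[StpSegment] = []
        for _, _, _, seg in entries:
            seq = sequences[seg.bac_id][seg.start: seg.end]
            orient = "+"
            if seg.majority_reverse():
                seq = revcomp(seq)
                orient = "-"
            if parts:
                part_no += 1
                agp_rows.append(
                    {
                        "object": chrom,
                        "object_beg": pos + 1,
                        "object_end": pos + gap_size,
                        "part_number": part_no,
                        "component_type": "N",
                        "component_id": gap_size,
                        "component_beg": "scaffold",
                        "component_end": "yes",
                        "orientation": "map",
                    }
                )
                parts.append("N" * gap_size)
                pos += gap_size
            part_no += 1
            agp_rows.append(
                {
                    "object": chrom,
                    "object_beg": pos + 1,
                    "object_end": pos + len(seq),
                    "part_number": part_no,
                    "component_type": "W",
                    "component_id": seg.segment_id,
                    "component_beg": 1,
                    "component_end": len(seq),
                    "orientation": orient,
                }
            )
            components[seg.segment_id] = sequences[seg.bac_id][seg.start: seg.end]
            parts.append(seq)
            pos += len(seq)
            ordered.append(seg)
        scaffolds[chrom] = SuperScaffold(
            chromosome=chrom,
            segments=ordered,
            gap_size=gap_size,
            sequence="".join(parts),
        )
    agp = pd.DataFrame(agp_rows, columns=mio.AGP_COLUMNS)
    return scaffolds, agp, components


def agp_to_fasta(agp: pd.DataFrame, components: Dict[str, str]) -> Dict[str, str]:
    """Rebuild scaffold sequences from an AGP frame plus component FASTA."""
    out: Dict[str, List[str]] = {}
    for row in agp.itertuples(index=False):
        parts = out.setdefault(row.object, [])
        if row.component_type in ("N", "U"):
            parts.append("N" * int(row.component_id))
        else:
            seq = components[row.component_id][
                int(row.component_beg) - 1: int(row.component_end)
            ]
            if row.orientation == "-":
                seq = revcomp(seq)
            parts.append(seq)
    return {name: "".join(parts) for name, parts in out.items()}


# ------------------------------------------------------------- helpers


def gene_maps_to_frame(gene_maps: Dict[str, BacGeneMap]) -> pd.DataFrame:
    rows = []
    for bac_id in sorted(gene_maps):
        for g in gene_maps[bac_id].genes:
            rows.append(
                {
                    "bac_id": bac_id,
                    "gene_id": g.gene_id,
                    "bac_start": g.bac_start,
                    "bac_end": g.bac_end,
                    "guide_chrom": g.guide_chrom,
                    "guide_start": g.guide_start,
                    "guide_end": g.guide_end,
                    "orientation": g.orientation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "bac_id", "gene_id", "bac_start", "bac_end",
            "guide_chrom", "guide_start", "guide_end", "orientation",
        ],
    )


def frame_to_gene_maps(df: pd.DataFrame) -> Dict[str, BacGeneMap]:
    maps: Dict[str, BacGeneMap] = {}
    for bac_id, group in df.groupby("bac_id"):
        placements = [
            GenePlacement(
                gene_id=r.gene_id,
                bac_start=int(r.bac_start),
                bac_end=int(r.bac_end),
                guide_chrom=r.guide_chrom,
                guide_start=int(r.guide_start),
                guide_end=int(r.guide_end),
                orientation=r.orientation,
            )
            for r in group.itertuples(index=False)
        ]
        placements.sort(key=lambda p: (p.guide_chrom, p.guide_start))
        maps[str(bac_id)] = BacGeneMap(bac_id=str(bac_id), genes=placements)
    return maps
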