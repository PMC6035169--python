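"""BAC anchoring on a guide genome from sequence-tag placements.

The anchoring rule: a BAC is anchored when its best window of ``window``
bp (300 kb by default) on one guide chromosome contains at least
``max(min_count, ceil(min_frac * total_tags))`` uniquely placed tags —
the "at least 20% of the tags, representing a minimum of three tags, in a
300-kb window" criterion.  Multi-position tags whose hits fall inside an
anchored window are then rescued as supplementary support, and a greedy
minimum tiling path is selected from the anchored set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthio import revcomp


@dataclass(frozen=True)
class AnchorParams:
    window: int = 300_000
    min_frac: float = 0.20
    min_count: int = 3

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def threshold(self, total_tags: int) -> int:
        return max(self.min_count, math.ceil(self.min_frac * total_tags))


@dataclass
class TagPlacement:
    tag_id: str
    bac_id: str
    hits: List[Tuple[str, int, str]]  # (chrom, start, strand)

    @property
    def uniqueness(self) -> str:
        if len(self.hits) == 0:
            return "unplaced"
        return "unique" if len(self.hits) == 1 else "multi"


@dataclass
class AnchoredBac:
    bac_id: str
    chromosome: str
    start: int  # anchor interval, 0-based half-open
    end: int
    window_start: int  # the winning window itself
    window_end: int
    supporting_unique_tags: int
    rescued_multi_tags: int = 0
    total_tags: int = 0

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ------------------------------------------------------------ dedup


def deduplicate_tags(tags: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Drop tag sequences shared by distinct BACs.

    Input is the tag->BAC multimap (columns tag_id, bac_id, and optionally
    tag_seq).  Returns the retained rows — each surviving tag belongs to
    exactly one BAC — and the number of discarded tag sequences.
    """
    if tags.empty:
        return tags.copy(), 0
    n_bacs = tags.groupby("tag_id")["bac_id"].transform("nunique")
    kept = tags[n_bacs == 1].reset_index(drop=True)
    discarded = tags.loc[n_bacs > 1, "tag_id"].nunique()
    return kept, discarded


# --------------------------------------------------------- placement


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit packed codes of every k-mer (k <= 32) of a code array."""
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    wide = codes.astype(np.uint64)
    out = np.zeros(codes.size - k + 1, dtype=np.uint64)
    for j in range(k):
        out |= wide[j: codes.size - k + 1 + j] << np.uint64(2 * (k - 1 - j))
    return out


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE_LUT[_c] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GuideIndex:
    """Seed-and-verify exact/1-mismatch matcher for fixed-length tags.

    Seeds are the packed ``seed_len``-mers of the guide (both query
    orientations are handled by also seeding each tag's reverse
    complement); candidate positions are verified by direct string
    comparison.  Tag length must not exceed ``2 * seed_len`` so that one
    of the two non-overlapping halves of a tag is mismatch-free whenever
    at most one mismatch is allowed (pigeonhole).
    """

    def __init__(self, sequences: Dict[str, str], tag_length: int):
        if tag_length < 8:
            raise ValueError("tag_length must be >= 8 for the built-in index")
        self.tag_length = tag_length
        self.seed_len = min(32, tag_length // 2)
        if tag_length > 2 * self.seed_len:
            self.seed_len = 32
            if tag_length > 64:
                raise ValueError("built-in placer supports tags up to 64 bp")
        self.sequences = sequences
        self.chroms = sorted(sequences)
        self._codes = {}
        self._sorted = {}
        for chrom in self.chroms:
            codes = _kmer_codes(_encode(sequences[chrom]), self.seed_len)
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes
            self._sorted[chrom] = (codes[order], order)

    def _seed_positions(self, chrom: str, code: int) -> np.ndarray:
        sorted_codes, order = self._sorted[chrom]
        code = np.uint64(code)  # avoid a full-array dtype cast per query
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        return order[lo:hi]

    def find(self, tag: str, mismatches: int = 0) -> List[Tuple[str, int, str]]:
        """All placements of ``tag`` with at most ``mismatches`` (0 or 1)."""
        if mismatches not in (0, 1):
            raise ValueError("mismatches must be 0 or 1")
        L = self.tag_length
        if len(tag) != L:
            raise ValueError(f"tag length {len(tag)} != index tag_length {L}")
        s = self.seed_len
        hits = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            q = _encode(query)
            if (q == 255).any():
                continue
            seeds = [(0, int(_kmer_codes(q[:s], s)[0]))]
            if mismatches == 1:
                seeds.append((L - s, int(_kmer_codes(q[L - s:], s)[0])))
            cand = set()
            for off, code in seeds:
                for chrom in self.chroms:
                    for p in self._seed_positions(chrom, code):
                        start = int(p) - off
                        if 0 <= start <= len(self.sequences[chrom]) - L:
                            cand.add((chrom, start))
            for chrom, start in cand:
                ref = self.sequences[chrom][start: start + L]
                mm = sum(a != b for a, b in zip(ref, query))
                if mm <= mismatches:
                    hits.append((chrom, start, strand))
        # a palindromic exact hit would appear once per strand; keep both —
        # callers classify uniqueness by distinct (chrom, start) positions
        return sorted(set(hits))


def place_tags(
    tags: pd.DataFrame,
    guide: Optional[Dict[str, str]] = None,
    placements_table: Optional[pd.DataFrame] = None,
    mismatches: int = 0,
) -> Dict[str, TagPlacement]:
    """Classify every tag as unique/multi/unplaced on the guide.

    Either align tag sequences with the built-in exact-match index
    (``guide`` given; ``mismatches`` 0 or 1) or consume an external
    BED-like placement table keyed by tag_id.  Uniqueness counts distinct
    (chromosome, start) positions.
    """
    if tags.empty:
        return {}
    if (guide is None) == (placements_table is None):
        raise ValueError("provide exactly one of guide or placements_table")
    rows = tags.drop_duplicates(["tag_id", "bac_id"])
    placements: Dict[str, TagPlacement] = {}
    if guide is not None:
        if "tag_seq" not in rows.columns:
            raise ValueError("tag table must carry tag_seq to use the built-in index")
        tag_length = len(rows["tag_seq"].iloc[0])
        index = GuideIndex(guide, tag_length)
        cache: Dict[str, List[Tuple[str, int, str]]] = {}
        for row in rows.itertuples(index=False):
            if row.tag_seq not in cache:
                cache[row.tag_seq] = index.find(row.tag_seq, mismatches)
            hits = cache[row.tag_seq]
            positions = sorted({(c, p) for c, p, _ in hits})
            strand_of = {(c, p): s for c, p, s in hits}
            placements[f"{row.tag_id}@{row.bac_id}"] = TagPlacement(
                tag_id=row.tag_id,
                bac_id=row.bac_id,
                hits=[(c, p, strand_of[(c, p)]) for c, p in positions],
            )
    else:
        by_tag: Dict[str, List[Tuple[str, int, str]]] = {}
        for row in placements_table.itertuples(index=False):
            by_tag.setdefault(row.tag_id, []).append((row.chrom, row.start, row.strand))
        for row in rows.itertuples(index=False):
            placements[f"{row.tag_id}@{row.bac_id}"] = TagPlacement(
                tag_id=row.tag_id,
                bac_id=row.bac_id,
                hits=sorted(by_tag.get(row.tag_id, [])),
            )
    return placements


# ---------------------------------------------------------- anchoring


def anchor_bac(
    bac_id: str,
    bac_placements: Sequence[TagPlacement],
    params: AnchorParams = AnchorParams(),
) -> Optional[AnchoredBac]:
    """Anchor one BAC from its (deduplicated) tag placements, or ``None``.

    Only uniquely placed tags count.  The window slides over unique-tag
    positions (event-driven; ties between equal-count windows resolved
    leftmost, chromosomes in sorted order), and the anchor interval spans
    the supporting tag starts inside the winning window.
    """
    total = len(bac_placements)
    by_chrom: Dict[str, List[int]] = {}
    for pl in bac_placements:
        if pl.uniqueness == "unique":
            chrom, pos, _ = pl.hits[0]
            by_chrom.setdefault(chrom, []).append(pos)
    best: Optional[Tuple[int, str, int, int]] = None  # count, chrom, lo_idx, hi_idx
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        j = 0
        for i in range(len(pos)):
            while pos[j] + params.window <= pos[i]:
                j += 1
            count = i - j + 1
            if best is None or count > best[0]:
                best = (count, chrom, j, i, pos)
    if best is None:
        return None
    count, chrom, j, i, pos = best
    if count < params.threshold(total):
        return None
    lo, hi = pos[j], pos[i]
    return AnchoredBac(
        bac_id=bac_id,
        chromosome=chrom,
        start=lo,
        end=max(hi, lo + 1),
        window_start=pos[j],
        window_end=pos[j] + params.window,
        supporting_unique_tags=count,
        total_tags=total,
    )


def anchor_all(
    placements: Dict[str, TagPlacement] | Iterable[TagPlacement],
    params: AnchorParams = AnchorParams(),
) -> Dict[str, AnchoredBac]:
    if isinstance(placements, dict):
        placements = placements.values()
    by_bac: Dict[str, List[TagPlacement]] = {}
    for pl in placements:
        by_bac.setdefault(pl.bac_id, []).append(pl)
    anchored = {}
    for bac_id in sorted(by_bac):
        a = anchor_bac(bac_id, by_bac[bac_id], params)
        if a is not None:
            anchored[bac_id] = a
    return anchored


def rescue_multi_tags(
    anchored: Dict[str, AnchoredBac],
    placements: Dict[str, TagPlacement] | Iterable[TagPlacement],
    params: AnchorParams = AnchorParams(),
) -> Dict[str, AnchoredBac]:
    """Credit multi-position tags whose hits land in an anchored window.

    Never changes the anchored/unanchored decision; the anchor interval
    may widen to include rescued hits but stays inside the winning window.
    """
    if isinstance(placements, dict):
        placements = placements.values()
    multi_by_bac: Dict[str, List[TagPlacement]] = {}
    for pl in placements:
        if pl.uniqueness == "multi":
            multi_by_bac.setdefault(pl.bac_id, []).append(pl)
    out: Dict[str, AnchoredBac] = {}
    for bac_id, anchor in anchored.items():
        rescued = 0
        lo, hi = anchor.start, anchor.end
        for pl in multi_by_bac.get(bac_id, []):
            inside = [
                p
                for c, p, _ in pl.hits
                if c == anchor.chromosome
                and anchor.window_start <= p < anchor.window_end
            ]
            if inside:
                rescued += 1
                lo = min(lo, min(inside))
                hi = max(hi, max(inside))
        out[bac_id] = replace(
            anchor, start=lo, end=max(hi, lo + 1), rescued_multi_tags=rescued
        )
    return out


# ------------------------------------------------- minimum tiling path


def select_mtp(
    anchored: Dict[str, AnchoredBac] | Iterable[AnchoredBac],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Greedy minimum tiling path over the anchored BAC intervals.

    Scans each chromosome left to right over the guide genes that are
    fully contained in at least one anchored BAC; at each step the
    candidate containing the leftmost uncovered gene that extends coverage
    furthest right is selected (ties: more contained genes, then
    lexicographic bac_id).  This is the optimal interval point-cover
    greedy, so the result covers every coverable gene with a minimum
    number of BACs.  Returns a frame (chromosome, order, bac_id, start, end).
    """
    if isinstance(anchored, dict):
        bacs = list(anchored.values())
    else:
        bacs = list(anchored)
    if not bacs:
        raise ValueError("select_mtp requires at least one anchored BAC")
    rows = []
    for chrom, group in _group_by_chrom(bacs).items():
        cgenes = genes[genes["chrom"] == chrom].sort_values("start")
        gene_iv = list(
            zip(cgenes["start"].tolist(), cgenes["end"].tolist(), cgenes["gene_id"])
        )

        def contains(b: AnchoredBac, g: Tuple[int, int, str]) -> bool:
            return b.start <= g[0] and g[1] <= b.end

        coverable = [g for g in gene_iv if any(contains(b, g) for b in group)]
        selected: List[AnchoredBac] = []
        covered: set = set()
        for g in coverable:
            if g[2] in covered:
                continue
            candidates = [b for b in group if contains(b, g)]
            candidates.sort(
                key=lambda b: (
                    -b.end,
                    -sum(1 for x in coverable if contains(b, x)),
                    b.bac_id,
                )
            )
            pick = candidates[0]
            selected.append(pick)
            covered.update(x[2] for x in coverable if contains(pick, x))
        selected.sort(key=lambda b: (b.start, b.bac_id))
        for order, b in enumerate(selected):
            rows.append(
                {
                    "chromosome": chrom,
                    "order": order,
                    "bac_id": b.bac_id,
                    "start": b.start,
                    "end": b.end,
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "order", "bac_id", "start", "end"])


def _group_by_chrom(bacs: Sequence[AnchoredBac]) -> Dict[str, List[AnchoredBac]]:
    out: Dict[str, List[AnchoredBac]] = {}
    for b in bacs:
        out.setdefault(b.chromosome, []).append(b)
    return {c: sorted(v, key=lambda b: (b.start, b.bac_id)) for c, v in sorted(out.items())}


def anchors_to_frame(anchored: Dict[str, AnchoredBac]) -> pd.DataFrame:
    rows = [
        {
            "bac_id": a.bac_id,
            "chromosome": a.chromosome,
            "start": a.start,
            "end": a.end,
            "midpoint": a.midpoint,
            "supporting_unique_tags": a.supporting_unique_tags,
            "rescued_multi_tags": a.rescued_multi_tags,
            "total_tags": a.total_tags,
        }
        for a in anchored.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "bac_id", "chromosome", "start", "end", "midpoint",
            "supporting_unique_tags", "rescued_multi_tags", "total_tags",
        ],
    ).sort_values(["chromosome", "start", "bac_id"]).reset_index(drop=True)
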