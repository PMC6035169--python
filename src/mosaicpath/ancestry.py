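"""Ancestral-species assignment of BAC contigs.

Stage one compares whole-genome read coverage of each contig by the two
candidate ancestral accessions: the covered-base fractions (depth at or
above ``min_depth``) are compared, and a contig is assigned to the species
with at least ``delta`` (10%) more covered fraction.  Stage two handles
contigs the coverage rule leaves unassigned (above a length floor) with
species-specific canonical 24-mers harvested from repetitive
(depth > mean + 2 SD) and well-covered (within 1 SD of the mean) regions of
the already-assigned contigs: the contig goes to the species whose k-mer
set masks strictly more of its sequence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .synthio import revcomp


@dataclass
class CoverageProfile:
    contig_id: str
    depth_a: np.ndarray
    depth_b: np.ndarray
    min_depth: int = 5

    def __post_init__(self) -> None:
        self.depth_a = np.asarray(self.depth_a, dtype=float)
        self.depth_b = np.asarray(self.depth_b, dtype=float)
        if self.depth_a.shape != self.depth_b.shape:
            raise ValueError("depth arrays must have equal length")
        if (self.depth_a < 0).any() or (self.depth_b < 0).any():
            raise ValueError("depths must be >= 0")


@dataclass
class AncestryCall:
    contig_id: str
    label: str  # species_a | species_b | unassigned
    method: Optional[str] = None  # coverage | kmer
    covered_fraction_a: Optional[float] = None
    covered_fraction_b: Optional[float] = None
    masked_bases_a: Optional[int] = None
    masked_bases_b: Optional[int] = None
    reason: Optional[str] = None


# ----------------------------------------------------------- coverage


def classify_by_coverage(profile: CoverageProfile, delta: float = 0.10) -> AncestryCall:
    """Assign by covered-base fraction difference of at least ``delta``."""
    n = profile.depth_a.size
    if n == 0:
        raise ValueError(f"contig {profile.contig_id!r} has zero length")
    fa = float((profile.depth_a >= profile.min_depth).mean())
    fb = float((profile.depth_b >= profile.min_depth).mean())
    if fa - fb >= delta:
        label, method = "species_a", "coverage"
    elif fb - fa >= delta:
        label, method = "species_b", "coverage"
    else:
        label, method = "unassigned", None
    return AncestryCall(
        contig_id=profile.contig_id,
        label=label,
        method=method,
        covered_fraction_a=fa,
        covered_fraction_b=fb,
    )


# --------------------------------------------------- diagnostic k-mers


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _all_kmers(seq: str, k: int) -> Set[str]:
    return {canonical(seq[i: i + k]) for i in range(len(seq) - k + 1)}


def _qualifying_mask(depth: np.ndarray) -> np.ndarray:
    """Bases in repetitive (depth > mean + 2 SD) or well-covered
    (within 1 SD of the mean) regions of a same-species depth track."""
    mean = float(depth.mean())
    sd = float(depth.std())
    return (depth > mean + 2 * sd) | (np.abs(depth - mean) <= sd)


def extract_diagnostic_kmers(
    contigs: Dict[str, str],
    calls: Sequence[AncestryCall],
    profiles: Dict[str, CoverageProfile],
    k: int = 24,
) -> Tuple[Set[str], Set[str]]:
    """Species-specific canonical k-mer sets from assigned contigs.

    Candidates come from qualifying regions (see :func:`_qualifying_mask`)
    of each assigned contig's own-species depth track; each species' final
    set excludes every k-mer seen anywhere in the other species' assigned
    contigs, so the two sets are disjoint by construction.
    """
    assigned = {c.contig_id: c.label for c in calls if c.label != "unassigned"}
    if not any(v == "species_a" for v in assigned.values()) or not any(
        v == "species_b" for v in assigned.values()
    ):
        raise ValueError(
            "need at least one contig assigned to each species; "
            "run the coverage stage first"
        )
    cand = {"species_a": set(), "species_b": set()}
    universe = {"species_a": set(), "species_b": set()}
    for contig_id, label in assigned.items():
        seq = contigs[contig_id]
        profile = profiles[contig_id]
        depth = profile.depth_a if label == "species_a" else profile.depth_b
        ok = _qualifying_mask(depth)
        universe[label] |= _all_kmers(seq, k)
        # k-mers fully inside a qualifying run
        run = 0
        for i in range(len(seq)):
            run = run + 1 if ok[i] else 0
            if run >= k:
                cand[label].add(canonical(seq[i - k + 1: i + 1]))
    set_a = cand["species_a"] - universe["species_b"]
    set_b = cand["species_b"] - universe["species_a"]
    return set_a, set_b


def classify_by_kmers(
    contig_id: str,
    sequence: str,
    set_a: Set[str],
    set_b: Set[str],
    k: int = 24,
    min_length: int = 50_000,
) -> AncestryCall:
    """Assign a long unassigned contig by diagnostic k-mer masking.

    The contig is assigned to the species whose k-mers mask strictly more
    bases (union of k-length windows); equal masking — including none —
    leaves it unassigned.  Contigs at or below ``min_length`` are skipped
    with the reason recorded.
    """
    if len(sequence) <= min_length:
        return AncestryCall(
            contig_id=contig_id,
            label="unassigned",
            reason=f"length {len(sequence)} <= min_length {min_length}",
        )
    masked = {}
    for name, kset in (("a", set_a), ("b", set_b)):
        mask = np.zeros(len(sequence), dtype=bool)
        if kset:
            for i in range(len(sequence) - k + 1):
                if canonical(sequence[i: i + k]) in kset:
                    mask[i: i + k] = True
        masked[name] = int(mask.sum())
    if masked["a"] > masked["b"]:
        label, method = "species_a", "kmer"
    elif masked["b"] > masked["a"]:
        label, method = "species_b", "kmer"
    else:
        label, method = "unassigned", None
    return AncestryCall(
        contig_id=contig_id,
        label=label,
        method=method,
        masked_bases_a=masked["a"],
        masked_bases_b=masked["b"],
    )


# ------------------------------------------------------------ pipeline


def classify_all(
    contigs: Dict[str, str],
    profiles: Dict[str, CoverageProfile],
    delta: float = 0.10,
    k: int = 24,
    min_length: int = 50_000,
    use_kmer_fallback: bool = True,
) -> List[AncestryCall]:
    """Coverage stage over all contigs, then the k-mer fallback for the
    remainder (when both species have coverage-assigned contigs)."""
    calls = [classify_by_coverage(profiles[c], delta=delta) for c in sorted(contigs)]
    if use_kmer_fallback:
        have_a = any(c.label == "species_a" for c in calls)
        have_b = any(c.label == "species_b" for c in calls)
        if have_a and have_b:
            set_a, set_b = extract_diagnostic_kmers(contigs, calls, profiles, k=k)
            for i, call in enumerate(calls):
                if call.label == "unassigned":
                    retry = classify_by_kmers(
                        call.contig_id,
                        contigs[call.contig_id],
                        set_a,
                        set_b,
                        k=k,
                        min_length=min_length,
                    )
                    if retry.label != "unassigned":
                        calls[i] = retry
    return calls


def summarize_ancestry(
    calls: Sequence[AncestryCall], lengths: Dict[str, int]
) -> pd.DataFrame:
    """Assigned bp and genome fractions per species (remainder unassigned)."""
    total = sum(lengths.values())
    bp = {"species_a": 0, "species_b": 0, "unassigned": 0}
    n = {"species_a": 0, "species_b": 0, "unassigned": 0}
    for call in calls:
        bp[call.label] += lengths[call.contig_id]
        n[call.label] += 1
    rows = [
        {
            "label": label,
            "n_contigs": n[label],
            "bp": bp[label],
            "fraction": (bp[label] / total) if total else 0.0,
        }
        for label in ("species_a", "species_b", "unassigned")
    ]
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[AncestryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "label": c.label,
                "method": c.method or "",
                "covered_fraction_a": c.covered_fraction_a,
                "covered_fraction_b": c.covered_fraction_b,
                "masked_bases_a": c.masked_bases_a,
                "masked_bases_b": c.masked_bases_b,
                "reason": c.reason or "",
            }
            for c in calls
        ]
    )
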