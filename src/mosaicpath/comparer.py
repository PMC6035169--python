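"""Orthology, colinearity and molecular dating.

Reciprocal best hits with identity/coverage floors define ortholog pairs;
pairs are flagged colinear when the subject gene falls in the query's
expected orthologous guide region.  Synonymous substitution rates follow
Nei & Gojobori (1986): per-codon synonymous site fractions from the
standard genetic code, observed differences decomposed over all shortest
mutational paths with equal weight (paths through stop codons excluded),
and the Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p).  Divergence
time uses T = Ks / (2k); LTR insertion ages use the Kimura two-parameter
distance with its own clock rate.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA: Dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: Tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"
_PURINES = frozenset("AG")


class SaturationError(ValueError):
    """Distance correction undefined: observed divergence at saturation."""


@dataclass(frozen=True)
class DatingParams:
    #: synonymous-substitution clock, substitutions/site/year
    k_site_rate: float = 6.5e-9
    #: LTR divergence clock, substitutions/site/year
    ltr_rate: float = 1.3e-8


@dataclass
class NGResult:
    ks: float
    ka: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int


# ------------------------------------------------------------- NG86


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon: at each position, the fraction of
    the three single-nucleotide changes that preserve the amino acid
    (changes to stop codons count as non-synonymous)."""
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if CODON_TO_AA.get(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def codon_path_counts(c1: str, c2: str) -> Tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two codons.

    All orderings of the differing positions are enumerated; paths that
    pass through a stop codon are excluded (when every path does, all are
    used).  Counts are averaged over the admitted paths with equal weight.
    """
    for c in (c1, c2):
        if c not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    admitted = [steps for stop, steps in paths if not stop] or [
        steps for _, steps in paths
    ]
    sd = nd = 0.0
    for steps in admitted:
        for a, b in steps:
            aa_a = CODON_TO_AA.get(a)
            aa_b = CODON_TO_AA.get(b)
            if aa_a is not None and aa_a == aa_b:
                sd += 1.0
            else:
                nd += 1.0
    k = len(admitted)
    return sd / k, nd / k


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        raise SaturationError(
            f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log(arg)


def _clean_codon_pair(a: str, b: str) -> bool:
    return all(ch in _BASES for ch in a + b)


def ks_ng86(seq1: str, seq2: str) -> NGResult:
    """Nei-Gojobori Ks/Ka for one aligned codon pair of sequences.

    Sequences must be equal length and a multiple of 3; codons containing
    gaps or ambiguous bases are dropped pairwise, and a terminal stop pair
    is ignored.  Internal stop codons raise :class:`ValueError`;
    saturation (pS or pN >= 3/4) raises :class:`SaturationError`.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()
    codons = [
        (seq1[i: i + 3], seq2[i: i + 3]) for i in range(0, len(seq1), 3)
    ]
    if codons and codons[-1][0] in STOP_CODONS and codons[-1][1] in STOP_CODONS:
        codons = codons[:-1]
    S = N = Sd = Nd = 0.0
    n_used = 0
    for k, (a, b) in enumerate(codons):
        if not _clean_codon_pair(a, b):
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {k + 1}")
        s = (syn_site_fraction(a) + syn_site_fraction(b)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = codon_path_counts(a, b)
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("no comparable codons after filtering")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return NGResult(
        ks=_jc_correct(pS),
        ka=_jc_correct(pN),
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=Sd,
        nonsyn_diffs=Nd,
        n_codons=n_used,
    )


# ------------------------------------------------------------- K2P


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance of an aligned pair.

    Gap columns are removed; with transition fraction P and transversion
    fraction Q over the compared sites,
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    n = ts = tv = 0
    for a, b in zip(seq1, seq2):
        if a not in _BASES or b not in _BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError("K2P distance undefined: divergence at saturation")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


# ----------------------------------------------------------- dating


def divergence_time(median_ks: float, params: DatingParams = DatingParams()) -> float:
    """Divergence time in years: T = Ks / (2k)."""
    if median_ks < 0:
        raise ValueError("median_ks must be >= 0")
    return median_ks / (2.0 * params.k_site_rate)


def ltr_insertion_time(d: float, params: DatingParams = DatingParams()) -> float:
    """LTR insertion age in years from the LTR-LTR distance: T = d / (2r)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return d / (2.0 * params.ltr_rate)


# ----------------------------------------------------- orthology (RBH)


def _best_hits(records: pd.DataFrame) -> pd.DataFrame:
    """Top-scoring subject per query; ties by higher identity, then
    lexicographic subject id."""
    ordered = records.sort_values(
        ["query", "score", "identity", "subject"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("query", keep="first")


def reciprocal_best_hits(
    ab: pd.DataFrame,
    ba: pd.DataFrame,
    min_identity: float = 70.0,
    min_coverage: float = 40.0,
) -> pd.DataFrame:
    """Reciprocal best hits between two gene sets.

    Inputs are similarity tables (query, subject, identity, coverage,
    score).  A pair is kept when each gene is the other's best hit and
    both records meet the identity and coverage floors.  Returns a frame
    (gene_a, gene_b, identity, coverage) sorted by gene_a.
    """
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba).set_index("query")
    rows = []
    for rec in best_ab.itertuples(index=False):
        if rec.subject not in best_ba.index:
            continue
        back = best_ba.loc[rec.subject]
        if back["subject"] != rec.query:
            continue
        if (
            rec.identity >= min_identity
            and rec.coverage >= min_coverage
            and back["identity"] >= min_identity
            and back["coverage"] >= min_coverage
        ):
            rows.append(
                {
                    "gene_a": rec.query,
                    "gene_b": rec.subject,
                    "identity": min(rec.identity, back["identity"]),
                    "coverage": min(rec.coverage, back["coverage"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "identity", "coverage"]
    ).sort_values("gene_a").reset_index(drop=True)


# --------------------------------------------------------- colinearity


def classify_colinearity(
    pairs: pd.DataFrame,
    host_region: Dict[str, Optional[Tuple[str, int, int]]],
    subject_interval: Dict[str, Tuple[str, int, int]],
) -> pd.Series:
    """Colinear / non_colinear / undetermined flag per ortholog pair.

    ``host_region`` maps each query gene to the guide orthologous region
    of its host segment (``None`` when the host is unanchored);
    ``subject_interval`` gives each subject gene's guide interval.  A pair
    is colinear when the subject overlaps the host's region.
    """
    flags = []
    for rec in pairs.itertuples(index=False):
        region = host_region.get(rec.gene_a)
        if region is None:
            flags.append("undetermined")
            continue
        chrom, start, end = region
        s_chrom, s_start, s_end = subject_interval[rec.gene_b]
        if s_chrom == chrom and s_start < end and start < s_end:
            flags.append("colinear")
        else:
            flags.append("non_colinear")
    return pd.Series(flags, index=pairs.index, name="colinear")


def colinearity_rates(flags: pd.Series) -> Dict[str, float]:
    """Colinear/non-colinear fractions among determined pairs."""
    determined = flags[flags != "undetermined"]
    n = len(determined)
    if n == 0:
        return {"colinear": math.nan, "non_colinear": math.nan, "n": 0}
    return {
        "colinear": float((determined == "colinear").mean()),
        "non_colinear": float((determined == "non_colinear").mean()),
        "n": n,
    }
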