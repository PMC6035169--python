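"""Single-dose SNP identification, cosegregation grouping and annotation.

In a high polyploid, alleles present on exactly one hom(oe)olog (single
dose) are the mappable markers: selfing a simplex parent yields carriers
and non-carriers at 3:1.  This module calls genotypes from allele counts
under depth/frequency thresholds, retains markers whose presence/absence
fits 3:1 by Pearson chi-square with limited missing data, clusters them
into cosegregation groups by two-point linkage (single linkage over
LOD/recombination-fraction edges), and annotates groups with an ancestral
species origin and guide-chromosome orthology.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.csgraph import connected_components

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, 3
STATE_LABELS = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


@dataclass(frozen=True)
class CallingParams:
    min_depth: int = 30
    max_depth: int = 1000
    min_minor_reads: int = 2
    min_minor_freq: float = 0.04
    missing_band: Tuple[float, float] = (0.01, 0.04)
    hom_max_freq: float = 0.01
    diallelic_only: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.missing_band
        if not (0 <= self.hom_max_freq <= lo <= hi <= self.min_minor_freq <= 0.5):
            raise ValueError("inconsistent frequency thresholds")


@dataclass(frozen=True)
class SegregationParams:
    alpha: float = 0.05
    max_missing_frac: float = 0.20


@dataclass
class SegregationResult:
    marker_id: str
    n_present: int
    n_absent: int
    n_missing: int
    chi2: float
    p: float
    single_dose: bool
    reason: str = ""


@dataclass(frozen=True)
class LinkageParams:
    lod_threshold: float = 10.0
    max_rf: float = 0.35
    min_group_size: int = 5
    min_shared: int = 20


@dataclass(frozen=True)
class OrthologyParams:
    min_markers: int = 5
    min_frac: float = 0.10


@dataclass
class CosegregationGroup:
    cg_id: str
    marker_ids: List[str]
    origin: str = "unassigned"
    chromosomes: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.marker_ids)


# ------------------------------------------------------ genotype calls


def call_genotype(
    ref_count: int, alt_count: int, params: CallingParams = CallingParams()
) -> int:
    """Call one genotype from (ref, alt) read counts.

    Depth outside [min_depth, max_depth] is missing.  Otherwise the minor
    allele frequency decides: >= ``min_minor_freq`` with at least
    ``min_minor_reads`` reads is heterozygous; below ``hom_max_freq``
    (sequencing error) is homozygous for the major allele; the band in
    between is ambiguous and set missing, as is a frequent minor allele
    supported by too few reads.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be >= 0")
    return int(
        call_matrix(
            np.array([[ref_count]]), np.array([[alt_count]]), params
        )[0, 0]
    )


def call_matrix(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    params: CallingParams = CallingParams(),
) -> np.ndarray:
    """Vectorised genotype calls for a markers x samples count matrix."""
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be >= 0")
    depth = ref + alt
    minor = np.minimum(ref, alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    out = np.full(ref.shape, MISSING, dtype=np.int8)
    in_depth = (depth >= params.min_depth) & (depth <= params.max_depth)
    lo, hi = params.missing_band
    hom = in_depth & (freq < params.hom_max_freq)
    out[hom & (ref >= alt)] = HOM_REF
    out[hom & (ref < alt)] = HOM_ALT
    het = (
        in_depth
        & (freq >= params.min_minor_freq)
        & (minor >= params.min_minor_reads)
    )
    out[het] = HET
    # everything else (missing band, depth out of range, under-supported
    # minor allele) stays MISSING
    return out


def presence_matrix(states: np.ndarray) -> np.ndarray:
    """Carrier (het or hom_alt) matrix with NaN for missing calls."""
    out = np.where(
        states == MISSING, np.nan, ((states == HET) | (states == HOM_ALT)).astype(float)
    )
    return out


# --------------------------------------------------------- segregation


def test_single_dose(
    states: np.ndarray,
    marker_id: str = "",
    params: SegregationParams = SegregationParams(),
) -> SegregationResult:
    """Pearson chi-square test of 3:1 carrier:non-carrier segregation.

    Carriers are het or hom_alt calls; the test uses df=1 on the
    non-missing individuals without continuity correction.  A marker is
    single dose when p >= alpha and the missing fraction is below
    ``max_missing_frac``.
    """
    states = np.asarray(states)
    n_total = states.size
    n_missing = int((states == MISSING).sum())
    n_present = int(((states == HET) | (states == HOM_ALT)).sum())
    n_absent = int((states == HOM_REF).sum())
    n = n_present + n_absent
    if n == 0:
        return SegregationResult(
            marker_id, 0, 0, n_missing, math.nan, math.nan, False,
            reason="no non-missing calls",
        )
    exp_present, exp_absent = 0.75 * n, 0.25 * n
    chi2 = (n_present - exp_present) ** 2 / exp_present + (
        n_absent - exp_absent
    ) ** 2 / exp_absent
    p = float(stats.chi2.sf(chi2, df=1))
    missing_frac = n_missing / n_total
    ok = p >= params.alpha and missing_frac < params.max_missing_frac
    reason = ""
    if p < params.alpha:
        reason = "segregation departs from 3:1"
    elif missing_frac >= params.max_missing_frac:
        reason = f"missing fraction {missing_frac:.3f} >= {params.max_missing_frac}"
    return SegregationResult(
        marker_id, n_present, n_absent, n_missing, float(chi2), p, ok, reason
    )


def segregation_table(
    states: np.ndarray,
    marker_ids: Sequence[str],
    params: SegregationParams = SegregationParams(),
) -> pd.DataFrame:
    results = [
        test_single_dose(states[i], marker_ids[i], params)
        for i in range(states.shape[0])
    ]
    return pd.DataFrame(
        [
            {
                "marker_id": r.marker_id,
                "n_present": r.n_present,
                "n_absent": r.n_absent,
                "n_missing": r.n_missing,
                "chi2": r.chi2,
                "p": r.p,
                "single_dose": r.single_dose,
                "reason": r.reason,
            }
            for r in results
        ]
    )


# ------------------------------------------------------ two-point linkage


def _pair_counts(x: np.ndarray, y: np.ndarray) -> Tuple[int, int, int, int, int]:
    both = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[both] > 0.5, y[both] > 0.5
    n11 = int((xs & ys).sum())
    n10 = int((xs & ~ys).sum())
    n01 = int((~xs & ys).sum())
    n00 = int((~xs & ~ys).sum())
    return n11, n10, n01, n00, int(both.sum())


def _loglik(r: float, n11: int, n10: int, n01: int, n00: int) -> float:
    # coupling-phase single-dose dominant pair under selfing:
    # P(absent, absent) = q^2, P(discordant) = 1/4 - q^2 each,
    # P(present, present) = 1/2 + q^2, with q = (1 - r)/2
    q = (1.0 - r) / 2.0
    p00 = q * q
    p_disc = 0.25 - q * q
    p11 = 0.5 + q * q
    eps = 1e-300
    return (
        n00 * math.log(max(p00, eps))
        + (n10 + n01) * math.log(max(p_disc, eps))
        + n11 * math.log(max(p11, eps))
    )


def two_point_linkage(
    presence_i: np.ndarray,
    presence_j: np.ndarray,
    params: LinkageParams = LinkageParams(),
) -> Tuple[float, float]:
    """Maximum-likelihood recombination fraction and LOD for two markers.

    Both markers are modelled as coupling-phase single-dose alleles on one
    homolog of a selfed simplex parent.  The likelihood over the 2x2
    carrier table is maximised on rf in [0, 0.5] by bounded search;
    LOD = log10 L(rf_hat) - log10 L(0.5).  Degenerate tables (a marker
    monomorphic among shared individuals, or too few shared individuals)
    return (0.5, 0.0).
    """
    n11, n10, n01, n00, n_shared = _pair_counts(
        np.asarray(presence_i, dtype=float), np.asarray(presence_j, dtype=float)
    )
    if n_shared < params.min_shared:
        return 0.5, 0.0
    if (n11 + n10 == 0 or n01 + n00 == 0) or (n11 + n01 == 0 or n10 + n00 == 0):
        return 0.5, 0.0

    def neg(r: float) -> float:
        return -_loglik(r, n11, n10, n01, n00)

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 0.5), method="bounded", options={"xatol": 1e-10}
    )
    candidates = [0.0, float(res.x), 0.5]
    rf = min(candidates, key=neg)
    if rf < 1e-8:
        rf = 0.0
    lod = (_loglik(rf, n11, n10, n01, n00) - _loglik(0.5, n11, n10, n01, n00)) / math.log(10)
    return rf, max(lod, 0.0)


def pairwise_linkage(
    presence: np.ndarray,
    marker_ids: Sequence[str],
    params: LinkageParams = LinkageParams(),
) -> pd.DataFrame:
    """Two-point rf/LOD for every marker pair (markers x individuals input)."""
    m = presence.shape[0]
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            rf, lod = two_point_linkage(presence[i], presence[j], params)
            rows.append(
                {
                    "marker_i": marker_ids[i],
                    "marker_j": marker_ids[j],
                    "rf": rf,
                    "lod": lod,
                }
            )
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "rf", "lod"])


def group_markers(
    linkage: pd.DataFrame,
    marker_ids: Sequence[str],
    params: LinkageParams = LinkageParams(),
) -> Tuple[List[CosegregationGroup], int]:
    """Single-linkage cosegregation groups over qualifying linkage edges.

    Edges require LOD >= ``lod_threshold`` and rf <= ``max_rf``;
    components smaller than ``min_group_size`` are discarded (their count
    is returned).
    """
    index = {mid: k for k, mid in enumerate(marker_ids)}
    m = len(marker_ids)
    good = linkage[
        (linkage["lod"] >= params.lod_threshold) & (linkage["rf"] <= params.max_rf)
    ]
    ii = [index[x] for x in good["marker_i"]]
    jj = [index[x] for x in good["marker_j"]]
    graph = sparse.coo_matrix(
        (np.ones(len(ii)), (ii, jj)), shape=(m, m)
    )
    n_comp, labels = connected_components(graph, directed=False)
    groups: List[CosegregationGroup] = []
    n_discarded = 0
    next_id = 1
    for comp in range(n_comp):
        members = [marker_ids[k] for k in range(m) if labels[k] == comp]
        if len(members) >= params.min_group_size:
            groups.append(
                CosegregationGroup(cg_id=f"CG{next_id:03d}", marker_ids=sorted(members))
            )
            next_id += 1
        else:
            n_discarded += 1
    groups.sort(key=lambda g: g.cg_id)
    return groups, n_discarded


# ------------------------------------------------------- species origin


def classify_snp_origin(
    panel_states: np.ndarray,
    samples: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    marker_ids: Sequence[str],
    min_carriers: int = 2,
    strict: bool = False,
) -> pd.Series:
    """Diagnostic origin per SNP from a species panel.

    Origin A requires carriers in at least ``min_carriers`` group-A
    accessions and none in group B (mirrored for origin B).  Missing panel
    calls count as absence of evidence by default; in ``strict`` mode a
    missing call in the group that must show absence blocks assignment.
    """
    cols = {s: k for k, s in enumerate(samples)}
    ia = [cols[s] for s in group_a]
    ib = [cols[s] for s in group_b]
    carrier = (panel_states == HET) | (panel_states == HOM_ALT)
    missing = panel_states == MISSING
    carriers_a = carrier[:, ia].sum(axis=1)
    carriers_b = carrier[:, ib].sum(axis=1)
    origin = np.full(len(marker_ids), "unassigned", dtype=object)
    is_a = (carriers_a >= min_carriers) & (carriers_b == 0)
    is_b = (carriers_b >= min_carriers) & (carriers_a == 0)
    if strict:
        is_a &= ~missing[:, ib].any(axis=1)
        is_b &= ~missing[:, ia].any(axis=1)
    origin[is_a] = "officinarum"
    origin[is_b] = "spontaneum"
    return pd.Series(origin, index=list(marker_ids), name="origin")


def assign_cg_origin(
    marker_origins: Sequence[str],
    pure_frac: float = 0.90,
    minor_frac: float = 0.10,
) -> str:
    """Label a cosegregation group from its markers' species origins.

    At least ``pure_frac`` of the origin-labelled markers from one species
    gives that species; both species above ``minor_frac`` gives
    recombinant; no labelled markers gives unassigned.
    """
    labelled = [o for o in marker_origins if o in ("officinarum", "spontaneum")]
    if not labelled:
        return "unassigned"
    n = len(labelled)
    f_off = labelled.count("officinarum") / n
    f_sp = 1.0 - f_off
    if f_off >= pure_frac:
        return "officinarum"
    if f_sp >= pure_frac:
        return "spontaneum"
    if f_off >= minor_frac and f_sp >= minor_frac:
        return "recombinant"
    return "officinarum" if f_off > f_sp else "spontaneum"


def assign_cg_orthology(
    marker_chroms: Sequence[Optional[str]],
    params: OrthologyParams = OrthologyParams(),
) -> List[str]:
    """Orthologous guide chromosome(s) of a cosegregation group.

    Counts aligned markers per chromosome; chromosomes with at least
    ``min_markers`` markers and ``min_frac`` of the group's aligned
    markers qualify, ranked by count (ties lexicographic); the top one or
    two are reported.  No aligned markers leaves the group unplaced.
    """
    aligned = [c for c in marker_chroms if c]
    if not aligned:
        return []
    counts = pd.Series(aligned).value_counts()
    n = len(aligned)
    passing = [
        (int(cnt), chrom)
        for chrom, cnt in counts.items()
        if cnt >= params.min_markers and cnt / n >= params.min_frac
    ]
    passing.sort(key=lambda t: (-t[0], t[1]))
    return [chrom for _, chrom in passing[:2]]


def annotate_groups(
    groups: Sequence[CosegregationGroup],
    marker_origin: pd.Series,
    marker_chrom: Dict[str, Optional[str]],
    orthology: OrthologyParams = OrthologyParams(),
    pure_frac: float = 0.90,
    minor_frac: float = 0.10,
) -> List[CosegregationGroup]:
    out = []
    for g in groups:
        origins = [marker_origin.get(m, "unassigned") for m in g.marker_ids]
        chroms = [marker_chrom.get(m) for m in g.marker_ids]
        out.append(
            CosegregationGroup(
                cg_id=g.cg_id,
                marker_ids=list(g.marker_ids),
                origin=assign_cg_origin(origins, pure_frac, minor_frac),
                chromosomes=assign_cg_orthology(chroms, orthology),
            )
        )
    return out
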