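"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; GFF3, AGP v2.1, bedGraph, BED placements and
the VCF-like allele-count tables are simple line formats written and parsed
here with explicit coordinate conventions: everything in memory is 0-based
half-open, GFF3 and AGP on disk are 1-based inclusive.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: Dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

GFF3_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "mosaicpath") -> None:
    """Write a gene table (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features from GFF3 back into 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "gene_id": attrs.get("ID", parts[8]),
                }
            )
    return pd.DataFrame(rows, columns=GFF3_COLUMNS)


# ------------------------------------------------------- tag multimap TSV


def write_tag_map(tags: pd.DataFrame, path: str | Path) -> None:
    tags.to_csv(path, sep="\t", index=False)


def read_tag_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tag_id": str, "bac_id": str, "tag_seq": str})


# --------------------------------------------------- BED-like placements


def read_placements_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED-like tag placement table.

    Columns: chrom, start, end, tag_id, score, strand (0-based half-open).
    A malformed row raises :class:`ValueError` naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "tag_id": parts[3],
                        "score": float(parts[4]) if parts[4] != "." else np.nan,
                        "strand": parts[5],
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tag_id", "score", "strand"]
    )


# ----------------------------------------------------------- bedGraph


def write_bedgraph(depths: Dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depth arrays as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for contig, depth in depths.items():
            depth = np.asarray(depth)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{depth[s]:g}\n")


def read_bedgraph(path: str | Path, lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Read a bedGraph back into dense per-base arrays of known lengths."""
    depths = {name: np.zeros(n, dtype=float) for name, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e, v = line.split("\t")
            if contig in depths:
                depths[contig][int(s): int(e)] = float(v)
    return depths


# ------------------------------------------- VCF-like allele-count table

COUNT_META = ["chrom", "pos", "ref", "alt"]


def write_allele_counts(
    meta: pd.DataFrame,
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write the allele-count TSV: chrom, pos, ref, alt, then one
    ``refCount,altCount`` column per sample.  ``pos`` is 1-based on disk."""
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_META + list(samples)) + "\n")
        for i, row in enumerate(meta.itertuples(index=False)):
            cells = [
                f"{ref_counts[i, j]},{alt_counts[i, j]}" for j in range(len(samples))
            ]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.ref}\t{row.alt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_allele_counts(
    path: str | Path,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray, List[str]]:
    """Read an allele-count TSV; returns (meta, ref_counts, alt_counts, samples).

    ``meta.pos`` is converted back to 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    samples = [c for c in df.columns if c not in COUNT_META]
    meta = df[COUNT_META].copy()
    meta["pos"] = meta["pos"].astype(int) - 1
    if samples and len(df):
        split = np.array(
            [
                [tuple(map(int, cell.split(","))) for cell in df[c]]
                for c in samples
            ]
        )  # (n_samples, n_markers, 2)
        ref = split[:, :, 0].T.astype(np.int64)
        alt = split[:, :, 1].T.astype(np.int64)
    else:
        ref = np.zeros((len(df), len(samples)), dtype=np.int64)
        alt = np.zeros((len(df), len(samples)), dtype=np.int64)
    return meta, ref, alt, samples


# ---------------------------------------------------------------- AGP

AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for row in agp.itertuples(index=False):
            fh.write("\t".join(str(getattr(row, c)) for c in AGP_COLUMNS) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(dict(zip(AGP_COLUMNS, parts)))
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ["object_beg", "object_end", "part_number"]:
        df[col] = df[col].astype(int)
    return df


# ------------------------------------------------------------- misc TSV


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
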