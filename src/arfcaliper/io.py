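"""Readers and writers for the flat-file formats the pipeline consumes.

narrowPeak (10-column), BED3/BED6, FASTA, bedGraph and simple TSV tables.
Also houses blacklist construction (regions called in every sample plus
the negative control) and blacklist filtering.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    Blacklist,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    build_trees,
    merge_intervals,
    overlapping_indices,
)

logger = logging.getLogger("arfcaliper")


class ParseError(ValueError):
    """Raised on a malformed line; the message names the offending line."""


def _fields(line: str, n: int, path: str, lineno: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n:
        raise ParseError(f"{path}:{lineno}: expected >= {n} columns, got {len(parts)}")
    return parts


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(
    path: str | Path, tf_id: str, clade: str = ".", subclade_id: str = "."
) -> PeakSet:
    """Read a 10-column narrowPeak file into a sorted :class:`PeakSet`.

    Column 7 is the signal value; column 10 the summit offset from the
    peak start, with -1 mapped to the interval midpoint (floor) so every
    peak has a usable summit downstream.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, 10, str(path), lineno)
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                signal = float(parts[6])
                summit = int(parts[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start coordinate {start}")
            iv = GenomicInterval(chrom, start, end)
            offset = summit if summit >= 0 else (end - start) // 2
            peaks.append(Peak(iv, summit_offset=offset, signal=signal, name=name))
    ps = PeakSet(tf_id, clade, subclade_id, peaks)
    logger.info("read_narrowpeak(%s): %d peaks for %s", path, len(ps), tf_id)
    return ps


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.signal:g}\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a name -> upper-case sequence map. Duplicate names error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate FASTA record {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    logger.info("read_fasta(%s): %d sequences, %d bp", path, len(genome),
                sum(len(s) for s in genome.values()))
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genes (BED6-like TSV) and BED


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a BED6-like gene table: chrom start end gene_id score strand."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, 6, str(path), lineno)
            strand = parts[5]
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            genes.append(GeneModel(parts[3], iv))
    logger.info("read_gene_table(%s): %d genes", path, len(genes))
    return genes


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.gene_id}\t0\t{g.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, 3, str(path), lineno)
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path: str | Path, labels=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            extra = f"\t{labels[i]}" if labels is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    per_chrom: dict[str, list[list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = _fields(line, 4, str(path), lineno)
            chrom = parts[0]
            per_chrom.setdefault(chrom, []).append(
                [int(parts[1]), int(parts[2]), float(parts[3])]
            )
    data = {
        chrom: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
        for chrom, rows in per_chrom.items()
    }
    return SignalTrack(data)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, (starts, ends, values) in track.data.items():
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# differential-expression table


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a DE TSV (gene, log2FC, FDR) and attach a response class.

    Classes: ``strong_up`` (fold change > 2, i.e. log2FC > 1, and
    FDR < 0.05), ``up`` (log2FC > 0, FDR < 0.05), ``down`` (log2FC < 0,
    FDR < 0.05), else ``unchanged``.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "log2fc", "fdr"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    sig = df["fdr"] < 0.05
    df["class"] = "unchanged"
    df.loc[sig & (df["log2fc"] < 0), "class"] = "down"
    df.loc[sig & (df["log2fc"] > 0), "class"] = "up"
    df.loc[sig & (df["log2fc"] > 1), "class"] = "strong_up"
    return df


# ---------------------------------------------------------------------------
# blacklist


def build_blacklist(
    peaksets: list[PeakSet], control_peaks: PeakSet, f: float = 0.5
) -> Blacklist:
    """Regions called in every sample AND the negative control.

    A candidate region (any peak from any input) is blacklisted when every
    peakset and the control contain a peak reciprocally overlapping it at
    fraction ``f``; qualifying candidates are merged.
    """
    from .overlap import reciprocal_overlap  # local import avoids a cycle

    if not peaksets:
        raise ValueError("build_blacklist requires at least one peakset")
    all_sets = list(peaksets) + [control_peaks]
    candidates = [p.interval for ps in all_sets for p in ps]
    set_trees = [build_trees(ps.intervals()) for ps in all_sets]
    set_ivs = [ps.intervals() for ps in all_sets]

    kept: list[GenomicInterval] = []
    for cand in candidates:
        ok = True
        for trees, ivs in zip(set_trees, set_ivs):
            hits = overlapping_indices(trees, cand)
            if not any(reciprocal_overlap(cand, ivs[i], f) for i in hits):
                ok = False
                break
        if ok:
            kept.append(cand)
    bl = Blacklist(kept)
    logger.info("build_blacklist: %d candidate peaks -> %d merged regions",
                len(candidates), len(bl))
    return bl


def apply_blacklist(peakset: PeakSet, blacklist: Blacklist) -> PeakSet:
    """Drop peaks overlapping any blacklist region by >= 1 bp."""
    trees = build_trees(blacklist.regions)
    kept = [p for p in peakset if not overlapping_indices(trees, p.interval)]
    logger.info("apply_blacklist(%s): %d -> %d peaks",
                peakset.tf_id, len(peakset), len(kept))
    return peakset.with_peaks(kept)
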