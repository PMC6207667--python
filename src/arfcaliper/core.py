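"""Core genomic data model.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``. All file I/O speaks the
BED / narrowPeak dialect, so no conversion happens at the boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger("arfcaliper")

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0


@dataclass(frozen=True)
class Peak:
    """A signal-valued peak with an optional summit.

    ``signal`` carries the narrowPeak column-7 value (peak intensity /
    read depth). ``summit_offset`` is measured from ``interval.start``;
    ``None`` means unset.
    """

    interval: GenomicInterval
    summit_offset: int | None = None
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < len(self.interval):
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak of "
                    f"length {len(self.interval)}"
                )

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (requires summit_offset set)."""
        if self.summit_offset is None:
            raise ValueError(f"peak {self.name} has no summit")
        return self.interval.start + self.summit_offset

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """Peaks of one TF dataset, tagged with clade / sub-clade labels.

    Peaks are kept sorted by (chrom, start, end); duplicate coordinates
    are rejected.
    """

    tf_id: str
    clade: str = "."
    subclade_id: str = "."
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.chrom, p.start, p.end)
        )
        seen: set[tuple[str, int, int]] = set()
        for p in self.peaks:
            key = (p.chrom, p.start, p.end)
            if key in seen:
                raise ValueError(f"duplicate peak coordinates {key} in {self.tf_id}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def with_peaks(self, peaks: list[Peak]) -> "PeakSet":
        return PeakSet(self.tf_id, self.clade, self.subclade_id, list(peaks))


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware TSS and TTS.

    For a + gene the TSS is ``start`` and the TTS is ``end - 1``;
    for a − gene the two are swapped.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id} requires an explicit strand")
        if len(self.interval) < 2:
            raise ValueError(f"gene {self.gene_id}: TSS and TTS would coincide")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class SignalTrack:
    """A step-function signal with bedGraph semantics.

    Per chromosome, stores sorted non-overlapping intervals with
    non-negative values. Bases not covered by any interval have value 0.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.data = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if np.any(values < 0):
                raise ValueError("track values must be >= 0")
            if np.any(ends <= starts):
                raise ValueError("track intervals must have end > start")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def span(self, chrom: str) -> int:
        """Rightmost covered coordinate of a chromosome."""
        starts, ends, _ = self.data[chrom]
        return int(ends[-1]) if len(ends) else 0

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end)."""
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def total_mass(self) -> float:
        return sum(
            float(np.sum((e - s) * v)) for s, e, v in self.data.values()
        )

    def covered_bp(self) -> int:
        return sum(int(np.sum(e - s)) for s, e, _ in self.data.values())

    def per_base(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Rasterize one chromosome to a dense per-base vector."""
        length = self.span(chrom) if length is None else length
        out = np.zeros(length)
        if chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                if s >= length:
                    break
                out[s:min(e, length)] = v
        return out


@dataclass
class Blacklist:
    """Merged artifact regions to be excluded from peak analyses."""

    regions: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.regions = merge_intervals(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their published defaults."""

    reciprocal_fraction: float = 0.5
    summit_window_bp: int = 101
    core_motif: str = "TGTC"
    corr_bin_bp: int = 200
    proximal_up_bp: int = 1100
    proximal_down_bp: int = 900
    distal_up_bp: int = 10_000
    distal_down_bp: int = 3_000
    model_window_bp: int = 201
    epochs: int = 35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_fraction <= 1:
            raise ValueError("reciprocal_fraction must be in (0, 1]")
        for name in (
            "summit_window_bp", "corr_bin_bp", "proximal_up_bp", "proximal_down_bp",
            "distal_up_bp", "distal_down_bp", "model_window_bp", "epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# interval utilities shared across modules


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that overlap by >= 1 bp into maximal regions.

    Book-ended intervals ([0,10) and [10,20)) are left separate.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            out[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def build_trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for >=1 bp overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def overlapping_indices(
    trees: dict[str, IntervalTree], iv: GenomicInterval
) -> list[int]:
    """Indices (payloads) of tree intervals overlapping ``iv`` by >= 1 bp."""
    if iv.chrom not in trees:
        return []
    return [hit.data for hit in trees[iv.chrom].overlap(iv.start, iv.end)]
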