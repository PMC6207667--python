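"""Synthetic genomes, planted motif grammars, peak families, gene
models, expression responses, and open-chromatin sets.

Every generator is a pure function of its arguments including the seed,
so fixtures are reproducible and nothing needs downloading. The genome
model is i.i.d. bases with a GC knob; planted elements are two core
motifs (TGTC / GACA) in a chosen orientation with a chosen spacer, and
peak families are built so that two TFs of the same clade co-bind a
planted element with a controlled probability — giving the downstream
overlap, spacing, target-gene and model analyses known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, PeakSet, SignalTrack
from .motifs import revcomp, scan_core_motif

logger = logging.getLogger("arfcaliper")

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """One planting instruction: ``count`` elements of a given
    orientation class (DR, ER, IR) with a fixed spacer."""

    orientation_class: str
    spacer_bp: int
    count: int

    def __post_init__(self) -> None:
        if self.orientation_class not in {"DR", "ER", "IR"}:
            raise ValueError(f"unknown orientation class {self.orientation_class!r}")
        if self.spacer_bp < 0 or self.count < 0:
            raise ValueError("spacer_bp and count must be >= 0")

    @property
    def element_len(self) -> int:
        return 4 + self.spacer_bp + 4


@dataclass
class TruthTable:
    """Ground truth of a simulation: planted elements and, once peak
    families exist, the per-peak truth (motif count, noise-free signal)."""

    elements: pd.DataFrame  # chrom, start, end, orientation_class, spacer_bp
    peaks: pd.DataFrame | None = None


def simulate_genome(
    length: int, gc_fraction: float, seed: int, chrom: str = "chr1"
) -> dict[str, str]:
    """An i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    seq = rng.choice(BASES, size=length, p=[at, gc, gc, at])
    return {chrom: "".join(seq)}


def _element_sequence(spec: PlantSpec, rng: np.random.Generator, probs) -> str:
    """Element sequence with spacer bases drawn from genome composition,
    redrawn until the element scans to exactly its two planted cores."""
    motifs = {"DR": ("TGTC", "TGTC"), "ER": ("TGTC", "GACA"), "IR": ("GACA", "TGTC")}
    up, down = motifs[spec.orientation_class]
    for _ in range(1000):
        spacer = "".join(rng.choice(BASES, size=spec.spacer_bp, p=probs))
        elem = up + spacer + down
        if len(scan_core_motif(elem)) == 2:
            return elem
    raise RuntimeError("could not draw a clean spacer")  # pragma: no cover


def plant_motif_architecture(
    genome: dict[str, str], plan: list[PlantSpec], seed: int
) -> tuple[dict[str, str], TruthTable]:
    """Overwrite genome bases with non-overlapping planted elements at
    uniformly sampled positions; the returned truth records every
    placement so re-scanning can verify recovery."""
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    seqs = {c: list(genome[c]) for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    probs = _composition(genome)

    records = []
    eid = 0
    for spec in plan:
        if spec.element_len > max(lengths):
            raise ValueError("planted element longer than every chromosome")
        for _ in range(spec.count):
            placed = False
            for _attempt in range(10_000):
                ci = rng.choice(len(chroms), p=lengths / lengths.sum())
                chrom = chroms[ci]
                hi = len(genome[chrom]) - spec.element_len
                if hi < 0:
                    continue
                start = int(rng.integers(0, hi + 1))
                end = start + spec.element_len
                if any(s < end and start < e for s, e in occupied[chrom]):
                    continue
                elem = _element_sequence(spec, rng, probs)
                seqs[chrom][start:end] = list(elem)
                occupied[chrom].append((start, end))
                records.append(
                    dict(element_id=f"e{eid}", chrom=chrom, start=start, end=end,
                         orientation_class=spec.orientation_class,
                         spacer_bp=spec.spacer_bp)
                )
                eid += 1
                placed = True
                break
            if not placed:
                raise ValueError("genome too small for requested plant counts")
    genome2 = {c: "".join(s) for c, s in seqs.items()}
    truth = TruthTable(pd.DataFrame(
        records,
        columns=["element_id", "chrom", "start", "end",
                 "orientation_class", "spacer_bp"],
    ))
    logger.info("plant_motif_architecture: planted %d elements", len(records))
    return genome2, truth


def _composition(genome: dict[str, str]) -> np.ndarray:
    concat = "".join(genome.values())
    counts = np.array([concat.count(b) for b in "ACGT"], dtype=float)
    return counts / counts.sum()


def simulate_peak_families(
    truth: TruthTable,
    genome: dict[str, str],
    n_clade_a: int,
    n_clade_b: int,
    within_clade_share: float = 0.8,
    cross_clade_share: float = 0.1,
    signal_beta: float = 3.0,
    noise_sd: float = 0.25,
    peak_width: int = 200,
    seed: int = 0,
    base_signal: float = 5.0,
    site_rate: float = 0.45,
    count_window_bp: int = 101,
) -> tuple[list[PeakSet], TruthTable]:
    """Peak families with controlled clade co-binding structure.

    Each planted element is latently a clade-A and/or clade-B site (rate
    ``site_rate`` per clade, coupled so that conditional cross-clade
    co-binding matches ``cross_clade_share``); each TF of a clade binds
    its clade's sites independently with probability
    ``within_clade_share``. Consequently the expected pairwise
    shared-peak fraction is ``within_clade_share`` within a clade and
    ``cross_clade_share`` across clades.

    A bound element yields a ``peak_width`` window centred on it with
    the summit at the centre and
    ``signal = (base + beta * motif count in the summit window) * LogNormal(0, noise_sd)``.
    """
    if truth.elements.empty:
        raise ValueError("truth contains no planted elements")
    if not 0 < within_clade_share <= 1:
        raise ValueError("within_clade_share must be in (0, 1]")
    if not 0 <= cross_clade_share <= within_clade_share:
        raise ValueError("need 0 <= cross_clade_share <= within_clade_share")
    gamma = cross_clade_share / within_clade_share
    r = site_rate
    if r * (1 - gamma) > (1 - r):
        raise ValueError("site_rate too high for the requested clade coupling")

    rng = np.random.default_rng(seed)
    elems = truth.elements
    n_el = len(elems)
    z_a = rng.random(n_el) < r
    # couple clade-B site status to clade-A's, preserving the marginal rate
    p_b = np.where(z_a, gamma, r * (1 - gamma) / (1 - r))
    z_b = rng.random(n_el) < p_b

    centers = ((elems["start"] + elems["end"]) // 2).to_numpy()
    chroms = elems["chrom"].to_numpy()
    # noise-free motif count in the summit-centred caliper window
    half_w = count_window_bp // 2
    true_counts = np.empty(n_el, dtype=np.int64)
    for i in range(n_el):
        seq = genome[chroms[i]]
        lo0 = centers[i] - half_w
        lo = max(0, lo0)
        hi = min(len(seq), lo0 + count_window_bp)
        true_counts[i] = len(scan_core_motif(seq[lo:hi]))

    peaksets = []
    peak_records = []
    tf_specs = [(f"A{i+1}", "A", z_a) for i in range(n_clade_a)] + [
        (f"B{i+1}", "B", z_b) for i in range(n_clade_b)
    ]
    half = peak_width // 2
    for tf_id, clade, z in tf_specs:
        bound = z & (rng.random(n_el) < within_clade_share)
        peaks = []
        for i in np.flatnonzero(bound):
            chrom = chroms[i]
            start = max(0, centers[i] - half)
            end = min(len(genome[chrom]), centers[i] + half)
            mean = base_signal + signal_beta * true_counts[i]
            signal = mean * float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else mean
            peaks.append(
                Peak(GenomicInterval(chrom, start, end),
                     summit_offset=int(centers[i] - start),
                     signal=signal, name=f"{tf_id}_{elems['element_id'].iat[i]}")
            )
            peak_records.append(
                dict(tf_id=tf_id, clade=clade,
                     element_id=elems["element_id"].iat[i],
                     chrom=chrom, start=start, end=end, summit=int(centers[i]),
                     true_count=int(true_counts[i]), true_signal_mean=mean)
            )
        peaksets.append(PeakSet(tf_id, clade, clade, peaks))
    truth_out = TruthTable(elems.copy(), pd.DataFrame(peak_records))
    logger.info("simulate_peak_families: %d TFs, %d elements, %s peaks/TF",
                len(tf_specs), n_el, [len(ps) for ps in peaksets])
    return peaksets, truth_out


def simulate_gene_annotation(
    genome_length: int, n_genes: int, gene_length: int, seed: int,
    chrom: str = "chr1",
) -> list[GeneModel]:
    """Non-overlapping genes with random strands, uniformly spread."""
    if n_genes == 0:
        return []
    slack = genome_length - n_genes * gene_length
    if slack < 0:
        raise ValueError("genes do not fit in the genome")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.integers(0, slack + 1, size=n_genes))
    starts = offsets + np.arange(n_genes) * gene_length
    strands = rng.choice(["+", "-"], size=n_genes)
    return [
        GeneModel(f"g{i+1:04d}",
                  GenomicInterval(chrom, int(s), int(s) + gene_length, str(st)))
        for i, (s, st) in enumerate(zip(starts, strands))
    ]


def simulate_expression_response(
    genes: list[GeneModel],
    clade_a_peaks: list[PeakSet],
    prox_effect: float,
    n_up: int,
    n_down: int,
    seed: int,
    tss_window_bp: int = 1000,
) -> pd.DataFrame:
    """A DE table in which up-regulated genes are preferentially (by
    factor ``prox_effect``) drawn from genes with a clade-A peak within
    1 kb of the TSS; ``prox_effect = 1`` gives the null."""
    if prox_effect < 1:
        raise ValueError("prox_effect must be >= 1")
    if n_up + n_down > len(genes):
        raise ValueError("more DE genes requested than genes available")
    from .targets import genes_with_tss_peak

    rng = np.random.default_rng(seed)
    has_peak = genes_with_tss_peak(genes, clade_a_peaks, d=tss_window_bp)
    weights = np.where([has_peak[g.gene_id] for g in genes], prox_effect, 1.0)
    weights = weights / weights.sum()
    idx = rng.choice(len(genes), size=n_up + n_down, replace=False, p=weights)
    up_idx, down_idx = set(idx[:n_up].tolist()), set(idx[n_up:].tolist())

    rows = []
    for i, g in enumerate(genes):
        if i in up_idx:
            lfc = 1.0 + rng.exponential(1.0)
            fdr = rng.uniform(0.0, 0.049)
        elif i in down_idx:
            lfc = -(1.0 + rng.exponential(1.0))
            fdr = rng.uniform(0.0, 0.049)
        else:
            lfc = rng.normal(0.0, 0.25)
            fdr = rng.uniform(0.05, 1.0)
        rows.append(dict(gene=g.gene_id, log2fc=lfc, fdr=fdr))
    return pd.DataFrame(rows)


def simulate_open_chromatin(
    genome_length: int,
    tissues: list[str],
    n_common: int,
    n_specific_per_tissue: int,
    region_width: int,
    seed: int,
    chrom: str = "chr1",
) -> tuple[dict[str, list[GenomicInterval]], dict[str, list[GenomicInterval]]]:
    """Per-tissue open-chromatin sets: shared regions plus planted
    tissue-specific regions, all mutually non-overlapping. Returns
    (per-tissue sets, per-tissue planted specific regions)."""
    total = n_common + len(tissues) * n_specific_per_tissue
    slack = genome_length - total * region_width
    if slack < 0:
        raise ValueError("open-chromatin regions do not fit")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.integers(0, slack + 1, size=total))
    starts = offsets + np.arange(total) * region_width
    regions = [GenomicInterval(chrom, int(s), int(s) + region_width) for s in starts]
    order = rng.permutation(total)
    common = [regions[i] for i in order[:n_common]]
    sets, planted = {}, {}
    pos = n_common
    for t in tissues:
        spec = [regions[i] for i in order[pos : pos + n_specific_per_tissue]]
        pos += n_specific_per_tissue
        sets[t] = sorted(common + spec, key=lambda iv: iv.start)
        planted[t] = sorted(spec, key=lambda iv: iv.start)
    return sets, planted


def track_from_peakset(
    peakset: PeakSet, chrom_lengths: dict[str, int]
) -> SignalTrack:
    """Signal-weighted coverage of a peak set as a step track (used for
    binned-correlation analyses)."""
    data = {}
    for chrom, length in chrom_lengths.items():
        dense = np.zeros(length)
        for p in peakset:
            if p.chrom == chrom:
                dense[p.start : min(p.end, length)] += p.signal
        # compress the dense vector into bedGraph-style steps
        change = np.flatnonzero(np.diff(dense)) + 1
        bounds = np.concatenate([[0], change, [length]])
        starts, ends = bounds[:-1], bounds[1:]
        values = dense[starts]
        keep = values > 0
        if keep.any():
            data[chrom] = (starts[keep], ends[keep], values[keep])
    return SignalTrack(data)
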