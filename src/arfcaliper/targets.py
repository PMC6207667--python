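"""Peak-to-gene assignment and auxin-induction enrichment.

Two distance rules, both strand-aware:

* proximal — peak overlaps [TSS − 1100, TTS + 900] (1 kb + 100 bp
  upstream of the TSS through 1 kb − 100 bp downstream of the TTS),
* distal — peak overlaps [TSS − 10 kb, TTS + 3 kb].

Each peak is linked to its closest qualifying gene (summit-to-TSS
distance; ties break to the lexicographically smaller gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, PeakSet, build_trees, overlapping_indices
from .overlap import RegionClassification

logger = logging.getLogger("arfcaliper")

PROXIMAL_UP_BP = 1100
PROXIMAL_DOWN_BP = 900
DISTAL_UP_BP = 10_000
DISTAL_DOWN_BP = 3_000


@dataclass
class TargetAssignment:
    """Peak-gene links under one distance rule."""

    rule: str
    links: pd.DataFrame  # peak_name, tf_id, clade, chrom, summit, gene_id, tss_distance

    def genes(self) -> list[str]:
        return sorted(self.links["gene_id"].unique())

    def peaks_of(self, gene_id: str) -> pd.DataFrame:
        return self.links[self.links["gene_id"] == gene_id]


def _gene_window(gene: GeneModel, up_bp: int, down_bp: int) -> GenomicInterval:
    """Strand-aware half-open regulatory window [TSS-up, TTS+down]."""
    if gene.strand == "+":
        start, end = gene.interval.start - up_bp, gene.interval.end + down_bp
    else:
        start, end = gene.interval.start - down_bp, gene.interval.end + up_bp
    return GenomicInterval(gene.chrom, max(0, start), end)


def _assign(
    peaksets: list[PeakSet], genes: list[GeneModel], up_bp: int, down_bp: int,
    rule: str,
) -> TargetAssignment:
    windows = [_gene_window(g, up_bp, down_bp) for g in genes]
    trees = build_trees(windows)
    rows = []
    for ps in peaksets:
        for p in ps:
            hits = overlapping_indices(trees, p.interval)
            if not hits:
                continue
            best = min(
                hits, key=lambda i: (abs(p.summit - genes[i].tss), genes[i].gene_id)
            )
            rows.append(
                dict(peak_name=p.name, tf_id=ps.tf_id, clade=ps.clade,
                     chrom=p.chrom, start=p.start, end=p.end, summit=p.summit,
                     gene_id=genes[best].gene_id,
                     tss_distance=abs(p.summit - genes[best].tss))
            )
    links = pd.DataFrame(
        rows, columns=["peak_name", "tf_id", "clade", "chrom", "start", "end",
                       "summit", "gene_id", "tss_distance"],
    )
    logger.info("assign_%s_targets: %d links, %d unique genes",
                rule, len(links), links["gene_id"].nunique())
    return TargetAssignment(rule, links)


def assign_proximal_targets(
    peaksets: list[PeakSet], genes: list[GeneModel],
    up_bp: int = PROXIMAL_UP_BP, down_bp: int = PROXIMAL_DOWN_BP,
) -> TargetAssignment:
    return _assign(peaksets, genes, up_bp, down_bp, "proximal")


def assign_distal_targets(
    peaksets: list[PeakSet], genes: list[GeneModel],
    up_bp: int = DISTAL_UP_BP, down_bp: int = DISTAL_DOWN_BP,
) -> TargetAssignment:
    return _assign(peaksets, genes, up_bp, down_bp, "distal")


def co_occupancy_summary(
    assignment: TargetAssignment, classification: RegionClassification | None = None
) -> pd.DataFrame:
    """Per-gene clade co-occupancy fractions over unique target genes.

    Genes are labeled A_only / B_only / both; with a region
    classification supplied, ``both`` is split into genes with at least
    one linked peak in a shared region (``both_via_shared_peak``) versus
    genes reached only through clade-independent peaks.
    """
    if assignment.links.empty:
        raise ValueError("empty assignment")
    rows = []
    for gene_id, sub in assignment.links.groupby("gene_id"):
        clades = set(sub["clade"])
        if clades >= {"A", "B"}:
            label = "both"
            detail = "both_via_independent_peaks"
            if classification is not None:
                for _, r in sub.iterrows():
                    iv = GenomicInterval(r["chrom"], r["start"], r["end"])
                    if classification.label_of(iv) == "shared":
                        detail = "both_via_shared_peak"
                        break
        else:
            label = "A_only" if clades == {"A"} else "B_only"
            detail = label
        rows.append(dict(gene_id=gene_id, label=label, detail=detail))
    df = pd.DataFrame(rows)
    frac = df["label"].value_counts(normalize=True)
    detail = df["detail"].value_counts(normalize=True)
    out = pd.DataFrame({
        "fraction": [
            frac.get("A_only", 0.0), frac.get("B_only", 0.0), frac.get("both", 0.0),
            detail.get("both_via_shared_peak", 0.0),
            detail.get("both_via_independent_peaks", 0.0),
        ]},
        index=["A_only", "B_only", "both",
               "both_via_shared_peak", "both_via_independent_peaks"],
    )
    out["n_genes"] = len(df)
    return out


def _peaks_near_span(gene: GeneModel, summits: dict, d: int) -> int:
    """Number of peak summits within ``d`` of the gene body span."""
    if gene.chrom not in summits:
        return 0
    arr = summits[gene.chrom]
    lo = gene.interval.start - d
    hi = gene.interval.end - 1 + d
    return int(np.searchsorted(arr, hi, side="right") - np.searchsorted(arr, lo, side="left"))


def peaks_within_distance(
    gene_sets: dict[str, list[GeneModel]],
    peaksets: list[PeakSet],
    d: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene counts of peak summits within ``d`` of the gene body,
    per gene group, with Welch two-sided t-tests between groups."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene groups")
    summits: dict[str, np.ndarray] = {}
    for ps in peaksets:
        for p in ps:
            summits.setdefault(p.chrom, []).append(p.summit)
    summits = {c: np.sort(np.array(v)) for c, v in summits.items()}

    rows = []
    for group, genes in gene_sets.items():
        if len(genes) < 2:
            raise ValueError(f"gene group {group!r} has fewer than 2 genes")
        for g in genes:
            rows.append(dict(group=group, gene_id=g.gene_id,
                             n_peaks=_peaks_near_span(g, summits, d)))
    counts = pd.DataFrame(rows)
    names = list(gene_sets)
    tests = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = counts.loc[counts["group"] == names[i], "n_peaks"]
            y = counts.loc[counts["group"] == names[j], "n_peaks"]
            t, p = stats.ttest_ind(x, y, equal_var=False)
            tests.append(dict(group_a=names[i], group_b=names[j],
                              mean_a=x.mean(), mean_b=y.mean(),
                              t=float(t), p=float(p)))
    return counts, pd.DataFrame(tests)


def genes_with_tss_peak(
    genes: list[GeneModel], peaksets: list[PeakSet], d: int = 1000
) -> dict[str, bool]:
    """Whether any peak overlaps the closed +/- d window around each TSS."""
    ivs = [iv for ps in peaksets for iv in ps.intervals()]
    trees = build_trees(ivs)
    out = {}
    for g in genes:
        win = GenomicInterval(g.chrom, max(0, g.tss - d), g.tss + d + 1)
        out[g.gene_id] = bool(overlapping_indices(trees, win))
    return out


def tss_proximal_enrichment(
    focus_genes: list[GeneModel],
    background_genes: list[GeneModel],
    peaksets: list[PeakSet],
    d: int = 1000,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of TSS-proximal peak enrichment in a focus
    gene set against the rest of the background universe.

    Returns (odds ratio, two-sided p, 2x2 table [[focus_with,
    focus_without], [rest_with, rest_without]]).
    """
    if not focus_genes:
        raise ValueError("empty focus gene set")
    focus_ids = {g.gene_id for g in focus_genes}
    has = genes_with_tss_peak(background_genes, peaksets, d)
    # focus genes may carry TSSs not present in the background list
    for g in focus_genes:
        if g.gene_id not in has:
            has.update(genes_with_tss_peak([g], peaksets, d))
    fw = sum(1 for g in focus_genes if has[g.gene_id])
    fo = len(focus_genes) - fw
    rest = [g for g in background_genes if g.gene_id not in focus_ids]
    rw = sum(1 for g in rest if has[g.gene_id])
    ro = len(rest) - rw
    table = np.array([[fw, fo], [rw, ro]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    logger.info("tss_proximal_enrichment: table %s OR=%.3g p=%.3g",
                table.tolist(), odds, p)
    return float(odds), float(p), table
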