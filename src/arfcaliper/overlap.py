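"""Pairwise and consensus comparison of peak sets.

The pairwise shared-peak matrix uses the reciprocal 50% overlap rule
with the smaller dataset as denominator; consensus construction and
A-only / B-only / shared classification use plain >=1-bp overlap
(occupancy-style consensus). Sub-clade-specific peaks must overlap a
peak of another member of the same sub-clade and no peak outside it,
with the co-member requirement waived for singleton sub-clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    PeakSet,
    SignalTrack,
    build_trees,
    merge_intervals,
    overlapping_indices,
)

logger = logging.getLogger("arfcaliper")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, f: float) -> bool:
    """True iff the shared bases cover at least fraction ``f`` of BOTH
    intervals (bedtools ``-f f -r`` semantics; >= is inclusive)."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    ov = a.overlap_len(b)
    return ov >= f * len(a) and ov >= f * len(b)


@dataclass
class SharedPeakMatrix:
    """Percent of the smaller dataset's peaks with a reciprocal-overlap
    partner in the other dataset, for every dataset pair."""

    percent: pd.DataFrame
    numerator: pd.DataFrame
    denominator: pd.DataFrame


def shared_peak_matrix(peaksets: list[PeakSet], f: float = 0.5) -> SharedPeakMatrix:
    if len(peaksets) < 2:
        raise ValueError("need at least two peaksets")
    ids = [ps.tf_id for ps in peaksets]
    n = len(peaksets)
    trees = [build_trees(ps.intervals()) for ps in peaksets]
    ivs = [ps.intervals() for ps in peaksets]

    pct = pd.DataFrame(np.nan, index=ids, columns=ids)
    num = pd.DataFrame(np.nan, index=ids, columns=ids)
    den = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i in range(n):
        if len(ivs[i]):
            pct.iloc[i, i], num.iloc[i, i], den.iloc[i, i] = 100.0, len(ivs[i]), len(ivs[i])
        for j in range(i + 1, n):
            if not ivs[i] or not ivs[j]:
                continue  # undefined ratio -> missing
            small, big = (i, j) if len(ivs[i]) <= len(ivs[j]) else (j, i)
            shared = sum(
                1
                for iv in ivs[small]
                if any(
                    reciprocal_overlap(iv, ivs[big][k], f)
                    for k in overlapping_indices(trees[big], iv)
                )
            )
            value = 100.0 * shared / len(ivs[small])
            for a, b in ((i, j), (j, i)):
                pct.iloc[a, b], num.iloc[a, b], den.iloc[a, b] = value, shared, len(ivs[small])
    return SharedPeakMatrix(pct, num, den)


def correlate_signal_tracks(
    tracks: dict[str, SignalTrack], bin_bp: int = 200, skip_zero_bins: bool = True
) -> pd.DataFrame:
    """Pearson correlation of genome-binned signal between tracks.

    The shared genome is tiled into ``bin_bp`` bins; per-track bin sums
    are correlated, optionally dropping bins that are zero in every
    track (deepTools ``--skipZeros`` behaviour).
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    names = list(tracks)
    chroms = sorted({c for t in tracks.values() for c in t.chroms})
    spans = {c: max(t.span(c) if c in t.data else 0 for t in tracks.values())
             for c in chroms}
    cols = []
    for name in names:
        parts = []
        for c in chroms:
            nbins = int(np.ceil(spans[c] / bin_bp))
            dense = tracks[name].per_base(c, nbins * bin_bp)
            parts.append(dense.reshape(nbins, bin_bp).sum(axis=1))
        cols.append(np.concatenate(parts))
    mat = np.column_stack(cols)
    if skip_zero_bins:
        mat = mat[mat.any(axis=1)]
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 bins survive; cannot correlate")
    r = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(np.atleast_2d(r), index=names, columns=names)


def consensus_peaks(
    peaksets: list[PeakSet],
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Union of all peaks merged at >=1-bp overlap, with each merged
    region annotated by the number of distinct TFs contributing a peak."""
    if not peaksets:
        raise ValueError("need at least one peakset")
    all_ivs = [iv for ps in peaksets for iv in ps.intervals()]
    regions = merge_intervals(all_ivs)
    trees = build_trees(regions)
    occupancy = np.zeros(len(regions), dtype=np.int64)
    for ps in peaksets:
        seen: set[int] = set()
        for iv in ps.intervals():
            seen.update(overlapping_indices(trees, iv))
        for idx in seen:
            occupancy[idx] += 1
    return regions, occupancy


@dataclass
class RegionClassification:
    """Merged union regions labeled A_only / B_only / shared."""

    regions: list[GenomicInterval]
    labels: list[str]  # parallel to regions
    occupancy_a: np.ndarray
    occupancy_b: np.ndarray

    def counts(self) -> dict[str, int]:
        out = {"A_only": 0, "B_only": 0, "shared": 0}
        for lab in self.labels:
            out[lab] += 1
        return out

    def label_of(self, iv: GenomicInterval) -> str | None:
        """Label of the classified region overlapping ``iv`` (>=1 bp)."""
        if not hasattr(self, "_trees"):
            self._trees = build_trees(self.regions)
        hits = overlapping_indices(self._trees, iv)
        return self.labels[hits[0]] if hits else None


def classify_regions(
    consensus_a: list[GenomicInterval], consensus_b: list[GenomicInterval]
) -> RegionClassification:
    """Merge the two clade consensus sets and label each merged region
    shared when both clades contribute (>=1-bp overlap), else A/B-only."""
    regions = merge_intervals(list(consensus_a) + list(consensus_b))
    trees = build_trees(regions)
    occ_a = np.zeros(len(regions), dtype=np.int64)
    occ_b = np.zeros(len(regions), dtype=np.int64)
    for iv in consensus_a:
        for idx in overlapping_indices(trees, iv):
            occ_a[idx] += 1
    for iv in consensus_b:
        for idx in overlapping_indices(trees, iv):
            occ_b[idx] += 1
    labels = [
        "shared" if a >= 1 and b >= 1 else ("A_only" if a >= 1 else "B_only")
        for a, b in zip(occ_a, occ_b)
    ]
    rc = RegionClassification(regions, labels, occ_a, occ_b)
    logger.info("classify_regions: %s", rc.counts())
    return rc


def subclade_specific_peaks(
    peaksets: list[PeakSet],
    subclade_map: dict[str, str],
    f: float = 0.5,
) -> dict[str, PeakSet]:
    """Peaks specific to each TF's sub-clade.

    A peak of TF t qualifies when it reciprocally overlaps (fraction f) a
    peak of at least one OTHER TF in t's sub-clade and overlaps no peak
    (>=1 bp) of any TF outside the sub-clade. For a singleton sub-clade
    the co-member requirement is waived: peaks unique to the TF qualify.
    """
    for ps in peaksets:
        if ps.tf_id not in subclade_map:
            raise KeyError(f"TF {ps.tf_id!r} missing from subclade_map")
    trees = {ps.tf_id: build_trees(ps.intervals()) for ps in peaksets}
    ivs = {ps.tf_id: ps.intervals() for ps in peaksets}
    members: dict[str, list[str]] = {}
    for tf, sc in subclade_map.items():
        members.setdefault(sc, []).append(tf)

    out: dict[str, PeakSet] = {}
    for ps in peaksets:
        sc = subclade_map[ps.tf_id]
        mates = [t for t in members[sc] if t != ps.tf_id and t in ivs]
        outsiders = [t for t in ivs if subclade_map.get(t) != sc]
        kept = []
        for p in ps:
            if any(
                overlapping_indices(trees[t], p.interval) for t in outsiders
            ):
                continue
            if mates:
                hit = any(
                    reciprocal_overlap(p.interval, ivs[t][k], f)
                    for t in mates
                    for k in overlapping_indices(trees[t], p.interval)
                )
                if not hit:
                    continue
            kept.append(p)
        out[ps.tf_id] = ps.with_peaks(kept)
        logger.info("subclade_specific_peaks(%s): %d of %d peaks",
                    ps.tf_id, len(kept), len(ps))
    return out
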