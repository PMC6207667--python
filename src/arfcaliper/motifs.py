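"""The "molecular caliper" analysis: TGTC core-motif scanning, per-peak
counts, random-window baselines, orientation/spacer spectra, helical
(10-bp) phasing, and signal-versus-count statistics.

The auxin response element core is the 4-mer TGTC. A GACA match on the
forward strand is a TGTC site on the reverse strand, so scanning for
TGTC and GACA on one strand covers both orientations. Two adjacent cores
form one of three orientation classes:

* DR (direct repeat)   TGTC .. TGTC  (or GACA .. GACA, its mirror)
* ER (everted repeat)  TGTC .. GACA
* IR (inverted repeat) GACA .. TGTC

with the spacer counted as the number of bases between the end of the
upstream 4-mer and the start of the downstream 4-mer. All three classes
are invariant under reverse complement of the enclosing window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PeakSet

logger = logging.getLogger("arfcaliper")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

COUNT_BINS = ["0", "1", "2", "3", "4", ">=5"]
ORIENTATION_CLASSES = ["DR", "ER", "IR"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifInstance:
    """One core-motif hit: ``orient`` F reads the motif on the forward
    strand, R reads its reverse complement (a reverse-strand site)."""

    position: int
    orient: str  # {F, R}


def _find_all(seq: str, sub: str) -> list[int]:
    """All (possibly overlapping) start positions of ``sub`` in ``seq``."""
    hits = []
    i = seq.find(sub)
    while i != -1:
        hits.append(i)
        i = seq.find(sub, i + 1)
    return hits


def scan_core_motif(
    seq: str, motif: str = "TGTC", forward_only: bool = False
) -> list[MotifInstance]:
    """All occurrences of the core motif on either strand of ``seq``.

    Reported on forward-strand coordinates, sorted by position; N never
    matches. ``forward_only`` suppresses reverse-strand (R) hits.
    """
    seq = seq.upper()
    rc = revcomp(motif)
    out = [MotifInstance(p, "F") for p in _find_all(seq, motif)]
    if not forward_only:
        out += [MotifInstance(p, "R") for p in _find_all(seq, rc)]
    return sorted(out, key=lambda m: (m.position, m.orient))


def _window_bounds(summit: int, window_bp: int, chrom_len: int) -> tuple[int, int]:
    lo = summit - window_bp // 2
    return max(0, lo), min(chrom_len, lo + window_bp)


def summit_window_counts(
    peakset: PeakSet,
    genome: dict[str, str],
    window_bp: int = 101,
    motif: str = "TGTC",
    forward_only: bool = False,
) -> np.ndarray:
    """Per-peak count of core-motif instances (both strands) in the
    summit-centred window, clipped at chromosome boundaries."""
    counts = np.empty(len(peakset), dtype=np.int64)
    for i, p in enumerate(peakset):
        if p.chrom not in genome:
            raise KeyError(f"peak {p.name}: chromosome {p.chrom!r} absent from genome")
        lo, hi = _window_bounds(p.summit, window_bp, len(genome[p.chrom]))
        counts[i] = len(scan_core_motif(genome[p.chrom][lo:hi], motif, forward_only))
    return counts


@dataclass
class CountDistribution:
    """Fraction of windows falling in instance-count bins 0,1,2,3,4,>=5."""

    fractions: pd.Series  # indexed by COUNT_BINS
    n: int

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if not np.isclose(total, 1.0):
            raise ValueError(f"fractions sum to {total}, expected 1")


def count_distribution(counts) -> CountDistribution:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("count_distribution requires at least one count")
    binned = np.minimum(counts, 5)
    frac = np.bincount(binned, minlength=6) / counts.size
    return CountDistribution(pd.Series(frac, index=COUNT_BINS), n=counts.size)


def poisson_reference(
    genome: dict[str, str], window_bp: int, motif: str = "TGTC"
) -> pd.Series:
    """Closed-form Poisson count-bin reference for random windows.

    With i.i.d. bases at the genome's observed composition, the expected
    number of both-strand core hits in a window is
    lambda = 2 * (window - |motif| + 1) * prod(base probabilities of the
    motif); the bin masses are Poisson(lambda) collapsed to {0..4, >=5}.
    """
    concat = "".join(genome.values())
    n = len(concat)
    p = {b: concat.count(b) / n for b in "ACGT"}
    p_motif = float(np.prod([p[b] for b in motif.upper()]))
    lam = 2.0 * (window_bp - len(motif) + 1) * p_motif
    pmf = stats.poisson.pmf(np.arange(5), lam)
    masses = np.append(pmf, 1.0 - pmf.sum())
    return pd.Series(masses, index=COUNT_BINS)


def random_window_counts(
    genome: dict[str, str],
    n_windows: int,
    window_bp: int,
    seed: int,
    motif: str = "TGTC",
) -> np.ndarray:
    """Per-window core-motif counts for uniformly placed windows."""
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) - window_bp for c in chroms])
    if np.any(lengths < 0):
        raise ValueError("genome shorter than window")
    weights = (lengths + 1) / (lengths + 1).sum()
    which = rng.choice(len(chroms), size=n_windows, p=weights)
    counts = np.empty(n_windows, dtype=np.int64)
    for i, ci in enumerate(which):
        seq = genome[chroms[ci]]
        start = int(rng.integers(0, len(seq) - window_bp + 1))
        counts[i] = len(scan_core_motif(seq[start : start + window_bp], motif))
    return counts


def random_window_baseline(
    genome: dict[str, str],
    n_windows: int,
    window_bp: int,
    seed: int,
    motif: str = "TGTC",
) -> tuple[CountDistribution, pd.Series]:
    """Scan uniformly placed windows and return the empirical count
    distribution together with the Poisson closed-form reference."""
    counts = random_window_counts(genome, n_windows, window_bp, seed, motif)
    dist = count_distribution(counts)
    ref = poisson_reference(genome, window_bp, motif)
    logger.info("random_window_baseline: n=%d, fraction zero=%.3f (Poisson %.3f)",
                n_windows, dist.fractions["0"], ref["0"])
    return dist, ref


def multi_motif_enrichment_test(peak_counts, random_counts) -> tuple[float, float]:
    """Fisher's exact test (two-sided) of multi-core enrichment.

    2x2 table: rows = (>=2 instances, <2 instances), columns =
    (peak windows, random windows). Returns (odds ratio, p); degenerate
    margins give an odds ratio of inf or 0 with the exact p.
    """
    peak_counts = np.asarray(peak_counts)
    random_counts = np.asarray(random_counts)
    if peak_counts.size == 0 or random_counts.size == 0:
        raise ValueError("both count vectors must be non-empty")
    a = int(np.sum(peak_counts >= 2))
    b = int(np.sum(random_counts >= 2))
    c = peak_counts.size - a
    d = random_counts.size - b
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# orientation / spacer spectra


def classify_pair(up: MotifInstance, down: MotifInstance) -> tuple[str, int]:
    """Orientation class and spacer of an ordered (upstream, downstream)
    instance pair. (R,R) is canonicalized to DR — it is a direct repeat
    read on the opposite strand."""
    if down.position < up.position:
        raise ValueError("pair must be ordered by position")
    spacer = down.position - (up.position + 4)
    if spacer < 0:
        raise ValueError("instances overlap; no spacer defined")
    key = (up.orient, down.orient)
    orient = {"FF": "DR", "RR": "DR", "FR": "ER", "RF": "IR"}[key[0] + key[1]]
    return orient, spacer


@dataclass
class SpacingSpectrum:
    """Orientation x spacer matrix of percentages over two-instance peaks."""

    percent: pd.DataFrame  # rows DR/ER/IR, columns spacer 0..max
    n_two_instance: int

    def __post_init__(self) -> None:
        total = float(self.percent.to_numpy().sum())
        if not np.isclose(total, 100.0):
            raise ValueError(f"spectrum cells sum to {total}, expected 100")

    def argmax_cell(self) -> tuple[str, int]:
        arr = self.percent.to_numpy()
        i, j = np.unravel_index(int(arr.argmax()), arr.shape)
        return str(self.percent.index[i]), int(self.percent.columns[j])


def pair_spacing_spectrum(
    peakset: PeakSet,
    genome: dict[str, str],
    window_bp: int = 101,
    motif: str = "TGTC",
    max_spacer: int | None = None,
) -> SpacingSpectrum:
    """Orientation/spacer spectrum over peaks whose summit window holds
    exactly two core instances (more would make the spacing ambiguous)."""
    pairs: list[tuple[str, int]] = []
    for p in peakset:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.name}: chromosome {p.chrom!r} absent from genome")
        lo, hi = _window_bounds(p.summit, window_bp, len(genome[p.chrom]))
        inst = scan_core_motif(genome[p.chrom][lo:hi], motif)
        if len(inst) != 2:
            continue
        try:
            pairs.append(classify_pair(inst[0], inst[1]))
        except ValueError:
            continue  # physically overlapping cores carry no spacer
    if not pairs:
        raise ValueError("no peaks with exactly two core-motif instances")
    if max_spacer is None:
        max_spacer = max(s for _, s in pairs)
    mat = pd.DataFrame(
        0.0, index=ORIENTATION_CLASSES, columns=range(max_spacer + 1)
    )
    kept = 0
    for orient, spacer in pairs:
        if spacer <= max_spacer:
            mat.loc[orient, spacer] += 1
            kept += 1
    mat = mat * (100.0 / kept)
    logger.info("pair_spacing_spectrum(%s): %d two-instance peaks", peakset.tf_id, kept)
    return SpacingSpectrum(mat, kept)


def phasing_periodogram(
    spectrum_row, period: int = 10, max_spacer: int = 50
) -> float:
    """Helical-phasing score of one orientation class' spacer profile.

    Projects the (non-negative) spacer frequencies onto the complex tone
    exp(-2*pi*i*s/period) over spacers 0..max_spacer and returns the
    squared magnitude normalized by the squared total mass — 1 for mass
    concentrated on one phase (e.g. spacers 7, 17, 27, ...), near 0 for a
    flat profile.
    """
    x = np.asarray(spectrum_row, dtype=float)[: max_spacer + 1]
    if np.any(x < 0):
        raise ValueError("spacer frequencies must be >= 0")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero spacer profile")
    s = np.arange(x.size)
    tone = np.exp(-2j * np.pi * s / period)
    return float(np.abs(np.dot(x, tone)) ** 2 / total**2)


def signal_by_count(peakset: PeakSet, counts) -> pd.DataFrame:
    """Per count-bin signal summaries with Welch t-tests between
    adjacent bins (raw p-values; no multiplicity correction)."""
    counts = np.asarray(counts)
    if counts.size != len(peakset):
        raise ValueError("counts must align with peaks")
    signals = np.array([p.signal for p in peakset])
    binned = np.minimum(counts, 5)
    rows = []
    prev_vals = None
    for b in range(6):
        vals = signals[binned == b]
        row = {
            "bin": COUNT_BINS[b],
            "n": vals.size,
            "mean": vals.mean() if vals.size else np.nan,
            "median": np.median(vals) if vals.size else np.nan,
            "q1": np.percentile(vals, 25) if vals.size else np.nan,
            "q3": np.percentile(vals, 75) if vals.size else np.nan,
        }
        if prev_vals is not None and vals.size >= 2 and prev_vals.size >= 2:
            t, p = stats.ttest_ind(vals, prev_vals, equal_var=False)
            row["t_vs_prev"], row["p_vs_prev"] = float(t), float(p)
        else:
            row["t_vs_prev"], row["p_vs_prev"] = np.nan, np.nan
        rows.append(row)
        prev_vals = vals
    return pd.DataFrame(rows).set_index("bin")
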