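"""Sequence-to-binding-strength regression and cross-dataset prediction.

Training sets pair 201-bp summit-centred peak sequences, labeled with
the peak signal, with an equal number of peak-free genomic windows
labeled 0. The default regressor is a small convolution-plus-pooling
architecture: exact-match 4-mer detector filters are convolved along
the sequence and sum-pooled into k-mer counts, a second structured
layer pools co-occurrences of the two core-motif strands into
orientation x spacer pair counts, and a linear readout over the pooled
features is trained by stochastic gradient descent on squared error for
a fixed number of passes. Cross-dataset transfer is summarized as the
percent of variance explained (100 * squared Pearson correlation of
predictions with held-out labels).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.linear_model import SGDRegressor
from sklearn.preprocessing import StandardScaler

from .core import PeakSet, build_trees, overlapping_indices
from .motifs import classify_pair, revcomp, scan_core_motif

logger = logging.getLogger("arfcaliper")

_ALPHABET = "ACGT"
_ONE_HOT = {b: np.eye(4)[i] for i, b in enumerate(_ALPHABET)}
_ONE_HOT["N"] = np.zeros(4)


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) one-hot encoding; N maps to an all-zero column."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return np.array([_ONE_HOT[b] for b in seq])


@dataclass(frozen=True)
class TrainingExample:
    sequence: str
    label: float
    origin: str  # {positive, negative}
    split: str  # {train, test}

    def __post_init__(self) -> None:
        if self.origin == "negative" and self.label != 0:
            raise ValueError("negative examples must carry label 0")
        if self.label < 0:
            raise ValueError("labels must be >= 0")


def build_training_set(
    peakset: PeakSet,
    genome: dict[str, str],
    seed: int,
    test_fraction: float = 0.2,
    window_bp: int = 201,
) -> list[TrainingExample]:
    """Summit-centred positives labeled with peak signal plus an equal
    number of peak-free windows labeled 0, split train/test by seed."""
    rng = np.random.default_rng(seed)
    half = window_bp // 2
    positives = []
    for p in peakset:
        seq = genome[p.chrom]
        start = p.summit - half
        if start < 0 or start + window_bp > len(seq):
            logger.info("build_training_set: peak %s too close to the "
                        "chromosome edge, skipped", p.name)
            continue
        positives.append((seq[start : start + window_bp], p.signal))

    trees = build_trees(peakset.intervals())
    chroms = list(genome)
    weights = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    negatives: list[str] = []
    attempts = 0
    from .core import GenomicInterval

    while len(negatives) < len(positives):
        attempts += 1
        if attempts > 200 * max(1, len(positives)):
            raise ValueError("genome too crowded to sample peak-free negatives")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        hi = len(genome[chrom]) - window_bp
        if hi < 0:
            continue
        start = int(rng.integers(0, hi + 1))
        win = GenomicInterval(chrom, start, start + window_bp)
        if overlapping_indices(trees, win):
            continue
        negatives.append(genome[chrom][start : start + window_bp])

    examples = [
        TrainingExample(s, lab, "positive", "train") for s, lab in positives
    ] + [TrainingExample(s, 0.0, "negative", "train") for s in negatives]
    n = len(examples)
    n_test = int(round(n * test_fraction))
    test_idx = set(rng.permutation(n)[:n_test].tolist())
    examples = [
        TrainingExample(e.sequence, e.label, e.origin,
                        "test" if i in test_idx else "train")
        for i, e in enumerate(examples)
    ]
    logger.info("build_training_set(%s): %d positives, %d negatives, %d test",
                peakset.tf_id, len(positives), len(negatives), n_test)
    return examples


# ---------------------------------------------------------------------------
# feature convolution


def _kmer_index(k: int = 4) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(itertools.product(_ALPHABET, repeat=k))}


_KMER_IDX = _kmer_index(4)


def featurize(
    sequences: list[str], motif: str = "TGTC", max_spacer: int = 15
) -> np.ndarray:
    """Pooled convolutional features for each sequence.

    256 exact-match 4-mer counts (sum-pooled filter responses) plus
    3 * (max_spacer + 1) core-motif pair counts by orientation class and
    spacer — the geometry-aware pooling layer.
    """
    n_pair = 3 * (max_spacer + 1)
    out = np.zeros((len(sequences), 256 + n_pair))
    class_base = {"DR": 0, "ER": 1, "IR": 2}
    for row, seq in enumerate(sequences):
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        for i in range(len(seq) - 3):
            idx = _KMER_IDX.get(seq[i : i + 4])
            if idx is not None:
                out[row, idx] += 1
        inst = scan_core_motif(seq, motif)
        for a, b in itertools.combinations(inst, 2):
            if b.position - (a.position + len(motif)) < 0:
                continue
            orient, spacer = classify_pair(a, b)
            if spacer <= max_spacer:
                out[row, 256 + class_base[orient] * (max_spacer + 1) + spacer] += 1
    return out


class BindingModel:
    """Convolution-plus-pooling regressor with an SGD linear readout."""

    def __init__(self, motif: str = "TGTC", max_spacer: int = 15,
                 alpha: float = 1e-4):
        self.motif = motif
        self.max_spacer = max_spacer
        self.alpha = alpha
        self._scaler: StandardScaler | None = None
        self._reg: SGDRegressor | None = None
        self._y_mean = 0.0
        self._y_scale = 1.0

    def fit(self, sequences: list[str], labels, epochs: int = 35,
            seed: int = 0) -> "BindingModel":
        if len(sequences) < 10:
            raise ValueError("need at least 10 training examples")
        y = np.asarray(labels, dtype=float)
        X = featurize(sequences, self.motif, self.max_spacer)
        self._scaler = StandardScaler()
        Xs = self._scaler.fit_transform(X)
        self._y_mean = float(y.mean())
        self._y_scale = float(y.std()) or 1.0
        ys = (y - self._y_mean) / self._y_scale
        self._reg = SGDRegressor(
            loss="squared_error", penalty="l2", alpha=self.alpha,
            max_iter=epochs, tol=None, shuffle=True,
            learning_rate="invscaling", eta0=0.01,
            random_state=seed,
        )
        self._reg.fit(Xs, ys)
        return self

    def predict(self, sequences: list[str]) -> np.ndarray:
        if self._reg is None:
            raise RuntimeError("model is not trained")
        X = featurize(sequences, self.motif, self.max_spacer)
        ys = self._reg.predict(self._scaler.transform(X))
        return ys * self._y_scale + self._y_mean


def train_binding_model(
    train_set: list[TrainingExample],
    arch_config: dict | None = None,
    epochs: int = 35,
    seed: int = 0,
) -> BindingModel:
    """Train the default regressor on the ``train`` split of a
    training-set collection."""
    cfg = arch_config or {}
    model = BindingModel(**cfg)
    train = [e for e in train_set if e.split == "train"]
    model.fit([e.sequence for e in train], [e.label for e in train],
              epochs=epochs, seed=seed)
    return model


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either vector has zero variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cross_prediction_matrix(
    models: dict[str, BindingModel],
    test_sets: dict[str, list[TrainingExample]],
) -> pd.DataFrame:
    """cell(i, j) = percent of variance in dataset j's held-out labels
    explained by model i (100 * r^2)."""
    names = list(models)
    mat = pd.DataFrame(np.nan, index=names, columns=list(test_sets))
    for j, (tname, examples) in enumerate(test_sets.items()):
        test = [e for e in examples if e.split == "test"]
        if len(test) < 3:
            continue  # cell stays missing
        seqs = [e.sequence for e in test]
        labels = np.array([e.label for e in test])
        for iname, model in models.items():
            r = _safe_r(model.predict(seqs), labels)
            mat.loc[iname, tname] = 100.0 * r * r
    return mat


def cluster_models(
    matrix: pd.DataFrame, impute_missing: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of datasets on distance
    100 − symmetrized variance explained. Returns (linkage, leaf order).
    """
    mat = matrix.to_numpy(dtype=float)
    if np.isnan(mat).any():
        if not impute_missing:
            raise ValueError("matrix has missing cells; set impute_missing")
        mat = np.where(np.isnan(mat), np.nanmean(mat), mat)
    if mat.shape[0] == 1:
        return np.empty((0, 4)), [str(matrix.index[0])]
    sym = (mat + mat.T) / 2.0
    dist = np.clip(100.0 - sym, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [str(matrix.index[i]) for i in order]


@dataclass
class ElementScore:
    """Sliding-window predictions along a regulatory element and the
    length-normalized cumulative (area-under-curve) binding score."""

    predictions: np.ndarray
    element_length: int

    @property
    def cumulative(self) -> float:
        if self.predictions.size < 2:
            return 0.0  # a single point has zero area under the curve
        return float(np.trapezoid(self.predictions) / self.element_length)


def score_element(
    model: BindingModel, element_seq: str, window_bp: int = 201
) -> ElementScore:
    """Predict binding at every 201-bp window (step 1) along an element
    and integrate into a length-normalized cumulative score."""
    L = len(element_seq)
    if L < window_bp:
        raise ValueError(f"element length {L} shorter than window {window_bp}")
    windows = [element_seq[i : i + window_bp] for i in range(L - window_bp + 1)]
    preds = model.predict(windows)
    return ElementScore(preds, L)
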