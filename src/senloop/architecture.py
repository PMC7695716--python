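"""Chromosome architecture: A/B compartments and TAD borders.

Compartment scores come from PCA of the Pearson-correlation transform of the
observed-over-expected matrix at 100 kb resolution; the component most
correlated (in absolute value) with a reference activity track (e.g. an
H3K4me1-like coverage profile) is chosen and its sign fixed so that active
(A) compartment bins score positive.

TAD borders are called from insulation-score minima on 40 kb matrices, each
border carrying a 1-10 confidence score; per-condition consensus keeps
borders scored above a threshold in every replicate, and two border sets are
compared with normalized mutual information over the induced binary bin
labellings.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import argrelextrema, peak_prominences
from sklearn.metrics import normalized_mutual_info_score

from .contacts import ContactMatrix, MatrixKind

__all__ = [
    "CompartmentTrack",
    "BorderSet",
    "compartment_scores",
    "call_borders",
    "consensus_borders",
    "border_nmi",
]


@dataclasses.dataclass
class CompartmentTrack:
    """Per-bin signed compartment score; A where score > 0, B where < 0."""

    resolution: int
    scores: np.ndarray  # NaN on masked bins

    @property
    def labels(self) -> np.ndarray:
        lab = np.where(self.scores > 0, "A", "B").astype(object)
        lab[np.isnan(self.scores)] = None
        return lab


@dataclasses.dataclass
class BorderSet:
    """TAD border positions (bin indices) with 1-10 confidence scores."""

    positions: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=int)
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.scores = self.scores[order]
        if len(self.positions) and (np.diff(self.positions) <= 0).any():
            raise ValueError("border positions must be strictly increasing")
        if len(self.scores) and ((self.scores < 1) | (self.scores > 10)).any():
            raise ValueError("border scores must lie in [1, 10]")

    def __len__(self):
        return len(self.positions)


def compartment_scores(
    matrix: ContactMatrix,
    reference_track: np.ndarray,
    n_components: int = 3,
    min_abs_correlation: float = 0.2,
) -> CompartmentTrack:
    """Compartment eigenvector with reference-track sign fixing.

    The obs/exp matrix restricted to unmasked bins is transformed to its
    Pearson correlation matrix and decomposed; among the first
    ``n_components`` principal components the one with the largest absolute
    Pearson correlation to ``reference_track`` is selected and flipped so the
    correlation is positive.  Raises when no component reaches
    ``min_abs_correlation``.
    """
    if matrix.kind != MatrixKind.OBS_OVER_EXP:
        raise ValueError("compartment_scores expects an obs/exp matrix")
    reference_track = np.asarray(reference_track, dtype=float)
    if reference_track.shape != (matrix.n_bins,):
        raise ValueError("reference track must cover every bin")
    live = matrix.unmasked() & ~np.isnan(matrix.values).all(axis=1)
    sub = matrix.values[np.ix_(live, live)]
    sub = np.where(np.isnan(sub), 1.0, sub)  # missing pixels carry no signal
    corr = np.corrcoef(sub)
    corr = np.where(np.isnan(corr), 0.0, corr)
    # PCA on the correlation matrix: eigenvectors of its centred covariance
    centred = corr - corr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    ref = reference_track[live]
    best, best_r = None, 0.0
    for k in range(min(n_components, vt.shape[0])):
        comp = u[:, k] * s[k]
        if np.std(comp) == 0 or np.std(ref) == 0:
            continue
        r = np.corrcoef(comp, ref)[0, 1]
        if abs(r) > abs(best_r):
            best, best_r = comp, r
    if best is None or abs(best_r) < min_abs_correlation:
        raise ValueError(
            "no compartment-like component: max |correlation| with reference "
            f"= {abs(best_r):.3f} < {min_abs_correlation}"
        )
    if best_r < 0:
        best = -best
    scores = np.full(matrix.n_bins, np.nan)
    scores[live] = best
    return CompartmentTrack(resolution=matrix.resolution, scores=scores)


def insulation_profile(matrix: ContactMatrix, window_bins: int) -> np.ndarray:
    """Mean contact signal in a sliding square crossing the diagonal.

    For bin ``i`` the score is the mean of ``values[i-w:i, i:i+w]`` over
    unmasked pixels; positions too close to either end are NaN.
    """
    n = matrix.n_bins
    w = int(window_bins)
    if w < 1 or 2 * w > n:
        raise ValueError("window larger than chromosome")
    v = np.array(matrix.values, dtype=float)
    live = matrix.unmasked()
    v[~live, :] = np.nan
    v[:, ~live] = np.nan
    prof = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        block = v[i - w : i, i : i + w]
        if np.isnan(block).all():
            continue
        prof[i] = np.nanmean(block)
    return prof


def call_borders(matrix: ContactMatrix, window_bins: int = 10) -> BorderSet:
    """Insulation-score border caller with decile confidence scores.

    Borders are local minima of the insulation profile; each minimum's
    prominence is ranked and mapped onto deciles 1-10, so the deepest
    insulation valleys carry the highest confidence.  A constant matrix has
    no local minima and yields an empty set.
    """
    prof = insulation_profile(matrix, window_bins)
    finite = np.isfinite(prof)
    if finite.sum() < 3:
        return BorderSet(np.array([], dtype=int), np.array([], dtype=int))
    # work on the finite segment; argrelextrema needs strict inequalities
    idx = np.flatnonzero(finite)
    seg = prof[idx]
    minima_local = argrelextrema(seg, np.less)[0]
    if minima_local.size == 0:
        return BorderSet(np.array([], dtype=int), np.array([], dtype=int))
    prom = peak_prominences(-seg, minima_local)[0]
    keep = prom > 0
    minima_local, prom = minima_local[keep], prom[keep]
    if minima_local.size == 0:
        return BorderSet(np.array([], dtype=int), np.array([], dtype=int))
    ranks = np.argsort(np.argsort(prom)) + 1  # 1..m by increasing prominence
    scores = np.ceil(10.0 * ranks / len(ranks)).astype(int)
    return BorderSet(idx[minima_local], scores)


def consensus_borders(
    replicate_border_sets: list[BorderSet],
    min_score: int = 7,
    tolerance_bins: int = 0,
) -> BorderSet:
    """Borders scored above ``min_score`` in every replicate.

    A border from the first replicate is kept when each other replicate has a
    border within ``tolerance_bins`` that is also scored above ``min_score``;
    the reported position and score are those of the first replicate.
    """
    if not replicate_border_sets:
        raise ValueError("no replicate border sets")
    if len(replicate_border_sets) < 2:
        raise ValueError("consensus requires at least 2 replicates")
    first = replicate_border_sets[0]
    keep_pos, keep_score = [], []
    for pos, score in zip(first.positions, first.scores):
        if score <= min_score:
            continue
        ok = True
        for other in replicate_border_sets[1:]:
            good = other.scores > min_score
            if not (np.abs(other.positions[good] - pos) <= tolerance_bins).any():
                ok = False
                break
        if ok:
            keep_pos.append(pos)
            keep_score.append(score)
    return BorderSet(np.array(keep_pos, dtype=int), np.array(keep_score, dtype=int))


def border_nmi(set_a: BorderSet, set_b: BorderSet, n_bins: int) -> float:
    """Normalized mutual information between two border bin labellings.

    Each set induces a binary border/non-border labelling over the ``n_bins``
    grid; NMI uses arithmetic-mean normalization.  When one labelling is
    constant (e.g. an empty set against a non-empty one) its entropy is zero
    and the NMI is 0 by convention; two identical labellings give 1.
    """
    for s in (set_a, set_b):
        if len(s) and s.positions.max() >= n_bins:
            raise ValueError("n_bins smaller than max border index")
    a = np.zeros(n_bins, dtype=int)
    b = np.zeros(n_bins, dtype=int)
    a[set_a.positions] = 1
    b[set_b.positions] = 1
    if np.array_equal(a, b):
        return 1.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
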