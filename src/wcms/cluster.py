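"""Binary-Pearson proximity, group-average dendrograms, novelty calling and
the Mantel matrix-correlation test.

The similarity between two spectra is the Pearson correlation of their 0/1
peak vectors (the phi coefficient).  Clustering uses group-average (UPGMA)
linkage on the distance d = 1 - r, with node heights d/2 so the dendrogram
is ultrametric.  A query whose best similarity against every reference type
strain falls below the novelty threshold (default 0.5) is flagged as a
candidate novel species.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .peaks import PeakMatrixBuilder, align_peaks, binarize, pick_peaks
from .types import (
    BinaryPeakMatrix,
    Dendrogram,
    MantelResult,
    NoveltyCall,
    PeakList,
    SimilarityMatrix,
    Spectrum,
)

NOVELTY_THRESHOLD = 0.5


def pearson_binary(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 0/1 vectors (phi coefficient)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant bit vector")
    return float(np.corrcoef(x, y)[0, 1])


def proximity(matrix: BinaryPeakMatrix) -> SimilarityMatrix:
    """Pairwise binary-Pearson similarity over spectrum columns."""
    bits = matrix.bits.astype(float)
    if bits.shape[1] < 2:
        raise ValueError("need at least two spectra")
    constant = np.ptp(bits, axis=0) == 0
    if constant.any():
        offenders = [matrix.labels[j] for j in np.flatnonzero(constant)]
        raise ValueError(f"undefined correlation: constant peak profile for {offenders}")
    values = np.corrcoef(bits.T)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(matrix.labels), values)


def upgma(similarity: SimilarityMatrix) -> Dendrogram:
    """Group-average agglomerative tree on d = 1 - r; heights are d/2."""
    d = similarity.to_distance()
    n = len(similarity.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    merges = [(int(a), int(b), float(h) / 2.0) for a, b, h, _ in linkage]
    return Dendrogram(list(similarity.labels), merges)


def cut_dendrogram(dendrogram: Dendrogram, n_clusters: int) -> np.ndarray:
    """Flat cluster labels (0..k-1) from cutting the tree into k groups."""
    n = len(dendrogram.leaf_labels)
    linkage = _to_scipy_linkage(dendrogram)
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return flat - 1


def _to_scipy_linkage(dendrogram: Dendrogram) -> np.ndarray:
    n = len(dendrogram.leaf_labels)
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    rows = []
    for k, (a, b, h) in enumerate(dendrogram.merges):
        size = sizes[a] + sizes[b]
        sizes[n + k] = size
        rows.append([a, b, 2.0 * h, size])
    return np.asarray(rows, float)


def call_novelty(query_bits: np.ndarray, library_bits: np.ndarray,
                 library_labels: Sequence[str], query_label: str = "query",
                 threshold: float = NOVELTY_THRESHOLD) -> NoveltyCall:
    """Best-match similarity of a query against a reference library.

    ``query_bits`` must already be aligned to the library's consensus
    positions (run the peak matching jointly over library + query).
    """
    library_bits = np.asarray(library_bits)
    if library_bits.ndim != 2 or library_bits.shape[1] == 0:
        raise ValueError("empty reference library")
    sims = [pearson_binary(query_bits, library_bits[:, j])
            for j in range(library_bits.shape[1])]
    best = int(np.argmax(sims))
    return NoveltyCall(query_label, library_labels[best], float(sims[best]),
                       threshold=threshold)


def mantel(mat_a: SimilarityMatrix, mat_b: SimilarityMatrix,
           n_permutations: int = 9999, seed: int | None = None) -> MantelResult:
    """One-sided Mantel test for positive association of two matrices.

    r is the Pearson correlation over the upper-triangle off-diagonal
    entries; the null distribution permutes rows and columns of the second
    matrix jointly; p = (1 + #{r_perm >= r_obs}) / (n_permutations + 1).
    """
    if mat_a.labels != mat_b.labels:
        raise ValueError("matrix labels differ or are ordered differently")
    n = len(mat_a.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    va = mat_a.values[iu]
    if np.ptp(va) == 0 or np.ptp(mat_b.values[iu]) == 0:
        raise ValueError("constant off-diagonal entries")
    r_obs = float(np.corrcoef(va, mat_b.values[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    za = (va - va.mean()) / va.std()
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vb = mat_b.values[np.ix_(perm, perm)][iu]
        r_perm = float(np.mean(za * (vb - vb.mean()) / vb.std()))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, seed)


class SpectralClusterer(ClusterMixin, BaseEstimator):
    """Fingerprint clustering of relative spectra or a prebuilt bit matrix.

    fit computes the binary peak matrix (when given spectra), the
    binary-Pearson proximity matrix, the group-average dendrogram and, when
    ``n_clusters`` is set, flat cluster labels.

    Attributes (after fit): ``binary_matrix_``, ``similarity_``,
    ``dendrogram_``, ``labels_``.
    """

    def __init__(self, n_clusters: int | None = None,
                 max_shift: float = 20.0, threshold_percent: float = 5.0,
                 mz_window: tuple[float, float] = (3500.0, 20000.0),
                 min_rel_intensity: float = 1.0, min_prominence: float = 1.0):
        self.n_clusters = n_clusters
        self.max_shift = max_shift
        self.threshold_percent = threshold_percent
        self.mz_window = mz_window
        self.min_rel_intensity = min_rel_intensity
        self.min_prominence = min_prominence

    def _builder(self) -> PeakMatrixBuilder:
        return PeakMatrixBuilder(self.min_rel_intensity, self.min_prominence,
                                 self.max_shift, self.threshold_percent,
                                 tuple(self.mz_window))

    def fit(self, X, y=None) -> "SpectralClusterer":
        if isinstance(X, BinaryPeakMatrix):
            self.binary_matrix_ = X
        else:
            self.binary_matrix_ = self._builder().fit(X).transform(X)
        self.similarity_ = proximity(self.binary_matrix_)
        self.dendrogram_ = upgma(self.similarity_)
        if self.n_clusters is not None:
            self.labels_ = cut_dendrogram(self.dendrogram_, self.n_clusters)
        else:
            self.labels_ = np.zeros(len(self.similarity_.labels), dtype=int)
        return self


class NoveltyIdentifier(BaseEstimator):
    """Known/novel identification against a type-strain spectral library.

    fit stores the reference peak lists and their strain labels; predict
    re-runs the peak matching jointly over references plus each query and
    returns the best-matching strain, or ``"candidate_novel"`` when the best
    binary-Pearson similarity is below the threshold.
    """

    def __init__(self, threshold: float = NOVELTY_THRESHOLD,
                 max_shift: float = 20.0, threshold_percent: float = 5.0,
                 mz_window: tuple[float, float] = (3500.0, 20000.0),
                 min_rel_intensity: float = 1.0, min_prominence: float = 1.0):
        self.threshold = threshold
        self.max_shift = max_shift
        self.threshold_percent = threshold_percent
        self.mz_window = mz_window
        self.min_rel_intensity = min_rel_intensity
        self.min_prominence = min_prominence

    def _peaklist(self, x: Spectrum | PeakList) -> PeakList:
        if isinstance(x, PeakList):
            return x
        if x.stage is not x.stage.RELATIVE:
            from .preprocess import preprocess
            x = preprocess(x)
        return pick_peaks(x, self.min_rel_intensity, self.min_prominence)

    def fit(self, X: Sequence[Spectrum | PeakList], y: Sequence[str] | None = None,
            ) -> "NoveltyIdentifier":
        if len(X) == 0:
            raise ValueError("empty reference library")
        self.reference_peaklists_ = [self._peaklist(x) for x in X]
        self.reference_labels_ = (list(y) if y is not None
                                  else [pl.label for pl in self.reference_peaklists_])
        if len(self.reference_labels_) != len(self.reference_peaklists_):
            raise ValueError("labels length mismatch")
        return self

    def decision_function(self, X: Sequence[Spectrum | PeakList]) -> list[NoveltyCall]:
        """One NoveltyCall per query, each aligned jointly with the library."""
        calls = []
        for x in X:
            qpl = self._peaklist(x)
            aligned = align_peaks(self.reference_peaklists_ + [qpl],
                                  self.max_shift)
            bits = binarize(aligned, self.threshold_percent,
                            tuple(self.mz_window)).bits
            calls.append(call_novelty(bits[:, -1], bits[:, :-1],
                                      self.reference_labels_, qpl.label,
                                      self.threshold))
        return calls

    def predict(self, X: Sequence[Spectrum | PeakList]) -> np.ndarray:
        return np.array([
            c.best_match if c.verdict == "assigned" else "candidate_novel"
            for c in self.decision_function(X)
        ], dtype=object)
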