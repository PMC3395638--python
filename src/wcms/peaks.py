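"""Peak picking, cross-spectrum peak matching, and binarization.

Peak matching follows a greedy single-linkage grouping: all (m/z, spectrum)
pairs are pooled in ascending m/z order and a peak joins the currently open
consensus position if it lies within ``max_shift`` Da of its running-mean
m/z, otherwise it opens a new position.  A spectrum never contributes two
peaks to one position — the nearer peak wins and the other opens a fresh
position.  ``max_shift`` defaults to 20 Da (20 grid steps at the default
1 Da working grid).

Binarization is strict: a peak counts as present only when its relative
intensity exceeds the threshold (default >5 %), and only consensus positions
inside the clustering window (default m/z 3,500-20,000) are kept.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    CLUSTER_WINDOW,
    AlignedPeakMatrix,
    BinaryPeakMatrix,
    PeakList,
    Spectrum,
    Stage,
)

DEFAULT_MAX_SHIFT = 20.0
DEFAULT_THRESHOLD = 5.0


def pick_peaks(spectrum: Spectrum, min_rel_intensity: float = 1.0,
               min_prominence: float = 1.0) -> PeakList:
    """Local maxima of a relative-intensity spectrum.

    Returns apex (m/z, relative intensity) pairs for maxima with height
    above ``min_rel_intensity`` percent and prominence at least
    ``min_prominence`` percent.
    """
    if spectrum.stage is not Stage.RELATIVE:
        raise ValueError(f"{spectrum.label}: pick peaks on relative-stage spectra")
    if len(spectrum) < 3:
        return PeakList(spectrum.label, [])
    idx, _ = signal.find_peaks(spectrum.intensity, height=min_rel_intensity,
                               prominence=min_prominence)
    pairs = [(float(spectrum.mz[i]), float(min(spectrum.intensity[i], 100.0)))
             for i in idx]
    return PeakList(spectrum.label, pairs)


def align_peaks(peaklists: Sequence[PeakList],
                max_shift: float = DEFAULT_MAX_SHIFT) -> AlignedPeakMatrix:
    """Group peaks across spectra into consensus positions.

    Greedy pass over the pooled peaks in ascending m/z; the consensus m/z of
    an open position is the running mean of its members.
    """
    if not peaklists:
        raise ValueError("no peak lists to align")
    if max_shift <= 0:
        raise ValueError("max_shift must be positive")
    labels = [pl.label for pl in peaklists]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate spectrum labels")
    pooled = sorted(
        (mz, j, inten)
        for j, pl in enumerate(peaklists)
        for mz, inten in pl.peaks
    )
    # each group: [consensus, sum_mz, members {spectrum: (mz, intensity)}]
    groups: list[dict] = []
    for mz, j, inten in pooled:
        g = groups[-1] if groups else None
        if g is not None and abs(mz - g["consensus"]) <= max_shift:
            if j in g["members"]:
                # nearest peak wins; the other opens a new position
                prev_mz, prev_int = g["members"][j]
                if abs(prev_mz - g["consensus"]) <= abs(mz - g["consensus"]):
                    groups.append({"consensus": mz, "sum": mz, "n": 1,
                                   "members": {j: (mz, inten)}})
                    continue
                # replace the previous (farther) peak; it opens its own position
                g["members"][j] = (mz, inten)
                g["sum"] += mz - prev_mz
                g["consensus"] = g["sum"] / g["n"]
                groups.append({"consensus": prev_mz, "sum": prev_mz, "n": 1,
                               "members": {j: (prev_mz, prev_int)}})
                # keep groups ordered by consensus for the sorted invariant
                groups.sort(key=lambda d: d["consensus"])
                continue
            g["members"][j] = (mz, inten)
            g["sum"] += mz
            g["n"] += 1
            g["consensus"] = g["sum"] / g["n"]
        else:
            groups.append({"consensus": mz, "sum": mz, "n": 1,
                           "members": {j: (mz, inten)}})
    groups.sort(key=lambda d: d["consensus"])
    positions = np.array([g["consensus"] for g in groups])
    # merge numerically identical consensus positions is unnecessary: strict
    # increase is guaranteed by construction except for pathological ties
    eps = 1e-9
    for i in range(1, len(positions)):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + eps
    values = np.zeros((len(groups), len(peaklists)))
    for i, g in enumerate(groups):
        for j, (_, inten) in g["members"].items():
            values[i, j] = inten
    return AlignedPeakMatrix(positions, labels, values)


def binarize(aligned: AlignedPeakMatrix,
             threshold_percent: float = DEFAULT_THRESHOLD,
             mz_window: tuple[float, float] = CLUSTER_WINDOW) -> BinaryPeakMatrix:
    """Presence/absence matrix: bit = 1 iff intensity strictly > threshold.

    Consensus positions outside ``mz_window`` (inclusive bounds) are dropped.
    """
    lo, hi = mz_window
    keep = (aligned.positions >= lo) & (aligned.positions <= hi)
    bits = (aligned.values[keep] > threshold_percent).astype(np.int8)
    return BinaryPeakMatrix(aligned.positions[keep], list(aligned.labels), bits,
                            mz_window=mz_window)


class PeakMatrixBuilder(TransformerMixin, BaseEstimator):
    """Relative spectra -> binary peak matrix, as one sklearn transformer."""

    def __init__(self, min_rel_intensity: float = 1.0,
                 min_prominence: float = 1.0,
                 max_shift: float = DEFAULT_MAX_SHIFT,
                 threshold_percent: float = DEFAULT_THRESHOLD,
                 mz_window: tuple[float, float] = CLUSTER_WINDOW):
        self.min_rel_intensity = min_rel_intensity
        self.min_prominence = min_prominence
        self.max_shift = max_shift
        self.threshold_percent = threshold_percent
        self.mz_window = mz_window

    def fit(self, X: Sequence[Spectrum | PeakList], y=None) -> "PeakMatrixBuilder":
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: Sequence[Spectrum | PeakList]) -> BinaryPeakMatrix:
        from .preprocess import preprocess  # avoid import cycle at module load

        peaklists = []
        for x in X:
            if isinstance(x, PeakList):
                peaklists.append(x)
                continue
            if x.stage is not Stage.RELATIVE:
                x = preprocess(x)  # default chain for raw profile input
            peaklists.append(pick_peaks(x, self.min_rel_intensity,
                                        self.min_prominence))
        aligned = align_peaks(peaklists, self.max_shift)
        return binarize(aligned, self.threshold_percent, tuple(self.mz_window))
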