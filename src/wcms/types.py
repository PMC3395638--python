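"""Domain containers for whole-cell MALDI-TOF (WC-MS) fingerprinting.

All m/z values are treated as singly protonated species ([M+H]+, linear
positive mode); no charge deconvolution is performed.  Intensities are
arbitrary units until a spectrum reaches the ``relative`` stage, where they
are percent of the base peak.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ACQUISITION_RANGE = (2000.0, 20000.0)
"""Instrument acquisition window in m/z (Da)."""

CLUSTER_WINDOW = (3500.0, 20000.0)
"""m/z window whose peaks enter the binary matrix used for clustering."""


class Stage(str, enum.Enum):
    """Processing state of a profile spectrum."""

    RAW = "raw"
    SMOOTHED = "smoothed"
    BASELINED = "baselined"
    RELATIVE = "relative"


@dataclass
class Spectrum:
    """One strain-replicate profile: paired m/z and intensity arrays.

    Parameters
    ----------
    label : str
        Strain/replicate identifier.
    mz : ndarray
        Strictly increasing m/z values in Da.
    intensity : ndarray
        Non-negative intensities, same length as ``mz``.
    stage : Stage
        Processing state; ``relative`` implies max intensity == 100
        (or an all-zero, flagged spectrum).
    empty : bool
        Set when normalisation found no signal at all.
    """

    label: str
    mz: np.ndarray
    intensity: np.ndarray
    stage: Stage = Stage.RAW
    empty: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"{self.label}: mz length {self.mz.size} != "
                f"intensity length {self.intensity.size}"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"{self.label}: non-monotonic m/z")
        if np.any(self.intensity < -1e-9):
            raise ValueError(f"{self.label}: negative intensity")
        if not isinstance(self.stage, Stage):
            self.stage = Stage(self.stage)
        if self.stage is Stage.RELATIVE and self.intensity.size:
            peak = self.intensity.max()
            if peak > 0 and abs(peak - 100.0) > 1e-6:
                raise ValueError(f"{self.label}: relative stage but max != 100")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_intensity(self, intensity: np.ndarray, stage: Stage) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, float), stage=stage)


@dataclass
class PeakList:
    """Centroided peaks of one spectrum: (m/z, relative intensity %) pairs."""

    label: str
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = [(float(m), float(i)) for m, i in self.peaks]
        mzs = [m for m, _ in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError(f"{self.label}: peaks not sorted by m/z")
        for m, i in self.peaks:
            if not 0.0 <= i <= 100.0 + 1e-9:
                raise ValueError(f"{self.label}: relative intensity {i} outside [0, 100]")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)


@dataclass
class SequenceSet:
    """Ordered FASTA records with a declared alphabet."""

    records: list[tuple[str, str]]
    alphabet: str = "protein"  # or "nucleotide"

    _PROTEIN = set("ACDEFGHIKLMNPQRSTVWY")
    _NUCLEOTIDE = set("ACGTUN-")

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        allowed = self._PROTEIN if self.alphabet == "protein" else self._NUCLEOTIDE
        for sid, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(f"{sid}: illegal {self.alphabet} letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


@dataclass
class AlignedPeakMatrix:
    """Consensus peak positions x spectra, relative intensities (0 = absent)."""

    positions: np.ndarray
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("consensus positions not strictly increasing")
        if self.values.shape != (self.positions.size, len(self.labels)):
            raise ValueError("values shape must be (n_positions, n_labels)")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 100 + 1e-6):
            raise ValueError("relative intensities outside [0, 100]")


@dataclass
class BinaryPeakMatrix:
    """Presence/absence matrix over consensus positions within an m/z window."""

    positions: np.ndarray
    labels: list[str]
    bits: np.ndarray
    mz_window: tuple[float, float] = CLUSTER_WINDOW

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.bits = np.asarray(self.bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = self.bits.astype(np.int8)
        lo, hi = self.mz_window
        if self.positions.size and (self.positions.min() < lo or self.positions.max() > hi):
            raise ValueError("positions outside mz_window")
        if self.bits.shape != (self.positions.size, len(self.labels)):
            raise ValueError("bits shape must be (n_positions, n_labels)")


@dataclass
class SimilarityMatrix:
    """Symmetric strain x strain Pearson coefficients, unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("Pearson values outside [-1, 1]")

    def to_distance(self) -> np.ndarray:
        """d = 1 - r, the distance used for group-average clustering."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class Dendrogram:
    """Group-average (UPGMA) merge tree.

    ``merges`` holds ``n_leaves - 1`` rows ``(node_a, node_b, height)`` where
    nodes 0..n-1 are leaves in ``leaf_labels`` order, node n+i is the cluster
    created by merge i, and ``height`` is half the inter-cluster distance at
    the merge (an ultrametric node height).
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str = "group average"

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("need n-1 merges for n leaves")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class NoveltyCall:
    """Best library match for a query spectrum and the known/novel verdict."""

    query: str
    best_match: str
    best_similarity: float
    threshold: float = 0.5

    @property
    def verdict(self) -> str:
        return "candidate_novel" if self.best_similarity < self.threshold else "assigned"


@dataclass
class MantelResult:
    """One-sided Mantel matrix-correlation test result."""

    r: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.r <= 1 + 1e-9:
            raise ValueError("r outside [-1, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p outside (0, 1]")
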