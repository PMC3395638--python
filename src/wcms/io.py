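"""Readers and writers for the formats the pipeline touches.

Native spectrum interchange is two-column (m/z, intensity) text, either
whitespace- or comma-delimited, matching common MALDI instrument exports.
FASTA goes through Biopython; matrices through pandas CSV; dendrograms are
serialised to Newick.
"""

from __future__ import annotations

from pathlib import Path


import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    AlignedPeakMatrix,
    BinaryPeakMatrix,
    Dendrogram,
    PeakList,
    SequenceSet,
    SimilarityMatrix,
    Spectrum,
    Stage,
)


# ---------------------------------------------------------------------------
# spectra

def read_spectrum(path: str | Path, label: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) text or CSV file as a raw spectrum.

    Comment lines starting with ``#`` are ignored; rows with non-numeric
    fields are rejected.  The m/z column must be strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mzs: list[float] = []
    ints: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    if not mzs:
        raise ValueError(f"{path}: empty spectrum file")
    if np.any(np.diff(mzs) <= 0):
        raise ValueError(f"{path}: non-monotonic m/z")
    return Spectrum(label or path.stem, np.array(mzs), np.array(ints), Stage.RAW)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   header: str | None = None) -> None:
    """Write a spectrum as two-column text (6 significant digits preserved)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# label={spectrum.label} stage={spectrum.stage.value}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6g} {i:.6g}\n")


# ---------------------------------------------------------------------------
# peak lists

def read_peaklist(path: str | Path, label: str | None = None) -> PeakList:
    """Read a peak list CSV with columns mz, relative_intensity."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    mz_col = cols.get("mz") or cols.get("m/z")
    int_col = cols.get("relative_intensity") or cols.get("intensity")
    if mz_col is None or int_col is None:
        raise ValueError(f"{path}: need mz and relative_intensity columns")
    pairs = sorted(zip(df[mz_col].astype(float), df[int_col].astype(float)))
    return PeakList(label or Path(path).stem, pairs)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    pd.DataFrame(peaklist.peaks, columns=["mz", "relative_intensity"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path, alphabet: str = "protein") -> SequenceSet:
    """Read FASTA, keeping record order; ids must be unique, sequences non-empty."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet(records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, seq in seqs.records:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# matrices

def write_matrix_csv(labels: list[str], values: np.ndarray, path: str | Path,
                     index_name: str = "label") -> None:
    df = pd.DataFrame(np.asarray(values), index=labels, columns=labels)
    df.index.name = index_name
    df.to_csv(path, float_format="%.10g")


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return [str(x) for x in df.index], df.to_numpy(dtype=float)


def read_similarity_csv(path: str | Path) -> SimilarityMatrix:
    labels, values = read_matrix_csv(path)
    return SimilarityMatrix(labels, values)


def write_aligned_matrix_csv(matrix: AlignedPeakMatrix | BinaryPeakMatrix,
                             path: str | Path) -> None:
    """Positions as rows, spectra as columns."""
    values = matrix.values if isinstance(matrix, AlignedPeakMatrix) else matrix.bits
    df = pd.DataFrame(values, index=np.round(matrix.positions, 6),
                      columns=matrix.labels)
    df.index.name = "mz"
    df.to_csv(path, float_format="%.10g")


def read_binary_matrix_csv(path: str | Path,
                           mz_window: tuple[float, float] = (3500.0, 20000.0),
                           ) -> BinaryPeakMatrix:
    df = pd.read_csv(path, index_col=0)
    return BinaryPeakMatrix(df.index.to_numpy(float), [str(c) for c in df.columns],
                            df.to_numpy(), mz_window=mz_window)


# ---------------------------------------------------------------------------
# trees

def dendrogram_to_newick(dendrogram: Dendrogram, digits: int = 6) -> str:
    """Serialise a merge list as a rooted ultrametric Newick string.

    Branch length of a node is its parent's height minus its own height
    (leaves have height 0).
    """
    n = len(dendrogram.leaf_labels)
    reps: dict[int, str] = {}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, lab in enumerate(dendrogram.leaf_labels):
        reps[i] = lab.replace(" ", "_")
    node = n
    for a, b, h in dendrogram.merges:
        la = f"{reps[a]}:{h - heights[a]:.{digits}g}"
        lb = f"{reps[b]}:{h - heights[b]:.{digits}g}"
        reps[node] = f"({la},{lb})"
        heights[node] = h
        node += 1
    root = reps[node - 1] if dendrogram.merges else reps[0]
    return root + ";"


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram_to_newick(dendrogram) + "\n")
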