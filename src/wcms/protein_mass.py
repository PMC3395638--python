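"""Theoretical average masses of (ribosomal) proteins, the N-terminal
Met-excision rule, modification hypotheses, and observed-peak annotation.

Average (not monoisotopic) masses are used throughout, as appropriate for
linear-mode MALDI-TOF of intact proteins.  The constants table below is the
single versioned source for residue masses and modification deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import PeakList, SequenceSet

CONSTANTS_VERSION = "iupac-average-2011/unimod-average"

#: Average residue (monomer minus water) masses in Da, standard IUPAC table.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153
PROTON_MASS = 1.00728

#: Average-mass deltas of the built-in post-translational modifications.
MODIFICATION_DELTAS: Mapping[str, float] = {
    "methylation": 14.0266,
    "acetylation": 42.0367,
    "beta_methylthiolation": 46.0916,
}

#: Second residues that trigger initiator-Met excision (small side chains
#: accepted by methionine aminopeptidase).
MET_LOSS_SECOND_RESIDUES = frozenset("GASCTPV")


@dataclass
class ProteinRecord:
    """A protein with its mature (post N-terminal rule) theoretical mass.

    ``modifications`` lists the post-translational modification hypotheses
    this particular protein may carry (keys of MODIFICATION_DELTAS).
    Modifications are protein-specific — e.g. among ribosomal proteins,
    methylation of L33, acetylation of S18 and β-methylthiolation of S12
    are the conserved forms — so an empty list means only the unmodified
    hypothesis is entertained.
    """

    id: str
    theoretical_mass: float
    gene: str = ""
    subunit: str = ""
    sequence: str | None = None
    length: int | None = None
    second_residue: str | None = None
    met_loss: bool = False
    modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.theoretical_mass <= 0:
            raise ValueError(f"{self.id}: non-positive theoretical mass")
        if self.sequence:
            if self.length is not None and self.length != len(self.sequence):
                raise ValueError(f"{self.id}: length inconsistent with sequence")
            if (self.second_residue is not None and len(self.sequence) > 1
                    and self.second_residue != self.sequence[1]):
                raise ValueError(f"{self.id}: second residue inconsistent")


@dataclass
class AnnotationMatch:
    """An observed peak paired with its best theoretical hypothesis.

    ``error`` is signed, observed minus the hypothesis mass (theoretical
    plus modification delta); ``error_vs_unmodified`` is observed minus the
    unmodified theoretical mass — for modified matches this is the
    convention used when errors are reported against the gene-derived mass.
    """

    observed_mz: float
    protein_id: str
    subunit: str
    modification: str  # "none" or a MODIFICATION_DELTAS key
    error: float
    error_vs_unmodified: float
    channel: str = "wcms"


@dataclass
class DetectionReport:
    """Distinct-protein detection counts per channel."""

    detected: dict[str, list[str]]          # channel -> sorted protein ids
    counts: dict[str, int]                  # channel -> len(detected)
    in_range: list[str]                     # ids with mass inside mass_range
    undetected: dict[str, list[str]]        # channel -> in-range but unmatched
    mass_range: tuple[float, float]


def average_mass(sequence: str) -> float:
    """Theoretical average molecular mass of a protein: residues + one water."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in sequence.upper():
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None
    return total


def met_loss_expected(second_residue: str) -> bool:
    """N-terminal rule decision from the second residue alone."""
    return second_residue.upper() in MET_LOSS_SECOND_RESIDUES


def apply_nterm_rule(sequence: str) -> tuple[str, bool]:
    """Excise the initiator Met when the second residue is small.

    Returns the mature sequence and whether excision was applied.  The rule
    fires iff the sequence starts with M and the next residue is one of
    G, A, S, C, T, P, V.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if len(seq) >= 2 and seq[0] == "M" and met_loss_expected(seq[1]):
        return seq[1:], True
    return seq, False


def predict_masses(seqs: SequenceSet) -> list[ProteinRecord]:
    """Mature theoretical masses for a set of protein sequences."""
    if seqs.alphabet != "protein":
        raise ValueError("protein sequences required")
    records = []
    for sid, seq in seqs.records:
        mature, lost = apply_nterm_rule(seq)
        records.append(ProteinRecord(
            id=sid,
            theoretical_mass=average_mass(mature),
            sequence=seq.upper(),
            length=len(seq),
            second_residue=seq[1].upper() if len(seq) > 1 else None,
            met_loss=lost,
        ))
    return records


def annotate_peaks(observed: PeakList | Iterable[float],
                   records: Sequence[ProteinRecord],
                   tolerance: float = 5.0,
                   allow_modifications: bool = True,
                   channel: str = "wcms",
                   ) -> tuple[list[AnnotationMatch], list[float]]:
    """Match observed peaks to the nearest theoretical hypothesis.

    The hypothesis space per protein is the unmodified mass plus, when
    ``allow_modifications``, the deltas of that protein's declared
    modification hypotheses.  Each peak is
    assigned the hypothesis minimising the absolute mass difference and
    reported only when that difference is within ``tolerance`` Da; peaks
    matching nothing are returned in the second element.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not records:
        raise ValueError("no protein records to annotate against")
    mzs = list(observed.mz) if isinstance(observed, PeakList) else [float(m) for m in observed]
    hypotheses: list[tuple[float, ProteinRecord, str]] = []
    for rec in records:
        hypotheses.append((rec.theoretical_mass, rec, "none"))
        if allow_modifications:
            for mod in rec.modifications:
                hypotheses.append((rec.theoretical_mass + MODIFICATION_DELTAS[mod], rec, mod))
    hyp_masses = np.array([h[0] for h in hypotheses])
    matches: list[AnnotationMatch] = []
    unmatched: list[float] = []
    for mz in mzs:
        diffs = np.abs(hyp_masses - mz)
        best = int(np.argmin(diffs))
        if diffs[best] <= tolerance:
            mass, rec, mod = hypotheses[best]
            matches.append(AnnotationMatch(
                observed_mz=mz,
                protein_id=rec.id,
                subunit=rec.subunit or rec.id,
                modification=mod,
                error=mz - mass,
                error_vs_unmodified=mz - rec.theoretical_mass,
                channel=channel,
            ))
        else:
            unmatched.append(mz)
    return matches, unmatched


def detection_report(matches_by_channel: Mapping[str, Sequence[AnnotationMatch]],
                     records: Sequence[ProteinRecord],
                     mass_range: tuple[float, float] = (2000.0, 20000.0),
                     ) -> DetectionReport:
    """Distinct proteins detected per channel, and in-range misses."""
    lo, hi = mass_range
    in_range = [r.id for r in records if lo <= r.theoretical_mass <= hi]
    detected: dict[str, list[str]] = {}
    undetected: dict[str, list[str]] = {}
    for channel, matches in matches_by_channel.items():
        ids = sorted({m.protein_id for m in matches})
        detected[channel] = ids
        undetected[channel] = [i for i in in_range if i not in set(ids)]
    return DetectionReport(
        detected=detected,
        counts={ch: len(ids) for ch, ids in detected.items()},
        in_range=in_range,
        undetected=undetected,
        mass_range=mass_range,
    )


def shared_mass_sets(records_by_group: Mapping[str, Sequence[ProteinRecord]],
                     tolerance: float = 5.0) -> list[list[tuple[str, str]]]:
    """Masses shared across *all* groups, as lists of (group, protein id).

    Useful for asking whether any single mass could serve as a universal
    biomarker across a set of genomes: the returned list is empty unless a
    mass (within ``tolerance``) occurs in every group.
    """
    groups = list(records_by_group)
    if not groups:
        return []
    first = records_by_group[groups[0]]
    shared = []
    for rec in first:
        members = [(groups[0], rec.id)]
        for g in groups[1:]:
            hit = next((r for r in records_by_group[g]
                        if abs(r.theoretical_mass - rec.theoretical_mass) <= tolerance),
                       None)
            if hit is None:
                break
            members.append((g, hit.id))
        else:
            shared.append(members)
    return shared


# ---------------------------------------------------------------------------
# packaged worked example: ribosomal proteins of M. extorquens AM1

def load_am1_table() -> pd.DataFrame:
    """The packaged AM1 ribosomal-protein table (54 rows).

    Columns: locus_tag, gene, subunit, length, second_aa, met_loss,
    theoretical_mass, wcms_mz, wcms_error, ribosome_mz, ribosome_error,
    remark.
    """
    with resources.files("wcms.data").joinpath("am1_ribosomal_proteins.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"locus_tag": str})
    return df


#: Conserved protein-specific modification hypotheses (as in E. coli).
RIBOSOMAL_MODIFICATIONS: Mapping[str, tuple[str, ...]] = {
    "L33": ("methylation",),
    "S18": ("acetylation",),
    "S12": ("beta_methylthiolation",),
}


def am1_protein_records(df: pd.DataFrame | None = None) -> list[ProteinRecord]:
    """ProteinRecords from the packaged table (printed masses, no sequences)."""
    df = load_am1_table() if df is None else df
    return [
        ProteinRecord(
            id=str(row.locus_tag),
            theoretical_mass=float(row.theoretical_mass),
            gene=str(row.gene),
            subunit=str(row.subunit),
            length=int(row.length),
            second_residue=str(row.second_aa),
            met_loss=(row.met_loss == "yes"),
            modifications=RIBOSOMAL_MODIFICATIONS.get(str(row.subunit), ()),
        )
        for row in df.itertuples()
    ]


def am1_observed_peaks(channel: str, df: pd.DataFrame | None = None) -> list[float]:
    """Observed peak m/z of one channel ('wcms' or 'ribosome')."""
    df = load_am1_table() if df is None else df
    col = {"wcms": "wcms_mz", "ribosome": "ribosome_mz",
           "purified_ribosome": "ribosome_mz"}[channel]
    return [float(v) for v in df[col].dropna()]
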