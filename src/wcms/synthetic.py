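"""Synthetic multi-species spectral libraries.

Each species is a latent set of protein-like masses in m/z 2,000-20,000 with
latent relative heights; a replicate spectrum is a sum of Gaussian peaks at
jittered positions with multiplicative lognormal intensity noise, per-peak
dropout, and a sloped baseline, sampled on a uniform grid.  "Sibling"
species pairs share a controllable fraction of their latent masses, which
mirrors the near-identical type-strain pairs whose fingerprints correlate
at roughly 0.5.  A companion generator derives a 16S-like similarity table
from latent peak sharing, so the Mantel machinery has a positively
correlated matrix pair to work on.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .types import ACQUISITION_RANGE, SimilarityMatrix, Spectrum, Stage


@dataclass
class SpeciesProfile:
    """Latent fingerprint of one species."""

    species_id: str
    peak_mz: np.ndarray          # unique latent masses, Da
    peak_intensity: np.ndarray   # latent relative heights, percent (0, 100]

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, float)
        self.peak_intensity = np.asarray(self.peak_intensity, float)
        if self.peak_mz.size != self.peak_intensity.size:
            raise ValueError("mz / intensity length mismatch")
        if np.any((self.peak_intensity <= 0) | (self.peak_intensity > 100)):
            raise ValueError("latent heights must lie in (0, 100]")
        if len(np.unique(np.round(self.peak_mz, 6))) != self.peak_mz.size:
            raise ValueError("latent masses must be unique")


@dataclass
class NoiseModel:
    """Replicate-to-replicate variability of whole-cell spectra.

    Defaults emulate the observation that culture conditions shift peak
    intensities substantially while peak positions stay put: modest m/z
    jitter, strong multiplicative intensity noise, a few percent dropout,
    and a gently sloped low-level baseline.
    """

    mz_jitter_sd: float = 2.0        # Da
    intensity_cv: float = 0.25       # lognormal sigma of multiplicative noise
    dropout_prob: float = 0.03
    baseline_amplitude: float = 2.0  # percent-scale offset at low m/z
    baseline_slope: float = -1e-4    # per Da
    peak_width: float = 3.0          # Gaussian sigma, Da
    grid_step: float = 1.0           # Da
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        for name in ("mz_jitter_sd", "intensity_cv", "baseline_amplitude",
                     "peak_width", "grid_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.grid_step == 0 or self.peak_width == 0:
            raise ValueError("grid_step and peak_width must be positive")


def make_species(n_species: int, n_peaks: int = 30,
                 shared_fraction_pairs: Mapping[tuple[int, int], float] | None = None,
                 seed: int | None = None,
                 mz_range: tuple[float, float] = (3600.0, 19500.0),
                 min_separation: float = 40.0) -> list[SpeciesProfile]:
    """Draw latent fingerprints; designated pairs share a fraction of masses.

    ``shared_fraction_pairs`` maps (i, j) species indices to the fraction of
    ``n_peaks`` they share: species j reuses ``round(fraction * n_peaks)``
    of species i's masses.  All other masses are mutually separated by at
    least ``min_separation`` Da (default 40, i.e. 2x the default matching
    radius) so distinct latent peaks stay distinct after alignment.  Heights
    are log-uniform over [5, 100] percent so some peaks sit near the 5 %
    binarization threshold.
    """
    if n_peaks < 5:
        raise ValueError("n_peaks must be >= 5")
    shared_fraction_pairs = dict(shared_fraction_pairs or {})
    for (i, j), frac in shared_fraction_pairs.items():
        if not 0 <= frac < 1:
            raise ValueError("shared fractions must be in [0, 1)")
        if not (0 <= i < n_species and 0 <= j < n_species and i != j):
            raise ValueError(f"bad sibling pair ({i}, {j})")
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    # candidate lattice with guaranteed pairwise separation; species draw
    # cells without replacement, so separation holds across species too
    lattice = lo + min_separation * np.arange(int((hi - lo) / min_separation) + 1)
    if lattice.size < n_species * n_peaks:
        raise ValueError("mass range cannot hold the requested peaks "
                         "at the required separation")
    rng.shuffle(lattice)
    candidates = list(lattice)

    def draw_mass() -> float:
        return float(candidates.pop())

    masses: list[np.ndarray] = []
    for s in range(n_species):
        inherited: list[float] = []
        for (i, j), frac in shared_fraction_pairs.items():
            if j == s and i < s:
                k = round(frac * n_peaks)
                inherited = list(rng.choice(masses[i], size=k, replace=False))
        own = [draw_mass() for _ in range(n_peaks - len(inherited))]
        masses.append(np.sort(np.array(inherited + own)))
    profiles = []
    for s in range(n_species):
        heights = np.exp(rng.uniform(np.log(5.0), np.log(100.0), size=n_peaks))
        profiles.append(SpeciesProfile(f"sp{s}", masses[s], heights))
    return profiles


def render_replicate(profile: SpeciesProfile, noise: NoiseModel,
                     label: str | None = None,
                     rng: np.random.Generator | None = None) -> Spectrum:
    """One raw replicate spectrum of a species under the noise model."""
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    lo, hi = ACQUISITION_RANGE
    grid = np.arange(lo, hi + noise.grid_step / 2, noise.grid_step)
    y = np.zeros_like(grid)
    keep = rng.random(profile.peak_mz.size) >= noise.dropout_prob
    jitter = rng.normal(0.0, noise.mz_jitter_sd, size=profile.peak_mz.size)
    scale = np.exp(rng.normal(0.0, noise.intensity_cv, size=profile.peak_mz.size))
    for m, h, k, dj, sc in zip(profile.peak_mz, profile.peak_intensity,
                               keep, jitter, scale):
        if not k:
            continue
        mu = m + dj
        y += h * sc * np.exp(-0.5 * ((grid - mu) / noise.peak_width) ** 2)
    if noise.baseline_amplitude > 0:
        baseline = noise.baseline_amplitude * np.clip(
            1.0 + noise.baseline_slope * (grid - lo), 0.0, None)
        y = y + baseline
    return Spectrum(label or profile.species_id, grid, y, Stage.RAW)


def render_library(profiles: Sequence[SpeciesProfile], n_replicates: int,
                   noise: NoiseModel, seed: int | None = None,
                   ) -> tuple[list[Spectrum], list[str]]:
    """Replicate spectra for every species; returns (spectra, species truth).

    Labels are ``<species>_r<k>``; the truth list gives the species of each
    spectrum in order.
    """
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    spectra, truth = [], []
    for profile in profiles:
        for r in range(n_replicates):
            spectra.append(render_replicate(
                profile, noise, label=f"{profile.species_id}_r{r}", rng=rng))
            truth.append(profile.species_id)
    return spectra, truth


def latent_jaccard(a: SpeciesProfile, b: SpeciesProfile,
                   tolerance: float = 1e-6) -> float:
    """Jaccard index of two species' latent mass sets."""
    am, bm = a.peak_mz, b.peak_mz
    shared = sum(1 for m in am if np.any(np.abs(bm - m) <= tolerance))
    union = am.size + bm.size - shared
    return shared / union if union else 1.0


def make_correlated_16s(profiles: Sequence[SpeciesProfile],
                        decay: float = 0.0, seed: int | None = None,
                        ) -> SimilarityMatrix:
    """A 16S-like similarity table derived from latent peak sharing.

    Similarity is an affine map of the latent Jaccard index into the
    97-100 % range typical of congeneric type strains (stored as fractions
    0.97-1.00), with optional symmetric noise of scale ``decay``.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three species")
    rng = np.random.default_rng(seed)
    n = len(profiles)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            jac = latent_jaccard(profiles[i], profiles[j])
            sim = 0.97 + 0.03 * jac
            if decay > 0:
                sim = float(np.clip(sim + rng.normal(0.0, decay), 0.90, 1.0))
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix([p.species_id for p in profiles], values)


def provenance_header(seed: int | None, noise: NoiseModel, **extra) -> str:
    """One-line provenance note written into generated spectrum files."""
    fields = {"seed": seed, **{k: getattr(noise, k) for k in
                               ("mz_jitter_sd", "intensity_cv", "dropout_prob",
                                "peak_width", "grid_step")}, **extra}
    return "synthetic " + " ".join(f"{k}={v}" for k, v in fields.items())
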