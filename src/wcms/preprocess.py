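"""Profile-spectrum preprocessing: smoothing, baseline subtraction,
relative-intensity normalisation, averaging.

The default chain mirrors the classical SpecAlign-style treatment of linear
mode whole-cell spectra: three cycles of Savitzky-Golay smoothing, a
morphological top-hat baseline, then scaling to percent of the base peak.
The smoothing window/order are not dictated by the method itself; gentle
defaults (window 7 points, order 2) are exposed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import Spectrum, Stage


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    sg_window : odd number of points of the Savitzky-Golay window
    sg_polyorder : polynomial order (< sg_window)
    sg_cycles : how many times the filter is applied (default 3)
    baseline_method : "rolling_min_tophat" or "none"
    baseline_halfwidth : half-width of the structuring element in Da
    """

    sg_window: int = 7
    sg_polyorder: int = 2
    sg_cycles: int = 3
    baseline_method: str = "rolling_min_tophat"
    baseline_halfwidth: float = 50.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_cycles < 0:
            raise ValueError("sg_cycles must be >= 0")
        if self.baseline_method not in ("rolling_min_tophat", "none"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")


def smooth(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Apply ``sg_cycles`` passes of a Savitzky-Golay filter."""
    config = config or PreprocessConfig()
    if spectrum.stage not in (Stage.RAW, Stage.SMOOTHED):
        raise ValueError(f"{spectrum.label}: cannot smooth stage {spectrum.stage.value}")
    if config.sg_window > len(spectrum):
        raise ValueError(f"{spectrum.label}: SG window exceeds spectrum length")
    y = spectrum.intensity.copy()
    for _ in range(config.sg_cycles):
        y = signal.savgol_filter(y, config.sg_window, config.sg_polyorder)
    # the filter can produce tiny negative overshoots near sharp features
    np.clip(y, 0.0, None, out=y)
    return spectrum.with_intensity(y, Stage.SMOOTHED)


def estimate_baseline(spectrum: Spectrum, halfwidth: float) -> np.ndarray:
    """Morphological opening (rolling minimum then maximum) of the profile.

    The structuring element spans ``2*halfwidth`` Da on the spectrum's grid,
    so any feature narrower than that is excluded from the baseline.
    """
    step = float(np.median(np.diff(spectrum.mz))) if len(spectrum) > 1 else 1.0
    size = max(3, 2 * int(round(halfwidth / step)) + 1)
    size = min(size, len(spectrum))
    y = spectrum.intensity
    # pad by linear edge extrapolation so a sloped baseline is recovered
    # exactly at the boundaries (a bare opening leaves a slope*halfwidth
    # artifact inside one half-window of each edge)
    half = size // 2
    n = y.size
    k = max(min(half, n - 1), 1)
    slope_l = (y[k] - y[0]) / k
    slope_r = (y[-1] - y[-1 - k]) / k
    left = y[0] - slope_l * np.arange(half, 0, -1)
    right = y[-1] + slope_r * np.arange(1, half + 1)
    padded = np.concatenate([left, y, right])
    opened = ndimage.grey_opening(padded, size=size, mode="nearest")
    return opened[half:half + n] if half else opened


def subtract_baseline(spectrum: Spectrum,
                      config: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the top-hat baseline estimate, clipping at zero."""
    config = config or PreprocessConfig()
    if spectrum.stage not in (Stage.RAW, Stage.SMOOTHED):
        raise ValueError(
            f"{spectrum.label}: cannot baseline stage {spectrum.stage.value}")
    if config.baseline_method == "none":
        return spectrum.with_intensity(spectrum.intensity, Stage.BASELINED)
    baseline = estimate_baseline(spectrum, config.baseline_halfwidth)
    y = np.maximum(spectrum.intensity - baseline, 0.0)
    return spectrum.with_intensity(y, Stage.BASELINED)


def to_relative(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to percent of the base peak (max = 100).

    An all-zero spectrum is returned unchanged with the ``empty`` flag set.
    """
    if spectrum.stage is Stage.RELATIVE:
        return spectrum
    if spectrum.stage is not Stage.BASELINED:
        raise ValueError(
            f"{spectrum.label}: normalise after baseline subtraction "
            f"(got stage {spectrum.stage.value})")
    peak = spectrum.intensity.max() if len(spectrum) else 0.0
    if peak <= 0:
        out = spectrum.with_intensity(spectrum.intensity, Stage.RELATIVE)
        out.empty = True
        return out
    return spectrum.with_intensity(spectrum.intensity * (100.0 / peak),
                                   Stage.RELATIVE)


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a common m/z grid."""
    y = np.interp(grid, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    return Spectrum(spectrum.label, grid, y, spectrum.stage, spectrum.empty)


def common_grid(spectra: Sequence[Spectrum]) -> np.ndarray:
    """Coarsest common uniform grid: step = max of the median raw spacings."""
    step = max(float(np.median(np.diff(s.mz))) for s in spectra)
    lo = min(float(s.mz[0]) for s in spectra)
    hi = max(float(s.mz[-1]) for s in spectra)
    return np.arange(lo, hi + step / 2, step)


def average_spectrum(spectra: Sequence[Spectrum], label: str | None = None,
                     ) -> Spectrum:
    """Pointwise arithmetic mean of relative-intensity replicate spectra.

    Spectra on differing grids are linearly resampled to the coarsest
    common uniform grid first.  The mean is returned as-is (percent units);
    its base peak is only 100 when the members share their base-peak position,
    so the result is at the ``baselined`` stage unless the invariant happens
    to hold.
    """
    if not spectra:
        raise ValueError("average of no spectra")
    for s in spectra:
        if s.stage is not Stage.RELATIVE:
            raise ValueError(f"{s.label}: average requires relative-stage spectra")
    grids_match = all(
        len(s) == len(spectra[0]) and np.array_equal(s.mz, spectra[0].mz)
        for s in spectra[1:]
    )
    if grids_match:
        grid = spectra[0].mz
        stack = np.vstack([s.intensity for s in spectra])
    else:
        grid = common_grid(spectra)
        stack = np.vstack([resample(s, grid).intensity for s in spectra])
    mean = stack.mean(axis=0)
    stage = (Stage.RELATIVE
             if mean.size and abs(mean.max() - 100.0) < 1e-9
             else Stage.BASELINED)
    return Spectrum(label or f"mean(n={len(spectra)})", grid, mean, stage)


def preprocess(spectrum: Spectrum, config: PreprocessConfig | None = None,
               ) -> Spectrum:
    """Full chain: smooth -> baseline -> relative."""
    config = config or PreprocessConfig()
    s = smooth(spectrum, config) if config.sg_cycles > 0 else spectrum
    return to_relative(subtract_baseline(s, config))


class SpectrumPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer wrapping the preprocessing chain.

    ``transform`` maps a sequence of raw :class:`Spectrum` objects to
    relative-intensity spectra; with ``average_replicates=True`` inputs whose
    labels share the prefix before the last ``_`` are averaged into one
    spectrum per strain.
    """

    def __init__(self, sg_window: int = 7, sg_polyorder: int = 2,
                 sg_cycles: int = 3, baseline_method: str = "rolling_min_tophat",
                 baseline_halfwidth: float = 50.0,
                 average_replicates: bool = False):
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.sg_cycles = sg_cycles
        self.baseline_method = baseline_method
        self.baseline_halfwidth = baseline_halfwidth
        self.average_replicates = average_replicates

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(self.sg_window, self.sg_polyorder, self.sg_cycles,
                                self.baseline_method, self.baseline_halfwidth)

    def fit(self, X: Sequence[Spectrum], y=None) -> "SpectrumPreprocessor":
        self._config()  # validate parameters
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: Sequence[Spectrum]) -> list[Spectrum]:
        config = self._config()
        out = [preprocess(s, config) for s in X]
        if self.average_replicates:
            groups: dict[str, list[Spectrum]] = {}
            for s in out:
                strain = s.label.rsplit("_", 1)[0]
                groups.setdefault(strain, []).append(s)
            out = [to_relative(average_spectrum(v, label=k))
                   for k, v in groups.items()]
        return out
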