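"""MTR asymmetry spectra and APT-weighted maps.

MTR_asym(x) = MTR(+x) - MTR(-x) = Z(-x) - Z(+x): the downfield excess
saturation relative to the mirrored upfield offset.  Evaluated at 3.5 ppm
(the backbone amide resonance) this is the APT-weighted quantity; the
per-pixel image of it is the APT-weighted map.  Values are dimensionless
internally; multiply by 100 (or use ``as_percent``) for the percent units
used in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correction import FitConfig, correct_stack
from .spectra import ImageStack, PixelSpectra, ZSpectrum, assemble_zspectra


@dataclass
class AsymmetrySpectrum:
    """MTR_asym versus positive offset (ppm), for one pixel or ROI."""

    offsets: np.ndarray
    values: np.ndarray
    source: str = "roi"

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def as_percent(self) -> np.ndarray:
        return 100.0 * self.values

    def value_at(self, offset: float, tol: float = 1e-6) -> float:
        idx = np.flatnonzero(np.abs(self.offsets - offset) <= tol)
        if idx.size == 0:
            raise ValueError(f"offset {offset} ppm not in asymmetry spectrum")
        return float(self.values[idx[0]])


def mtr_asym(spec: ZSpectrum, offset: float) -> float:
    """MTR_asym at one offset: Z(-offset) - Z(+offset).

    Both +offset and -offset must be on the spectrum grid; there is no
    silent nearest-neighbour substitution.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if not (spec.has_offset(offset) and spec.has_offset(-offset)):
        raise ValueError(f"offsets ±{offset} ppm not both present in spectrum")
    return spec.value_at(-offset) - spec.value_at(offset)


def asym_spectrum(spec: ZSpectrum, source: str = "roi") -> AsymmetrySpectrum:
    """MTR_asym at every positive offset whose negative twin exists."""
    pos = spec.offsets[spec.offsets > 0]
    usable = np.array([p for p in pos if spec.has_offset(-p)])
    values = np.array([mtr_asym(spec, p) for p in usable])
    return AsymmetrySpectrum(usable, values, source=source)


@dataclass
class APTMap:
    """Per-pixel MTR_asym at the target offset (default 3.5 ppm).

    ``values`` is NaN outside the validity mask; the default display window
    for rendering is (-5, +5) percent.
    """

    values: np.ndarray
    mask: np.ndarray
    target_offset: float = 3.5
    display_window: tuple[float, float] = (-0.05, 0.05)

    @property
    def as_percent(self) -> np.ndarray:
        return 100.0 * self.values


def asym_map(spectra: PixelSpectra, offset: float = 3.5) -> APTMap:
    """Per-pixel MTR_asym image from (corrected) per-pixel spectra."""
    i_neg = np.flatnonzero(np.abs(spectra.offsets + offset) <= 1e-6)
    i_pos = np.flatnonzero(np.abs(spectra.offsets - offset) <= 1e-6)
    if i_neg.size == 0 or i_pos.size == 0:
        raise ValueError(f"offsets ±{offset} ppm not in the acquisition grid")
    values = spectra.values[i_neg[0]] - spectra.values[i_pos[0]]
    values = np.where(spectra.mask, values, np.nan)
    return APTMap(values=values, mask=spectra.mask.copy(), target_offset=offset)


def build_apt_map(stack: ImageStack, config: FitConfig | None = None,
                  target_offset: float = 3.5,
                  b0_correct: bool = True) -> APTMap:
    """APT-weighted map from a raw offset image stack.

    Assembles per-pixel z-spectra, applies pixel-wise B0 correction (unless
    disabled) and evaluates MTR_asym at the target offset.
    """
    spectra = assemble_zspectra(stack)
    if b0_correct:
        spectra, _ = correct_stack(spectra, config)
    return asym_map(spectra, offset=target_offset)
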