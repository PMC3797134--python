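"""Z-spectrum containers, stack assembly, MTR computation and ROI geometry.

A z-spectrum is the normalized water signal S_sat/S_0 as a function of the
saturation offset (ppm from water).  Spectra are always stored with offsets
in ascending order (-6 ... +6 ppm for the default schedule); writers may
emit the acquisition (high-to-low) order but every in-memory container is
normalized on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .params import AcquisitionSchedule


class EmptyROIError(ValueError):
    """Raised when an ROI resolves to zero valid pixels."""


@dataclass
class ZSpectrum:
    """One z-spectrum (pixel or ROI average).

    ``state`` is one of ``raw``, ``fitted``, ``b0-corrected``; a corrected
    spectrum must carry the B0 estimate that was removed.  ``extrapolated``
    flags offsets that, after B0 shifting, fell outside the measured range
    and were evaluated by polynomial extrapolation.
    """

    offsets: np.ndarray
    values: np.ndarray
    state: str = "raw"
    b0_estimate: float | None = None
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and values must be 1-D and equal length")
        order = np.argsort(self.offsets)
        self.offsets = self.offsets[order]
        self.values = self.values[order]
        if self.extrapolated is not None:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)[order]
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be unique")
        if self.state == "b0-corrected" and self.b0_estimate is None:
            raise ValueError("corrected spectrum requires a b0_estimate")

    def value_at(self, offset: float, tol: float = 1e-6) -> float:
        """Value at an offset that must exist on the grid (no interpolation)."""
        idx = np.flatnonzero(np.abs(self.offsets - offset) <= tol)
        if idx.size == 0:
            raise ValueError(f"offset {offset} ppm not in spectrum grid")
        return float(self.values[idx[0]])

    def has_offset(self, offset: float, tol: float = 1e-6) -> bool:
        return bool(np.any(np.abs(self.offsets - offset) <= tol))

    def mirrored(self) -> "ZSpectrum":
        """Spectrum reflected about 0 ppm (Z(x) -> Z(-x))."""
        return ZSpectrum(-self.offsets[::-1], self.values[::-1].copy(),
                         state=self.state, b0_estimate=self.b0_estimate)


def compute_mtr(s_sat, s0):
    """Magnetization transfer ratio MTR = 1 - S_sat/S_0.

    ``s0`` must be strictly positive (element-wise for arrays).
    """
    s_sat = np.asarray(s_sat, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("S0 must be strictly positive to compute MTR")
    out = 1.0 - s_sat / s0
    return float(out) if out.ndim == 0 else out


@dataclass
class ImageStack:
    """Per-offset saturation images plus the unsaturated control image.

    ``sat_images`` has shape (n_offsets, H, W) in the order of
    ``schedule.offsets``; ``pixel_size_mm`` is the in-plane pixel pitch
    (field of view / matrix size).
    """

    sat_images: np.ndarray
    s0_image: np.ndarray
    schedule: AcquisitionSchedule
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.sat_images = np.asarray(self.sat_images, dtype=float)
        self.s0_image = np.asarray(self.s0_image, dtype=float)
        if self.sat_images.ndim != 3:
            raise ValueError("sat_images must have shape (n_offsets, H, W)")
        if self.sat_images.shape[0] != len(self.schedule):
            raise ValueError(
                f"{self.sat_images.shape[0]} saturation images for "
                f"{len(self.schedule)} scheduled offsets"
            )
        if self.s0_image.shape != self.sat_images.shape[1:]:
            raise ValueError("S0 image dimensions differ from saturation images")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.s0_image.shape


def estimate_background_sigma(s0_image: np.ndarray,
                              patch: int | None = None) -> float:
    """Noise scale from the darkest corner patch of the S0 image.

    The corner with the lowest mean signal is taken as background (air);
    its standard deviation estimates the additive noise sigma.  The patch
    scales with the image (1/8 of the side) so it stays clear of the body
    outline at any resolution.
    """
    s0_image = np.asarray(s0_image, dtype=float)
    h, w = s0_image.shape
    if patch is None:
        patch = max(2, min(h, w) // 8)
    p = min(patch, h, w)
    corners = [
        s0_image[:p, :p], s0_image[:p, -p:],
        s0_image[-p:, :p], s0_image[-p:, -p:],
    ]
    darkest = min(corners, key=lambda c: float(np.mean(c)))
    return float(np.std(darkest))


def s0_mask(s0_image: np.ndarray, noise_multiple: float = 5.0,
            threshold: float | None = None) -> np.ndarray:
    """Validity mask: pixel valid iff S0 exceeds ``noise_multiple`` times the
    estimated background noise (air is excluded; dividing by its S0 would be
    meaningless).  A noiseless image falls back to a tiny positive threshold
    so exact-zero air pixels are still rejected."""
    s0_image = np.asarray(s0_image, dtype=float)
    if threshold is None:
        sigma = estimate_background_sigma(s0_image)
        if sigma > 0:
            threshold = noise_multiple * sigma
        else:
            threshold = 1e-9 * max(float(np.max(s0_image)), 1.0)
    return s0_image > threshold


@dataclass
class PixelSpectra:
    """Per-pixel z-spectra for a whole image, with a validity mask.

    ``values`` has shape (n_offsets, H, W) with offsets ascending; masked
    pixels hold NaN and are excluded from all downstream maps and ROI
    statistics.
    """

    offsets: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    s0: np.ndarray
    pixel_size_mm: float
    state: str = "raw"
    b0: np.ndarray | None = None
    extrapolated: np.ndarray | None = None

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.mask.shape

    def spectrum_at(self, row: int, col: int) -> ZSpectrum:
        if not self.mask[row, col]:
            raise ValueError(f"pixel ({row}, {col}) is masked out")
        b0 = None if self.b0 is None else float(self.b0[row, col])
        extra = None if self.extrapolated is None else self.extrapolated[:, row, col]
        return ZSpectrum(self.offsets.copy(), self.values[:, row, col].copy(),
                         state=self.state, b0_estimate=b0, extrapolated=extra)


def assemble_zspectra(stack: ImageStack, noise_multiple: float = 5.0,
                      s0_threshold: float | None = None) -> PixelSpectra:
    """Organize an offset image stack into per-pixel z-spectra.

    Divides each saturation image by S0 pixel-wise, reorders offsets to
    ascending, and masks out pixels whose S0 is at the noise floor rather
    than propagating NaN/inf from the division.
    """
    if len(stack.schedule) == 0:
        raise ValueError("empty schedule")
    mask = s0_mask(stack.s0_image, noise_multiple=noise_multiple,
                   threshold=s0_threshold)
    offsets = np.asarray(stack.schedule.offsets, dtype=float)
    order = np.argsort(offsets)
    sat = stack.sat_images[order]
    values = np.full_like(sat, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[:, mask] = sat[:, mask] / stack.s0_image[mask]
    return PixelSpectra(offsets=offsets[order], values=values, mask=mask,
                        s0=stack.s0_image.copy(),
                        pixel_size_mm=stack.pixel_size_mm, state="raw")


@dataclass(frozen=True)
class ROI:
    """Circular region of interest.

    Centre is in 0-based pixel coordinates (row, col); ``area_mm2`` sets the
    radius via the pixel pitch (the protocol's typical ROI is 0.34 mm^2,
    about 2.8 pixels radius on a 256 grid over a 30 mm field of view).
    """

    label: str
    center_row: float
    center_col: float
    area_mm2: float
    animal_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("ROI area must be positive")

    def radius_px(self, pixel_size_mm: float) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi) / pixel_size_mm)

    def resolve(self, image_shape: tuple[int, int], pixel_size_mm: float,
                mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Member pixel indices: centre-to-centre distance <= radius, valid
        under ``mask``.  A point ROI smaller than one pixel keeps its centre
        pixel."""
        h, w = image_shape
        rr, cc = np.mgrid[0:h, 0:w]
        dist = np.hypot(rr - self.center_row, cc - self.center_col)
        inside = dist <= max(self.radius_px(pixel_size_mm), 0.5)
        if mask is not None:
            inside &= mask
        rows, cols = np.nonzero(inside)
        if rows.size == 0:
            raise EmptyROIError(f"ROI {self.label!r} contains no valid pixels")
        return rows, cols


def roi_spectrum(spectra: PixelSpectra, roi: ROI) -> ZSpectrum:
    """Offset-wise mean z-spectrum over the ROI's valid member pixels."""
    rows, cols = roi.resolve(spectra.image_shape, spectra.pixel_size_mm,
                             mask=spectra.mask)
    values = spectra.values[:, rows, cols].mean(axis=1)
    b0 = None
    if spectra.b0 is not None:
        b0 = float(np.nanmean(spectra.b0[rows, cols]))
    return ZSpectrum(spectra.offsets.copy(), values, state=spectra.state,
                     b0_estimate=b0)


def roi_mean(image: np.ndarray, roi: ROI, pixel_size_mm: float,
             mask: np.ndarray | None = None) -> float:
    """Mean of a scalar per-pixel map over the ROI."""
    rows, cols = roi.resolve(image.shape, pixel_size_mm, mask=mask)
    return float(np.nanmean(image[rows, cols]))
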