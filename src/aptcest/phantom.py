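"""Synthetic thorax phantom: tissue geometry, B0 field and image stacks.

The phantom emulates a single axial slice through a mouse thorax as seen in
saturation-transfer imaging of orthotopic lung tumors: near-zero-signal lung
parenchyma (air), one or two tumor nodules with elevated amide exchange
inside the lungs, a spinal-cord reference region with slightly negative
intrinsic MTR asymmetry, skeletal-muscle background, a smooth spatial B0
offset surface, and additive Gaussian noise on the magnitude images.

Each pixel's signal at nominal offset x is

    S(x) = S0_tissue * Z_tissue(x; b0(pixel)) + noise,

with Z simulated by the Bloch-McConnell model.  The local B0 field is
quantized to a configurable step (default 0.005 ppm) so that simulated
spectra can be shared between pixels of the same tissue; the quantization
error is an order of magnitude below the correction stage's fine-grid
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import simulate_zspectrum
from .params import (AcquisitionSchedule, PoolParams, SaturationParams,
                     ScannerParams, amide_pool, mt_pool, water_pool)
from .spectra import ImageStack, ZSpectrum

TISSUE_CODES = {"air": 0, "muscle": 1, "cord": 2, "tumor_a": 3, "tumor_b": 4}


@dataclass(frozen=True)
class TissueSpec:
    """Signal level and exchange-model pools of one tissue class."""

    name: str
    s0: float
    pools: tuple[PoolParams, ...]


def default_tissues(tumor_fraction: float = 3e-3,
                    tumor_fraction_b: float | None = None,
                    background_fraction: float = 1e-3,
                    include_mt: bool = True) -> dict[str, TissueSpec]:
    """Default tissue parameter sets.

    Muscle and cord share the background amide fraction; tumors carry an
    elevated fraction.  All signal-bearing tissues include the broad MT pool
    (the source of the intrinsically negative reference asymmetry) unless
    ``include_mt`` is False.
    """
    if tumor_fraction_b is None:
        tumor_fraction_b = tumor_fraction
    mt = (mt_pool(),) if include_mt else ()

    def pools(fraction):
        return (water_pool(), amide_pool(fraction)) + mt

    return {
        "air": TissueSpec("air", 0.0, (water_pool(),)),
        "muscle": TissueSpec("muscle", 1.0, pools(background_fraction)),
        "cord": TissueSpec("cord", 1.0, pools(background_fraction)),
        "tumor_a": TissueSpec("tumor_a", 1.1, pools(tumor_fraction)),
        "tumor_b": TissueSpec("tumor_b", 1.1, pools(tumor_fraction_b)),
    }


def build_tissue_map(image_size: int, include_tumor_b: bool = True) -> np.ndarray:
    """Thorax-slice label image: muscle body, two air lungs, cord, tumors."""
    u, v = np.mgrid[0:image_size, 0:image_size] / float(image_size)

    def ellipse(cu, cv, ru, rv):
        return ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0

    tmap = np.zeros((image_size, image_size), dtype=np.int8)
    tmap[ellipse(0.52, 0.50, 0.42, 0.44)] = TISSUE_CODES["muscle"]
    lungs = ellipse(0.45, 0.32, 0.22, 0.15) | ellipse(0.45, 0.68, 0.22, 0.15)
    tmap[lungs] = TISSUE_CODES["air"]
    tmap[ellipse(0.82, 0.50, 0.06, 0.06)] = TISSUE_CODES["cord"]
    tmap[ellipse(0.42, 0.68, 0.09, 0.09) & lungs] = TISSUE_CODES["tumor_a"]
    if include_tumor_b:
        tmap[ellipse(0.50, 0.32, 0.065, 0.065) & lungs] = TISSUE_CODES["tumor_b"]
    return tmap


def smooth_b0_surface(image_size: int, amplitude: float) -> np.ndarray:
    """Smooth static-field offset surface (ppm), peak magnitude = amplitude."""
    if amplitude == 0:
        return np.zeros((image_size, image_size))
    u, v = np.mgrid[0:image_size, 0:image_size] / float(image_size)
    surface = 0.7 * np.sin(np.pi * u + 0.4) * np.cos(np.pi * v - 0.3) \
        + 0.3 * (u - v)
    return amplitude * surface / np.max(np.abs(surface))


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic animal.

    ``b0_amplitude`` is the peak |B0| of the default smooth surface (ppm,
    within the ±0.5 ppm design range); ``noise_sigma`` is the additive
    Gaussian noise scale relative to muscle S0; ``b0_quantization`` trades
    simulation time against B0 granularity (0 disables).  Custom
    ``tissue_map`` / ``b0_field`` arrays override the built-in geometry.
    """

    image_size: int = 64
    fov_mm: float = 30.0
    tissues: dict[str, TissueSpec] = field(default_factory=default_tissues)
    include_tumor_b: bool = True
    b0_amplitude: float = 0.3
    noise_sigma: float = 0.01
    seed: int = 0
    b0_quantization: float = 0.005
    tissue_map: np.ndarray | None = None
    b0_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8 pixels")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        missing = set(TISSUE_CODES) - set(self.tissues)
        if missing:
            raise ValueError(f"tissue parameters missing for {sorted(missing)}")

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm / self.image_size


@dataclass
class PhantomTruth:
    """Ground truth saved alongside a generated stack."""

    tissue_map: np.ndarray
    tissue_labels: dict[int, str]
    b0_field: np.ndarray
    s0_map: np.ndarray
    true_asym_map: np.ndarray
    tissue_spectra: dict[str, ZSpectrum]
    tissue_asym: dict[str, float]
    target_offset: float = 3.5

    def tissue_fraction(self, name: str) -> float:
        """Fraction of pixels carrying the given tissue label."""
        code = TISSUE_CODES[name]
        return float(np.mean(self.tissue_map == code))

    def centroid(self, name: str) -> tuple[float, float]:
        rows, cols = np.nonzero(self.tissue_map == TISSUE_CODES[name])
        if rows.size == 0:
            raise ValueError(f"tissue {name!r} absent from phantom")
        return float(rows.mean()), float(cols.mean())


def generate_phantom_stack(
    spec: PhantomSpec,
    schedule: AcquisitionSchedule | None = None,
    sat: SaturationParams | None = None,
    scanner: ScannerParams | None = None,
    target_offset: float = 3.5,
) -> tuple[ImageStack, PhantomTruth]:
    """Simulate one phantom image stack plus its ground-truth record.

    Same spec and seed give bit-identical output.
    """
    schedule = schedule or AcquisitionSchedule.default()
    sat = sat or SaturationParams()
    scanner = scanner or ScannerParams()
    n = spec.image_size

    tmap = (spec.tissue_map if spec.tissue_map is not None
            else build_tissue_map(n, spec.include_tumor_b))
    b0 = (spec.b0_field if spec.b0_field is not None
          else smooth_b0_surface(n, spec.b0_amplitude))
    if tmap.shape != (n, n) or b0.shape != (n, n):
        raise ValueError("tissue_map and b0_field must match image_size")
    if spec.b0_quantization > 0:
        b0 = np.round(b0 / spec.b0_quantization) * spec.b0_quantization

    s0_map = np.zeros((n, n))
    sat_images = np.zeros((len(schedule), n, n))
    tissue_spectra: dict[str, ZSpectrum] = {}
    tissue_asym: dict[str, float] = {}
    true_asym = np.full((n, n), np.nan)

    for name, code in TISSUE_CODES.items():
        sel = tmap == code
        if not np.any(sel):
            continue
        tissue = spec.tissues[name]
        s0_map[sel] = tissue.s0
        zero_spec = simulate_zspectrum(tissue.pools, sat, scanner, schedule)
        tissue_spectra[name] = zero_spec
        if name == "air":
            continue
        asym = (zero_spec.value_at(-target_offset)
                - zero_spec.value_at(target_offset))
        tissue_asym[name] = asym
        true_asym[sel] = asym
        for b0_val in np.unique(b0[sel]):
            z = simulate_zspectrum(tissue.pools, sat, scanner, schedule,
                                   b0_offset=float(b0_val))
            # re-order simulated (ascending) values back to schedule order
            sched_idx = np.argsort(np.argsort(schedule.offsets))
            px = sel & (b0 == b0_val)
            sat_images[:, px] = (tissue.s0 * z.values[sched_idx])[:, None]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scale = spec.noise_sigma * spec.tissues["muscle"].s0
        sat_images = sat_images + rng.normal(0.0, scale, sat_images.shape)
        s0_image = s0_map + rng.normal(0.0, scale, s0_map.shape)
    else:
        s0_image = s0_map.copy()

    stack = ImageStack(sat_images=sat_images, s0_image=s0_image,
                       schedule=schedule, pixel_size_mm=spec.pixel_size_mm)
    truth = PhantomTruth(tissue_map=tmap.copy(),
                         tissue_labels={v: k for k, v in TISSUE_CODES.items()},
                         b0_field=b0.copy(), s0_map=s0_map,
                         true_asym_map=true_asym,
                         tissue_spectra=tissue_spectra,
                         tissue_asym=tissue_asym,
                         target_offset=target_offset)
    return stack, truth


def with_tumor_fractions(spec: PhantomSpec, fraction: float,
                         fraction_b: float | None = None) -> PhantomSpec:
    """Copy of a phantom spec with tumor amide fractions replaced."""
    if fraction_b is None:
        fraction_b = fraction
    tissues = dict(spec.tissues)
    for name, frac in (("tumor_a", fraction), ("tumor_b", fraction_b)):
        old = tissues[name]
        pools = tuple(replace(p, fraction=frac) if p.name == "amide" else p
                      for p in old.pools)
        tissues[name] = TissueSpec(old.name, old.s0, pools)
    return replace(spec, tissues=tissues)


def phantom_rois(truth: PhantomTruth, area_mm2: float = 2.0,
                 animal_id: str | None = None,
                 group: str | None = None):
    """Tumor and cord ROIs at the phantom's tissue centroids.

    The synthetic ROIs are larger than the in-vivo protocol's 0.34 mm^2
    because the phantom grid is coarser than a 256-matrix acquisition; the
    area is configurable.
    """
    from .spectra import ROI

    rois = []
    for name in ("tumor_a", "tumor_b"):
        if np.any(truth.tissue_map == TISSUE_CODES[name]):
            r, c = truth.centroid(name)
            rois.append(ROI(label="tumor", center_row=r, center_col=c,
                            area_mm2=area_mm2, animal_id=animal_id,
                            group=group))
    r, c = truth.centroid("cord")
    rois.append(ROI(label="cord", center_row=r, center_col=c,
                    area_mm2=area_mm2, animal_id=animal_id, group=group))
    return rois
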