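"""Acquisition and exchange-model parameter types.

Conventions used throughout the package:

* chemical-shift offsets are in ppm relative to the water resonance, with
  positive values downfield (backbone amide protons sit at +3.5 ppm);
* the saturation field amplitude B1 is in microtesla, durations in seconds;
* all parameter containers are frozen dataclasses so they can be hashed and
  used as cache keys for simulated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

#: Proton gyromagnetic ratio, MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class ScannerParams:
    """Static-field description of the scanner.

    The default emulates a 7 T small-animal system.  ``ppm_to_hz`` is the
    linear map ``x -> x * field_strength * gyromagnetic_ratio`` (Hz), used
    everywhere a ppm offset enters the Bloch equations.
    """

    field_strength: float = 7.0  # tesla
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO_MHZ_PER_T  # MHz / T

    def __post_init__(self) -> None:
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        if self.gyromagnetic_ratio <= 0:
            raise ValueError("gyromagnetic_ratio must be positive")

    @property
    def water_frequency_hz(self) -> float:
        """Proton Larmor frequency in Hz."""
        return self.field_strength * self.gyromagnetic_ratio * 1e6

    def ppm_to_hz(self, ppm):
        return ppm * self.field_strength * self.gyromagnetic_ratio

    def hz_to_ppm(self, hz):
        return hz / (self.field_strength * self.gyromagnetic_ratio)


@dataclass(frozen=True)
class SaturationParams:
    """Continuous-wave presaturation pulse parameters.

    Defaults follow the block-pulse protocol used for in-vivo APT imaging of
    the mouse thorax: B1 = 1.7 uT applied for 4 s before the readout.
    """

    b1_amplitude: float = 1.7  # microtesla
    duration: float = 4.0  # seconds
    pulse_shape: str = "continuous-wave block"

    def __post_init__(self) -> None:
        if self.b1_amplitude < 0:
            raise ValueError("b1_amplitude must be non-negative")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.pulse_shape != "continuous-wave block":
            raise ValueError(
                f"unsupported pulse shape {self.pulse_shape!r}; only "
                "'continuous-wave block' is modelled"
            )

    def omega1(self, scanner: ScannerParams) -> float:
        """Nutation frequency omega_1 = gamma * B1 in rad/s."""
        # MHz/T * uT = Hz, so no further unit factor is needed.
        return TWO_PI * scanner.gyromagnetic_ratio * self.b1_amplitude


@dataclass(frozen=True)
class PoolParams:
    """Relaxation and exchange parameters of one proton pool.

    ``fraction`` is the proton fraction relative to water (water itself is
    fixed at 1) and ``exchange_rate`` is the pool-to-water rate in 1/s; the
    reverse water-to-pool rate follows from detailed balance as
    ``fraction * exchange_rate``.
    """

    name: str
    t1: float  # s
    t2: float  # s
    fraction: float = 1.0
    shift: float = 0.0  # ppm, downfield positive
    exchange_rate: float = 0.0  # 1/s, pool -> water

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"pool {self.name!r}: relaxation times must be positive")
        if self.t2 > self.t1:
            raise ValueError(f"pool {self.name!r}: t2 must not exceed t1")
        if self.fraction < 0:
            raise ValueError(f"pool {self.name!r}: fraction must be non-negative")
        if self.exchange_rate < 0:
            raise ValueError(f"pool {self.name!r}: exchange_rate must be non-negative")
        if self.name == "water" and (self.shift != 0.0 or self.fraction != 1.0):
            raise ValueError("water pool must have shift 0 and fraction 1")


def water_pool(t1: float = 1.8, t2: float = 0.05) -> PoolParams:
    """Bulk-water pool with tissue-like relaxation at 7 T."""
    return PoolParams("water", t1=t1, t2=t2, fraction=1.0, shift=0.0)


def amide_pool(
    fraction: float = 1e-3,
    t1: float = 1.0,
    t2: float = 0.001,
    shift: float = 3.5,
    exchange_rate: float = 100.0,
) -> PoolParams:
    """Mobile-protein backbone amide pool, +3.5 ppm downfield of water.

    The default linewidth parameters (T2 = 1 ms, k = 100 /s) give an amide
    dip roughly 0.6 ppm wide at 1.7 uT, which the 0.5 ppm acquisition grid
    samples adequately; a much narrower dip cannot be interpolated reliably
    by any method from this protocol's offsets.
    """
    return PoolParams("amide", t1=t1, t2=t2, fraction=fraction, shift=shift,
                      exchange_rate=exchange_rate)


def mt_pool(
    fraction: float = 0.05,
    t1: float = 1.0,
    t2: float = 6e-5,
    shift: float = -2.4,
    exchange_rate: float = 40.0,
) -> PoolParams:
    """Broad background magnetization-transfer pool.

    The very short T2 gives a lineshape several ppm wide and the slightly
    upfield centre makes the background MT effect asymmetric about water, so
    reference tissue carrying this pool shows the small *negative* intrinsic
    MTR asymmetry observed in spinal cord and normal brain.  Off by default
    in the two-pool oracle configurations.
    """
    return PoolParams("mt", t1=t1, t2=t2, fraction=fraction, shift=shift,
                      exchange_rate=exchange_rate)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered saturation-offset schedule plus the unsaturated control flag.

    The default reproduces the acquisition protocol: 25 offsets from +6 ppm
    down to -6 ppm in 0.5 ppm steps, with an S0 control image acquired
    without presaturation.
    """

    offsets: tuple[float, ...]
    includes_s0: bool = True

    def __post_init__(self) -> None:
        if len(self.offsets) == 0:
            raise ValueError("schedule must contain at least one offset")
        arr = np.asarray(self.offsets, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("offsets must be finite")
        if len(np.unique(arr)) != len(arr):
            raise ValueError("offsets must be unique")
        object.__setattr__(self, "offsets", tuple(float(x) for x in arr))

    @classmethod
    def default(cls) -> "AcquisitionSchedule":
        """25 offsets, +6 to -6 ppm at 0.5 ppm spacing, high-to-low."""
        offsets = tuple(np.round(np.arange(6.0, -6.0 - 1e-9, -0.5), 6))
        return cls(offsets=offsets, includes_s0=True)

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)

    def ascending(self) -> np.ndarray:
        """Offsets sorted from most upfield (-) to most downfield (+)."""
        return np.sort(np.asarray(self.offsets, dtype=float))

    @property
    def positive_offsets(self) -> np.ndarray:
        """Strictly positive offsets that have a matching negative twin."""
        asc = self.ascending()
        pos = asc[asc > 0]
        return np.array([p for p in pos if np.any(np.isclose(asc, -p))])
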