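"""Bloch-McConnell simulation of continuous-wave saturation transfer.

The magnetization of ``n`` exchanging proton pools under continuous-wave
irradiation evolves as a linear time-invariant system

    dM/dt = A M + c,

where M stacks (Mx, My, Mz) for every pool, A holds relaxation, off-resonance
precession, the B1 nutation and the exchange rates, and c carries the
longitudinal recovery terms R1 * M0.  Exchange is modelled between water and
every solute pool (star topology) with detailed balance
``k_water->pool = fraction * k_pool->water``.

Because the pulse is a constant-amplitude block, the evolution over the
saturation time has the exact closed form

    M(t) = M_ss + expm(A t) (M(0) - M_ss),    M_ss = -A^{-1} c,

which is the default solver; a stiff ODE integration (Radau, rtol 1e-8) is
available as an independent route, and ``steady_state_z`` solves the
stationary system directly as a third.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import TWO_PI, AcquisitionSchedule, PoolParams, SaturationParams, ScannerParams
from .spectra import ZSpectrum


def _ordered_pools(pools: tuple[PoolParams, ...] | list[PoolParams]) -> list[PoolParams]:
    pools = list(pools)
    if not pools:
        raise ValueError("at least one pool is required")
    water = [p for p in pools if p.name == "water"]
    if len(water) != 1:
        raise ValueError("exactly one pool named 'water' is required")
    return water + [p for p in pools if p.name != "water"]


def bloch_matrix(pools, sat: SaturationParams, scanner: ScannerParams,
                 offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Evolution operator (A, c) for CW irradiation at ``offset`` ppm.

    Pool ordering in the state vector is water first, then the solute pools
    in input order; per pool the components are (Mx, My, Mz) in the frame
    rotating at the irradiation frequency, with B1 along x.
    """
    pools = _ordered_pools(pools)
    n = len(pools)
    omega1 = sat.omega1(scanner)
    A = np.zeros((3 * n, 3 * n))
    c = np.zeros(3 * n)

    # water <-> pool exchange rates; water loses magnetization to every pool
    k_to_water = np.array([p.exchange_rate for p in pools])
    k_from_water = np.array([p.fraction * p.exchange_rate for p in pools])
    k_from_water[0] = 0.0
    k_to_water[0] = 0.0

    for i, p in enumerate(pools):
        r1, r2 = 1.0 / p.t1, 1.0 / p.t2
        dw = TWO_PI * scanner.ppm_to_hz(p.shift - offset)  # rad/s
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        A[x, x] += -r2
        A[x, y] += dw
        A[y, x] += -dw
        A[y, y] += -r2
        A[y, z] += omega1
        A[z, y] += -omega1
        A[z, z] += -r1
        c[z] += r1 * p.fraction
        if i == 0:
            loss = float(np.sum(k_from_water))
            for comp in (x, y, z):
                A[comp, comp] -= loss
            for j in range(1, n):
                for d in range(3):
                    A[3 * 0 + d, 3 * j + d] += k_to_water[j]
        else:
            for comp in (x, y, z):
                A[comp, comp] -= k_to_water[i]
            for d in range(3):
                A[3 * i + d, 3 * 0 + d] += k_from_water[i]
    return A, c


def equilibrium(pools) -> np.ndarray:
    """Thermal-equilibrium state vector (Mz = fraction for every pool)."""
    pools = _ordered_pools(pools)
    m = np.zeros(3 * len(pools))
    m[2::3] = [p.fraction for p in pools]
    return m


def steady_state_z(pools, sat: SaturationParams, scanner: ScannerParams,
                   offset: float) -> float:
    """Normalized water Mz of the stationary system (direct linear solve).

    Independent of the time-evolution solvers: solves A M = -c.
    """
    A, c = bloch_matrix(pools, sat, scanner, offset)
    m = np.linalg.solve(A, -c)
    return float(m[2])


def evolve_z(pools, sat: SaturationParams, scanner: ScannerParams,
             offset: float, method: str = "expm") -> float:
    """Normalized water Mz after the saturation pulse at ``offset`` ppm."""
    if sat.duration == 0:
        return 1.0
    A, c = bloch_matrix(pools, sat, scanner, offset)
    m0 = equilibrium(pools)
    if method == "expm":
        m_ss = np.linalg.solve(A, -c)
        m = m_ss + expm(A * sat.duration) @ (m0 - m_ss)
    elif method == "ivp":
        sol = solve_ivp(lambda t, y: A @ y + c, (0.0, sat.duration), m0,
                        method="Radau", rtol=1e-8, atol=1e-10,
                        jac=lambda t, y: A)
        if not sol.success:
            raise RuntimeError(f"integration failed at offset {offset} ppm: "
                               f"{sol.message}")
        m = sol.y[:, -1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(m[2])


@lru_cache(maxsize=65536)
def _simulate_values(pools: tuple, sat: SaturationParams,
                     scanner: ScannerParams, offsets: tuple,
                     b0_offset: float, method: str) -> tuple:
    values = []
    for i, x in enumerate(offsets):
        try:
            values.append(evolve_z(pools, sat, scanner, x - b0_offset,
                                   method=method))
        except RuntimeError as err:
            raise RuntimeError(f"offset index {i} ({x} ppm): {err}") from err
    return tuple(values)


def simulate_zspectrum(pools, sat: SaturationParams, scanner: ScannerParams,
                       schedule: AcquisitionSchedule, b0_offset: float = 0.0,
                       method: str = "expm") -> ZSpectrum:
    """Simulate the z-spectrum S_sat/S_0 over an acquisition schedule.

    ``b0_offset`` (ppm) shifts the local water resonance: the spectrum
    recorded at nominal offset x then reflects irradiation at x - b0_offset
    relative to water, so the direct-saturation minimum appears at
    x = b0_offset.  Results are cached on the (hashable) parameter set.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    pools = tuple(_ordered_pools(pools))
    values = _simulate_values(pools, sat, scanner, schedule.offsets,
                              float(b0_offset), method)
    return ZSpectrum(np.asarray(schedule.offsets), np.asarray(values),
                     state="raw")


def simulate_mtr_asym(pools, sat: SaturationParams, scanner: ScannerParams,
                      offset: float = 3.5, b0_offset: float = 0.0,
                      method: str = "expm") -> float:
    """MTR asymmetry Z(-offset) - Z(+offset) of the simulated spectrum."""
    pools = tuple(_ordered_pools(pools))
    z = _simulate_values(pools, sat, scanner, (-offset, offset),
                         float(b0_offset), method)
    return z[0] - z[1]
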