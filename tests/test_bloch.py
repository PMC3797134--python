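import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptcest import (SaturationParams, ScannerParams, amide_pool,
                     bloch_matrix, simulate_mtr_asym, simulate_zspectrum,
                     steady_state_z, water_pool)
from aptcest.bloch import equilibrium, evolve_z


class TestEvolutionOperator:
    def test_requires_water_pool(self, sat, scanner):
        with pytest.raises(ValueError):
            bloch_matrix([amide_pool()], sat, scanner, 0.0)

    def test_zero_b1_preserves_equilibrium(self, scanner, two_pool):
        sat0 = SaturationParams(b1_amplitude=0.0)
        for offset in (-3.5, 0.0, 2.0):
            assert evolve_z(two_pool, sat0, scanner, offset) == pytest.approx(
                1.0, abs=1e-12)

    def test_far_off_resonance_leaves_water_unsaturated(self, sat, scanner,
                                                        water_only):
        assert evolve_z(water_only, sat, scanner, 100.0) == pytest.approx(
            1.0, abs=1e-3)

    def test_exchange_terms_conserve_total_magnetization(self, sat, scanner,
                                                         tumor_pools):
        """Detailed balance: the pure-exchange part of the operator moves
        magnetization between pools without creating or destroying it, so
        its columns sum to zero component-wise."""
        A, _ = bloch_matrix(tumor_pools, sat, scanner, 1.0)
        no_exchange = tuple(type(p)(p.name, p.t1, p.t2, p.fraction, p.shift, 0.0)
                            for p in tumor_pools)
        A0, _ = bloch_matrix(no_exchange, sat, scanner, 1.0)
        exchange = A - A0
        for comp in range(3):
            cols = exchange[comp::3, comp::3]
            assert np.allclose(cols.sum(axis=0), 0.0, atol=1e-12)

    def test_detailed_balance_rates(self, sat, scanner):
        """k_water->amide = fraction * k_amide->water appears in the
        operator's z-block off-diagonals."""
        pools = (water_pool(), amide_pool(fraction=2e-3, exchange_rate=50.0))
        A, _ = bloch_matrix(pools, sat, scanner, 100.0)
        assert A[5, 2] == pytest.approx(2e-3 * 50.0)  # water -> amide
        assert A[2, 5] == pytest.approx(50.0)  # amide -> water


class TestZSpectrumSimulation:
    def test_zero_duration_gives_unity(self, scanner, schedule, two_pool):
        zs = simulate_zspectrum(two_pool, SaturationParams(duration=0.0),
                                scanner, schedule)
        assert np.allclose(zs.values, 1.0)

    def test_zero_amide_fraction_is_symmetric(self, sat, scanner, schedule):
        pools = (water_pool(), amide_pool(fraction=0.0))
        assert abs(simulate_mtr_asym(pools, sat, scanner, 3.5)) < 1e-6
        zs = simulate_zspectrum(pools, sat, scanner, schedule)
        asym = zs.values[::-1] - zs.values  # mirror about 0 ppm
        assert np.max(np.abs(asym)) < 1e-6

    def test_zero_exchange_reproduces_no_amide_spectrum(self, sat, scanner,
                                                        schedule):
        """With k = 0 the amide pool only adds its (tiny) direct saturation;
        at fraction 0 vs rate 0 the water response matches to high accuracy
        away from the amide resonance."""
        no_amide = simulate_zspectrum((water_pool(),), sat, scanner, schedule)
        no_exchange = simulate_zspectrum(
            (water_pool(), amide_pool(fraction=1e-3, exchange_rate=0.0)),
            sat, scanner, schedule)
        off_amide = np.abs(no_amide.offsets - 3.5) > 1.2
        assert np.allclose(no_amide.values[off_amide],
                           no_exchange.values[off_amide], atol=1e-4)

    @pytest.mark.parametrize("pools_name", ["two_pool", "tumor_pools",
                                            "cord_pools"])
    def test_long_saturation_matches_steady_state_oracle(
            self, pools_name, scanner, schedule, request):
        """Time evolution at 30 s agrees with the independent stationary
        linear solve at every offset."""
        pools = request.getfixturevalue(pools_name)
        sat30 = SaturationParams(duration=30.0)
        zs = simulate_zspectrum(pools, sat30, scanner, schedule)
        ss = np.array([steady_state_z(pools, sat30, scanner, x)
                       for x in zs.offsets])
        assert np.max(np.abs(zs.values - ss)) < 1e-3

    def test_ode_integration_matches_matrix_exponential(self, sat, scanner,
                                                        tumor_pools):
        for offset in (-3.5, 0.5, 3.5):
            z_expm = evolve_z(tumor_pools, sat, scanner, offset, method="expm")
            z_ivp = evolve_z(tumor_pools, sat, scanner, offset, method="ivp")
            assert z_ivp == pytest.approx(z_expm, abs=1e-6)

    @given(b1=st.floats(0.0, 10.0), duration=st.floats(0.0, 10.0),
           fraction=st.floats(0.0, 0.01), rate=st.floats(0.0, 500.0),
           offset=st.floats(-6.0, 6.0))
    @settings(max_examples=60, deadline=None)
    def test_z_magnitude_never_exceeds_equilibrium(self, b1, duration,
                                                   fraction, rate, offset):
        """|Mz| <= M0 for any physical parameter set (short on-resonance
        pulses may transiently invert the magnetization, so the universal
        bound is [-1, 1], not [0, 1])."""
        pools = (water_pool(), amide_pool(fraction=fraction,
                                          exchange_rate=rate))
        sat = SaturationParams(b1_amplitude=b1, duration=duration)
        z = evolve_z(pools, sat, ScannerParams(), offset)
        assert -1.0 - 1e-9 <= z <= 1.0 + 1e-9

    @given(b1=st.floats(0.0, 5.0), fraction=st.floats(0.0, 0.01),
           rate=st.floats(0.0, 500.0), offset=st.floats(-6.0, 6.0))
    @settings(max_examples=60, deadline=None)
    def test_z_in_unit_interval_for_protocol_duration(self, b1, fraction,
                                                      rate, offset):
        """At the protocol's 4 s pulse the nutation transient has decayed
        and Z = S_sat/S_0 lies in [0, 1]."""
        pools = (water_pool(), amide_pool(fraction=fraction,
                                          exchange_rate=rate))
        sat = SaturationParams(b1_amplitude=b1, duration=4.0)
        z = evolve_z(pools, sat, ScannerParams(), offset)
        assert -1e-9 <= z <= 1.0 + 1e-9

    def test_asymmetry_strictly_increasing_in_amide_fraction(self, sat,
                                                             scanner):
        fractions = np.linspace(0.0, 0.01, 9)
        asyms = [simulate_mtr_asym((water_pool(), amide_pool(f)), sat,
                                   scanner, 3.5) for f in fractions]
        assert np.all(np.diff(asyms) > 0)

    def test_simulation_is_deterministic(self, sat, scanner, schedule,
                                         tumor_pools):
        a = simulate_zspectrum(tumor_pools, sat, scanner, schedule,
                               b0_offset=0.123)
        b = simulate_zspectrum(tumor_pools, sat, scanner, schedule,
                               b0_offset=0.123)
        assert np.array_equal(a.values, b.values)

    def test_b0_offset_moves_the_water_minimum(self, sat, scanner, schedule,
                                               tumor_pools):
        zs = simulate_zspectrum(tumor_pools, sat, scanner, schedule,
                                b0_offset=0.5)
        assert zs.offsets[np.argmin(zs.values)] == pytest.approx(0.5)
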