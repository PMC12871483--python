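"""Mode spectrum: amplitudes, rates, mode sums and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vesiclense as v
from vesiclense.errors import (DegenerateSpectrumError, DomainError,
                               InvalidGeometryError)

from conftest import random_membrane
from oracles import (milner_safran_rate, naive_plateau, naive_relative_msd)


class TestRates:
    def test_slowest_mode_matches_milner_safran_limit(self):
        """At equal solvent viscosities, zero tension and zero membrane
        viscosity the rates must equal the classical closed form."""
        p = v.MembraneParams.from_kT(1000.0)
        spec = v.mode_spectrum(p, 200e-9)
        for i, l in enumerate(spec.l_values[:50]):
            ref = milner_safran_rate(p.kappa_tilde, p.eta_out, 200e-9, int(l))
            assert spec.rate[i] == pytest.approx(ref, rel=1e-12)

    def test_l2_relaxation_time_for_stiff_large_vesicle(self):
        """1000 kT, R = 200 nm in room-temperature heavy water: the l=2
        mode relaxes in roughly 816 ns."""
        p = v.MembraneParams.from_kT(1000.0)
        spec = v.mode_spectrum(p, 200e-9)
        tau_ns = 1e9 / spec.rate[0]
        assert tau_ns > 800.0
        assert tau_ns == pytest.approx(816.5, rel=1e-3)

    def test_kappa_scaling_at_zero_tension(self):
        p = v.MembraneParams.from_kT(50.0)
        a = v.mode_spectrum(p, 60e-9)
        b = v.mode_spectrum(p.replace(kappa_tilde=2 * p.kappa_tilde), 60e-9)
        assert np.allclose(b.rate, 2 * a.rate, rtol=1e-13)
        assert np.allclose(b.amp2, a.amp2 / 2, rtol=1e-13)

    def test_rates_scale_as_inverse_radius_cubed(self):
        p = v.MembraneParams.from_kT(50.0)
        a = v.mode_spectrum(p, 50e-9)
        b = v.mode_spectrum(p, 100e-9)
        n = len(a.rate)
        assert np.allclose(b.rate[:n], a.rate[:n] / 8.0, rtol=1e-12)

    def test_rates_increase_with_l_without_tension_or_membrane_viscosity(self):
        spec = v.mode_spectrum(v.MembraneParams.from_kT(30.0), 80e-9)
        assert np.all(np.diff(spec.rate) > 0)

    def test_tension_raises_rates_and_lowers_amplitudes(self):
        p = v.MembraneParams.from_kT(30.0)
        a = v.mode_spectrum(p, 60e-9)
        b = v.mode_spectrum(p.replace(sigma=1e-3), 60e-9)
        assert np.all(b.rate > a.rate)
        assert np.all(b.amp2 < a.amp2)

    def test_membrane_viscosity_slows_rates_but_keeps_amplitudes(self):
        p = v.MembraneParams.from_kT(30.0)
        a = v.mode_spectrum(p, 60e-9)
        b = v.mode_spectrum(p.replace(eta_m=1e-9), 60e-9)
        assert np.all(b.rate < a.rate)
        assert np.allclose(b.amp2, a.amp2, rtol=0, atol=0)

    def test_geometry_errors(self):
        p = v.MembraneParams.from_kT(30.0)
        with pytest.raises(InvalidGeometryError):
            v.mode_spectrum(p, p.delta)
        with pytest.raises(InvalidGeometryError):
            v.mode_spectrum(p, 0.5 * p.delta)


class TestModeSums:
    def test_msd_zero_at_time_zero(self):
        spec = v.mode_spectrum(v.MembraneParams.from_kT(20.0), 50e-9)
        assert v.relative_msd(spec, 0.0) == 0.0

    def test_msd_matches_naive_summation(self):
        """Vectorized mode sum vs term-by-term fsum at 20 kT, R = 50 nm,
        t = 100 ns."""
        p = v.MembraneParams.from_kT(20.0, delta=4e-9)
        spec = v.mode_spectrum(p, 50e-9)
        got = v.relative_msd(spec, 100e-9)
        ref = naive_relative_msd(p, 50e-9, 100e-9)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_plateau_matches_naive_summation(self):
        p = v.MembraneParams.from_kT(20.0, delta=4e-9)
        spec = v.mode_spectrum(p, 50e-9)
        assert v.elastic_plateau(spec) == pytest.approx(
            naive_plateau(p, 50e-9), rel=1e-10)

    def test_mode_sum_oracle_equivalence_on_random_draws(self, rng):
        """Optimized summation equals brute force to < 1e-10 relative on
        100 random parameter draws."""
        for _ in range(100):
            p = random_membrane(rng)
            radius = float(rng.uniform(4 * p.delta, 300e-9))
            t = float(rng.uniform(0.0, 1e-6))
            spec = v.mode_spectrum(p, radius)
            assert v.relative_msd(spec, t) == pytest.approx(
                naive_relative_msd(p, radius, t), rel=1e-10, abs=1e-300)
            assert v.elastic_plateau(spec) == pytest.approx(
                naive_plateau(p, radius), rel=1e-10)

    def test_single_mode_plateau_is_the_saturated_term(self):
        spec = v.mode_spectrum(v.MembraneParams.from_kT(20.0), 50e-9)
        one = spec.truncated(2)
        expected = 5.0 / (4.0 * math.pi) * one.amp2[0]
        assert v.elastic_plateau(one) == pytest.approx(expected, rel=1e-14)

    def test_plateau_halves_when_rigidity_doubles(self):
        p = v.MembraneParams.from_kT(20.0)
        a = v.elastic_plateau(v.mode_spectrum(p, 50e-9))
        b = v.elastic_plateau(v.mode_spectrum(
            p.replace(kappa_tilde=2 * p.kappa_tilde), 50e-9))
        assert b == pytest.approx(a / 2, rel=1e-13)

    def test_negative_time_rejected(self):
        spec = v.mode_spectrum(v.MembraneParams.from_kT(20.0), 50e-9)
        with pytest.raises(DomainError):
            v.relative_msd(spec, -1e-9)

    def test_dimensioned_msd_and_roughness_are_consistent(self):
        """The roughness is half the long-time mean-square displacement
        (as a squared length)."""
        p = v.MembraneParams.from_kT(20.0)
        spec = v.mode_spectrum(p, 50e-9)
        msd_inf = 2.0 * (50e-9)**2 * v.elastic_plateau(spec)
        assert v.roughness(spec)**2 == pytest.approx(msd_inf / 2, rel=1e-12)
        assert v.mean_square_displacement(spec, 1.0) == pytest.approx(
            msd_inf, rel=1e-6)
        assert v.correlation_length(spec, p) == pytest.approx(
            math.sqrt(p.kappa_tilde / p.kT) * v.roughness(spec), rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(kappa_kT=st.floats(5.0, 2000.0),
           radius_nm=st.floats(20.0, 300.0),
           sigma=st.floats(0.0, 5e-3),
           eta_m=st.floats(0.0, 1e-9))
    def test_msd_monotone_and_bounded_by_plateau(self, kappa_kT, radius_nm,
                                                 sigma, eta_m):
        p = v.MembraneParams.from_kT(kappa_kT, sigma=sigma, eta_m=eta_m)
        spec = v.mode_spectrum(p, radius_nm * 1e-9)
        t_long = 30.0 / float(spec.rate[0])   # slowest mode fully relaxed
        t = np.geomspace(1e-11, t_long, 40)
        t = np.insert(t, 0, 0.0)
        msd = v.relative_msd(spec, t)
        plateau = v.elastic_plateau(spec)
        assert np.all(msd >= 0)
        assert np.all(np.diff(msd) >= 0)
        assert np.all(msd <= plateau * (1 + 1e-12))
        assert msd[-1] == pytest.approx(plateau, rel=1e-6)


def test_degenerate_spectrum_guard():
    with pytest.raises(DegenerateSpectrumError):
        v.ModeSpectrum(radius=1e-8, l_values=np.array([3, 4]),
                       amp2=np.ones(2), rate=np.ones(2), l_max=4)
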