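"""Restricted-diffusion series, Kärger exchange and the composite model."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mrcytometry import acquisition as acq
from mrcytometry import forward_models as fm
from mrcytometry.forward_models import (
    CompartmentGeometry,
    TissueParams,
    WaveformGPA,
)


@pytest.fixture(scope="module")
def sphere():
    return CompartmentGeometry("sphere", 7.5)


@pytest.fixture(scope="module")
def disk():
    return CompartmentGeometry("disk", 7.5)


class TestEigenSeries:
    def test_first_roots(self):
        assert fm.neumann_roots("sphere")[0] == pytest.approx(2.0816, abs=1e-3)
        assert fm.neumann_roots("disk")[0] == pytest.approx(1.8412, abs=1e-3)

    def test_roots_interlace_with_pi(self):
        for shape in ("sphere", "disk"):
            r = fm.neumann_roots(shape, 20)
            gaps = np.diff(r)
            assert np.all(gaps > 2.0) and np.all(gaps < 4.0)
            assert gaps[-1] == pytest.approx(math.pi, abs=0.05)

    def test_weights_sum_to_position_variance(self, sphere, disk):
        # sum_k B_k = <x²>: R²/5 for a sphere, R²/4 for a disk
        B_s, _ = fm.gpa_weights(sphere, 60)
        B_d, _ = fm.gpa_weights(disk, 60)
        assert B_s.sum() / sphere.R ** 2 == pytest.approx(0.2, abs=1e-5)
        assert B_d.sum() / disk.R ** 2 == pytest.approx(0.25, abs=1e-5)


class TestRestrictedAttenuation:
    def test_no_diffusion_no_dephasing(self, sphere, protocols):
        wf = acq.make_waveform(protocols[1], 0.8)
        assert fm.gpa_restricted_attenuation(sphere, 0.0, wf) == 1.0

    def test_double_integral_oracle(self, sphere):
        """Recursion equals a direct O(N²) pairwise closed form.

        For piecewise-constant g, each segment pair (i < j) contributes
        g_i g_j (e^{ah}-1)(1-e^{-ah}) e^{-a(j-i)h} / a² and each diagonal
        segment 2 g_i² (ah - 1 + e^{-ah}) / a² — an independent derivation
        path with no recursion.
        """
        rng = np.random.default_rng(3)
        g = rng.normal(size=400)
        g -= g.mean()
        h = 0.05
        idx = np.arange(len(g))
        for a in (0.05, 0.4, 2.0):
            E = math.exp(-a * h)
            c_off = (math.exp(a * h) - 1.0) * (1.0 - E) / a ** 2
            c_diag = 2.0 * (a * h - 1.0 + E) / a ** 2
            M = c_off * np.exp(-a * h * np.abs(idx[:, None] - idx[None, :]))
            np.fill_diagonal(M, c_diag)
            brute = float(g @ M @ g)
            rec = fm._gpa_double_integral(g, h, np.array([a]))[0]
            assert rec == pytest.approx(brute, rel=1e-8)

    def test_murday_cotts_equals_general_integral(self, sphere, protocols):
        for p, b in [(protocols[0], 0.5), (protocols[1], 1.0)]:
            wf = acq.make_waveform(p, b)
            a_int = fm.gpa_restricted_attenuation(sphere, 1.53, wf,
                                                  method="integral")
            a_mc = fm.gpa_restricted_attenuation(sphere, 1.53, wf,
                                                 method="murday_cotts")
            assert a_int == pytest.approx(a_mc, rel=1e-3)

    def test_series_truncation_converged(self, sphere, protocols):
        wf = acq.make_waveform(protocols[1], 1.0)
        a20 = fm.gpa_restricted_attenuation(sphere, 1.53, wf, n_terms=20)
        a40 = fm.gpa_restricted_attenuation(sphere, 1.53, wf, n_terms=40)
        assert abs(a20 - a40) < 1e-6

    def test_attenuation_in_unit_interval_and_decreasing_in_b(
        self, sphere, protocols
    ):
        for p in protocols:
            last = 1.0
            for b in p.b_values[1:]:
                wf = acq.make_waveform(p, b)
                s = fm.gpa_restricted_attenuation(sphere, 1.53, wf)
                assert 0.0 < s <= 1.0
                assert s <= last + 1e-12
                last = s


class TestRestrictedADC:
    def test_small_cell_fully_restricted(self, protocols):
        geom = CompartmentGeometry.from_diameter("sphere", 0.5)
        adc = fm.adc_restricted(geom, 1.53, protocols[1])  # tdiff 30 ms
        assert adc < 1e-3

    def test_high_frequency_free_limit(self, sphere):
        p = acq.DiffusionProtocol("OGSE_cosine", 10, 15, frequency=2000.0)
        adc = fm.adc_restricted(sphere, 1.53, p)
        assert adc > 0.9 * 1.53

    def test_monotone_nonincreasing_in_diffusion_time(self, sphere, protocols):
        ogse, p31, steam = protocols[2], protocols[1], protocols[3]
        adcs = [fm.adc_restricted(sphere, 1.53, p) for p in (ogse, p31, steam)]
        assert adcs[0] >= adcs[1] >= adcs[2]

    def test_bounded_by_free_diffusivity(self, protocols):
        for d in (2.0, 8.0, 15.0, 25.0):
            geom = CompartmentGeometry.from_diameter("sphere", d)
            for p in protocols:
                adc = fm.adc_restricted(geom, 1.53, p)
                assert 0.0 <= adc <= 1.53

    def test_invalid_b_ref(self, sphere, protocols):
        with pytest.raises(ValueError):
            fm.adc_restricted(sphere, 1.53, protocols[0], b_ref=0.0)

    def test_interpolated_cache_matches_exact(self, protocols):
        cache = WaveformGPA(protocols[1])
        for d in (5.0, 10.0, 15.0, 22.0):
            geom = CompartmentGeometry.from_diameter("sphere", d)
            exact = fm.adc_restricted(geom, 1.53, protocols[1])
            fast = cache.adc_restricted(d, 1.53)
            assert fast == pytest.approx(exact, rel=2e-3)


class TestExtracellular:
    def test_values(self):
        assert fm.extracellular_attenuation(0.0, 2.0) == 1.0
        assert fm.extracellular_attenuation(1.0, 2.0) == pytest.approx(
            math.exp(-2), rel=1e-12
        )

    def test_strictly_decreasing(self):
        b = np.linspace(0, 1, 11)
        s = fm.extracellular_attenuation(b, 2.0)
        assert np.all(np.diff(s) < 0)


class TestKarger:
    B = np.array([0.1, 0.2154, 0.4642, 1.0])

    def test_slow_exchange_limit(self):
        mix = 0.6 * np.exp(-self.B * 0.5) + 0.4 * np.exp(-self.B * 2.0)
        k = fm.karger_attenuation(self.B, 30.0, 0.6, 0.5, 2.0, 1e6)
        assert np.max(np.abs(k - mix)) < 1e-4

    def test_fast_exchange_limit(self):
        fast = np.exp(-self.B * (0.6 * 0.5 + 0.4 * 2.0))
        k = fm.karger_attenuation(self.B, 30.0, 0.6, 0.5, 2.0, 1e-4)
        assert np.max(np.abs(k - fast)) < 1e-3

    def test_intermediate_exchange_matches_ode_oracle(self):
        """Direct integration of the coupled two-pool equations."""
        vin, adc_in, dex, tau = 0.6, 0.5, 2.0, 100.0
        tdiff = 30.0
        k1 = 1.0 / tau
        k2 = k1 * vin / (1 - vin)
        for b in self.B:
            q2 = b / tdiff

            def rhs(t, m):
                m1, m2 = m
                return [
                    -q2 * adc_in * m1 - k1 * m1 + k2 * m2,
                    -q2 * dex * m2 - k2 * m2 + k1 * m1,
                ]

            sol = solve_ivp(rhs, (0.0, tdiff), [vin, 1 - vin],
                            rtol=1e-11, atol=1e-13)
            oracle = sol.y[:, -1].sum()
            val = fm.karger_attenuation(float(b), tdiff, vin, adc_in, dex, tau)
            assert val == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("tau", [0.5, 10.0, 100.0, 1e6])
    def test_b0_conservation(self, tau):
        assert fm.karger_attenuation(0.0, 30.0, 0.6, 0.5, 2.0, tau) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_degenerate_pure_intracellular(self):
        out = fm.karger_attenuation(1.0, 30.0, 1.0, 0.5, 2.0, 100.0)
        assert out == pytest.approx(math.exp(-0.5), rel=1e-12)


class TestExchangeRegime:
    def test_short_time_ignores_exchange(self, protocols):
        assert fm.exchange_regime(protocols[2]) == fm.IGNORE_EXCHANGE  # 5 ms

    def test_long_time_includes_exchange(self, protocols):
        assert fm.exchange_regime(protocols[1]) == fm.INCLUDE_EXCHANGE  # 30 ms
        assert fm.exchange_regime(protocols[3]) == fm.INCLUDE_EXCHANGE  # 70 ms

    def test_boundary_ignores_exchange(self, protocols):
        # PGSE 3/11 sits exactly at the 10 ms threshold
        assert acq.effective_diffusion_time(protocols[0]) == 10.0
        assert fm.exchange_regime(protocols[0]) == fm.IGNORE_EXCHANGE


class TestTotalSignal:
    def test_unit_at_b0(self, protocols):
        p = TissueParams(d=15, vin=0.6, f_IVIM=0.1, D_star=20.0)
        for proto in protocols:
            assert fm.total_signal(p, proto, 0.0) == pytest.approx(1.0)

    def test_collapses_to_single_compartments(self, protocols):
        proto = protocols[1]
        wf = acq.make_waveform(proto, 1.0)
        pin = TissueParams(d=15, vin=1.0, Din=1.53)
        sphere = CompartmentGeometry.from_diameter("sphere", 15)
        adc = fm.adc_restricted(sphere, 1.53, proto)
        assert fm.total_signal(pin, proto, 1.0) == pytest.approx(
            math.exp(-adc), rel=1e-9
        )
        pex = TissueParams(d=15, vin=0.0, Dex=2.0)
        assert fm.total_signal(pex, proto, 1.0) == pytest.approx(
            math.exp(-2.0), rel=1e-12
        )

    def test_composition_of_validated_parts(self, protocols):
        proto = protocols[1]
        params = TissueParams(d=15, vin=0.6, Din=1.53, Dex=2.0)
        sphere = CompartmentGeometry.from_diameter("sphere", 15)
        adc = fm.adc_restricted(sphere, 1.53, proto)
        expected = 0.6 * math.exp(-adc) + 0.4 * math.exp(-2.0)
        assert fm.total_signal(params, proto, 1.0) == pytest.approx(
            expected, rel=1e-9
        )

    def test_signal_in_unit_interval_nonincreasing(self, protocols):
        params = TissueParams(d=12, vin=0.5, tau_in=80.0, f_IVIM=0.05)
        for proto in protocols:
            b = np.array(proto.b_values)
            s = fm.total_signal(params, proto, b)
            assert np.all(s > 0) and np.all(s <= 1.0 + 1e-12)
            assert np.all(np.diff(s) <= 1e-12)

    def test_invalid_params_rejected(self, protocols):
        with pytest.raises(ValueError):
            fm.total_signal(TissueParams(d=45, vin=0.5), protocols[0], 0.5)
        with pytest.raises(ValueError):
            fm.total_signal(TissueParams(d=15, vin=1.5), protocols[0], 0.5)
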