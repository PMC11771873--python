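"""Allocation fields, sensory-space transforms and measurement densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from oriadapt import (
    KernelParams,
    StationaryParams,
    adapted_model,
    build_transform,
    control_model,
    stationary_sqrt_fisher,
    total_fisher,
)
from oriadapt._angles import TWO_PI, circular_grid, deg_to_circle, vm_pdf, wrap_circle
from oriadapt.core_model import FisherField, kernel_sqrt_fisher
from oriadapt.decision_model import decision_table, prob_reference_cw
from oriadapt.errors import DegenerateFieldError, ParameterError, VariantMismatchError


def vm_direct(x, mu, kappa):
    """Hand-coded von Mises density, independent of the package helper."""
    return np.exp(kappa * np.cos(x - mu)) / (2 * np.pi * i0(kappa))


class TestStationaryField:
    def test_uniform_limit_k_zero(self):
        field = stationary_sqrt_fisher(StationaryParams(0.0, 2.0, 5.0), 256)
        assert np.allclose(field.sqrt_j, 1.0 / TWO_PI)

    def test_matches_mixture_formula_pointwise(self):
        k, kappa = 0.25, 2.0
        field = stationary_sqrt_fisher(StationaryParams(k, kappa, 5.0), 2048)
        expected_0 = k * vm_direct(0.0, 0.0, kappa) + k * vm_direct(0.0, np.pi, kappa) \
            + (1 - 2 * k) / (2 * np.pi)
        idx0 = np.argmin(np.abs(field.grid))
        assert field.sqrt_j[idx0] == pytest.approx(expected_0, rel=1e-9)

    @pytest.mark.parametrize("k,kappa", [(0.0, 1.0), (0.25, 2.0), (0.5, 8.0), (0.1, 50.0)])
    def test_unit_circular_integral(self, k, kappa):
        field = stationary_sqrt_fisher(StationaryParams(k, kappa, 5.0), 2048)
        assert field.integral() == pytest.approx(1.0, abs=1e-9)

    def test_maxima_at_cardinals(self):
        field = stationary_sqrt_fisher(StationaryParams(0.3, 3.0, 5.0), 2048)
        assert np.abs(field.grid[np.argmax(field.sqrt_j)]) < TWO_PI / 2048 + 1e-12 or \
            np.abs(np.abs(field.grid[np.argmax(field.sqrt_j)]) - np.pi) < TWO_PI / 2048

    @pytest.mark.parametrize("bad", [dict(k=-0.1, kappa=1, kappa_i=1),
                                     dict(k=0.6, kappa=1, kappa_i=1),
                                     dict(k=0.2, kappa=0.0, kappa_i=1),
                                     dict(k=0.2, kappa=1, kappa_i=-2)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            StationaryParams(**bad)

    def test_small_grid_rejected(self):
        with pytest.raises(ParameterError):
            stationary_sqrt_fisher(StationaryParams(0.2, 2.0, 5.0), 32)


class TestTransform:
    def test_uniform_field_gives_identity(self):
        field = stationary_sqrt_fisher(StationaryParams(0.0, 1.0, 5.0), 512)
        F = build_transform(field)
        theta = np.linspace(-3, 3, 41)
        assert np.allclose(F.forward(theta), theta, atol=TWO_PI / 512)

    def test_symmetric_field_fixes_zero(self):
        field = stationary_sqrt_fisher(StationaryParams(0.3, 3.0, 5.0), 1024)
        F = build_transform(field)
        assert abs(float(F.forward(0.0))) < 1e-10

    def test_against_fine_quadrature_oracle(self):
        params = StationaryParams(0.27, 4.0, 5.0)
        F = build_transform(stationary_sqrt_fisher(params, 2048))
        # oracle: trapezoid cumulative at 10x resolution of the analytic mixture
        fine = circular_grid(20480)
        vals = (params.k * vm_direct(fine, 0.0, params.kappa)
                + params.k * vm_direct(fine, np.pi, params.kappa)
                + (1 - 2 * params.k) / (2 * np.pi))
        h = TWO_PI / fine.size
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * h)])
        total = cum[-1] + 0.5 * (vals[-1] + vals[0]) * h
        idx = np.arange(0, fine.size, 660)  # exact fine-grid evaluation points
        for i in idx:
            oracle = -np.pi + TWO_PI * cum[i] / total
            assert abs(float(F.forward(fine[i])) - oracle) < 1e-4

    def test_monotone_and_roundtrip(self):
        field = stationary_sqrt_fisher(StationaryParams(0.4, 6.0, 5.0), 2048)
        F = build_transform(field)
        assert np.all(np.diff(F.y) > 0)
        theta = np.linspace(-np.pi, np.pi, 513)[:-1]
        back = F.inverse(F.forward(theta))
        assert np.max(np.abs(wrap_circle(back - theta))) < TWO_PI / 2048

    def test_degenerate_field_rejected(self):
        grid = circular_grid(256)
        bad = FisherField(grid=grid, sqrt_j=np.where(grid > 0, 1.0, 0.0))
        with pytest.raises(DegenerateFieldError):
            build_transform(bad)


class TestAdaptedModel:
    def test_flat_kernel_reduces_to_control(self, stationary):
        flat = KernelParams(variant="two_peak", k1=0.0, k2=0.0, kappa1=1.0, kappa2=1.0)
        ctrl = control_model(stationary)
        ad = adapted_model(stationary, flat, 45.0)
        tab_c = decision_table(ctrl)
        tab_a = decision_table(ad)
        for t in (0.0, 22.5, 45.0, 80.0):
            for r in (t - 6.0, t + 2.0, t + 9.0):
                pc = prob_reference_cw(ctrl, t, r, table=tab_c)
                pa = prob_reference_cw(ad, t, r, table=tab_a)
                assert pa == pytest.approx(pc, abs=1e-6)

    def test_kernel_mode_at_adaptor(self, stationary, two_peak_kernel):
        ad = adapted_model(stationary, two_peak_kernel, 45.0)
        field = ad.field_sensory
        mode = field.grid[np.argmax(field.sqrt_j)]
        assert abs(wrap_circle(mode - ad.adaptor_sensory)) <= TWO_PI / field.n + 1e-12

    def test_shift_equivariance_across_adaptors(self, stationary, two_peak_kernel):
        """The isomorphism assumption: one kernel shape, recentered per adaptor."""
        m45 = adapted_model(stationary, two_peak_kernel, 45.0)
        m22 = adapted_model(stationary, two_peak_kernel, 22.5)
        shift = m45.adaptor_sensory - m22.adaptor_sensory
        # compare on the grid: J_a(45) shifted back should equal J_a(22.5)
        grid = m22.field_sensory.grid
        shifted = m45.field_sensory(grid + shift)
        assert np.max(np.abs(shifted - m22.field_sensory.sqrt_j)) < 1e-4

    def test_one_peak_with_second_peak_rejected(self):
        with pytest.raises(VariantMismatchError):
            KernelParams(variant="one_peak", k1=0.3, k2=0.1, kappa1=2.0, kappa2=2.0)

    def test_kernel_density_integrates_to_one(self, two_peak_kernel):
        field = kernel_sqrt_fisher(two_peak_kernel, 0.7, 1024)
        assert field.integral() == pytest.approx(1.0, abs=1e-9)

    def test_kernel_without_adaptor_rejected(self, stationary, two_peak_kernel):
        from oriadapt.core_model import ObserverModel
        with pytest.raises(ParameterError):
            ObserverModel(stationary, kernel=two_peak_kernel)


class TestMeasurementDensity:
    def test_flat_allocation_gives_plain_von_mises(self):
        model = control_model(StationaryParams(0.0, 1.0, 8.0))
        md = model.measurement_density(30.0)
        expected = vm_direct(md.grid, float(deg_to_circle(30.0)), 8.0)
        assert np.max(np.abs(md.density - expected)) < 1e-6

    @pytest.mark.parametrize("theta_deg", [0.0, 30.0, -60.0])
    def test_integrates_to_one(self, stationary, two_peak_kernel, theta_deg):
        for model in (control_model(stationary),
                      adapted_model(stationary, two_peak_kernel, 45.0)):
            assert model.measurement_density(theta_deg).integral() == \
                pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo_histogram(self, rng):
        """Total-variation distance to 1e6 sampled measurements below 1%."""
        model = control_model(StationaryParams(0.3, 3.0, 8.0))
        md = model.measurement_density(30.0)
        samples = model.sample_measurements(30.0, 1_000_000, rng)
        edges = np.linspace(-np.pi, np.pi, 181)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.interp(centers, md.grid, md.density, period=TWO_PI)
        tv = 0.5 * np.sum(np.abs(hist - dens)) * (edges[1] - edges[0])
        assert tv < 0.01


class TestTotalFisher:
    def test_fixed_resource_across_adaptation(self, stationary, two_peak_kernel):
        assert total_fisher(control_model(stationary)) == \
            pytest.approx(total_fisher(adapted_model(stationary, two_peak_kernel, 45.0)))

    def test_monotone_in_kappa_i(self):
        lo = total_fisher(control_model(StationaryParams(0.2, 2.0, 4.0)))
        hi = total_fisher(control_model(StationaryParams(0.2, 2.0, 8.0)))
        assert hi > lo

    def test_bessel_ratio_oracle(self):
        model = control_model(StationaryParams(0.2, 2.0, 8.0))
        expected = 8.0 * i1(8.0) / i0(8.0) * (2 * np.pi) ** 2
        assert total_fisher(model) == pytest.approx(expected, rel=1e-12)


class TestAngleConventions:
    @given(st.floats(min_value=-90.0, max_value=89.999))
    @settings(max_examples=50, deadline=None)
    def test_degree_circle_roundtrip(self, d):
        from oriadapt._angles import circle_to_deg
        assert circle_to_deg(deg_to_circle(d)) == pytest.approx(d, abs=1e-9)

    def test_cardinals_map_to_zero_and_pi(self):
        assert float(deg_to_circle(0.0)) == 0.0
        assert abs(float(deg_to_circle(-90.0))) == pytest.approx(np.pi)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_vm_pdf_normalized(self, kappa):
        grid = circular_grid(2048)
        assert np.mean(vm_pdf(grid, 0.3, kappa)) * TWO_PI == pytest.approx(1.0, abs=1e-6)
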