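import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from purkinje_ca import CellGeometry, CytosolGrid, SRState
from purkinje_ca.transport import (
    DiffusionParams,
    SercaParams,
    diffusion_step,
    longitudinal_dt_max,
    nsr_jsr_transfer,
    serca_uptake,
)


class TestDiffusion:
    def test_uniform_field_unchanged(self, small_geometry):
        grid = CytosolGrid(small_geometry, ca=np.full((4, 21), 0.7))
        out = diffusion_step(grid, DiffusionParams(), 0.02)
        assert np.allclose(out.ca, 0.7, rtol=1e-12)

    def test_mass_conserved(self, small_geometry, rng):
        ca = rng.uniform(0.0, 10.0, size=(4, 21))
        grid = CytosolGrid(small_geometry, ca=ca)
        before = grid.total_mass()
        out = grid
        for _ in range(50):
            out = diffusion_step(out, DiffusionParams(), 0.02)
        assert out.total_mass() == pytest.approx(before, rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_mass_conserved_property(self, seed):
        g = CellGeometry(n_discs=3, n_layers=11)
        ca = np.random.default_rng(seed).uniform(0.0, 5.0, size=(3, 11))
        grid = CytosolGrid(g, ca=ca)
        out = diffusion_step(grid, DiffusionParams(), 0.05)
        assert out.total_mass() == pytest.approx(grid.total_mass(), rel=1e-9)
        assert (out.ca >= -1e-12).all()

    def test_stability_error_names_bound(self, small_geometry):
        grid = CytosolGrid(small_geometry)
        params = DiffusionParams(d_radial=0.5)
        dt_max = longitudinal_dt_max(small_geometry, params)
        with pytest.raises(ValueError, match="maximum admissible dt"):
            diffusion_step(grid, params, dt_max * 1.01)

    def test_radial_profile_matches_analytic_kernel(self):
        """Point release at the core vs. the 2-D (axisymmetric) heat kernel.

        A mass M released at r=0 in a long cylinder spreads radially as
        c(r,t) = M / (4πDt·h) · exp(-r²/4Dt) while the front is far from
        the wall; checked at three radii and two times on a fine grid.
        """
        g = CellGeometry(length=10.0, diameter=8.0, n_discs=2, n_layers=161)
        D = 0.2
        params = DiffusionParams(d_radial=D, d_longitudinal=1e-9)
        ca = np.zeros((2, 161))
        mass = 50.0  # µM·µm³ per disc, deposited in the innermost shell
        ca[:, 0] = mass / g.layer_volumes[0, 0]
        grid = CytosolGrid(g, ca=ca)
        dt = 0.01
        h = g.disc_height
        r_centers = 0.5 * (g.radial_edges[:-1] + g.radial_edges[1:])
        checked = 0
        t = 0.0
        for t_target in (0.6, 1.2):
            while t < t_target - 1e-9:
                grid = diffusion_step(grid, params, dt)
                t += dt
            for r in (0.4, 0.8, 1.2):
                k = int(np.argmin(np.abs(r_centers - r)))
                analytic = mass / (4 * np.pi * D * t * h) * np.exp(
                    -r_centers[k] ** 2 / (4 * D * t)
                )
                assert grid.ca[0, k] == pytest.approx(analytic, rel=0.02)
                checked += 1
        assert checked == 6

    def test_anisotropy_default_ratio(self):
        p = DiffusionParams(d_radial=0.5)
        assert p.d_longitudinal == pytest.approx(0.35)


class TestSerca:
    def test_zero_calcium_zero_uptake(self, small_geometry):
        grid = CytosolGrid(small_geometry, ca=np.zeros((4, 21)))
        sr = SRState(small_geometry)
        up = serca_uptake(grid, sr, SercaParams())
        assert np.all(up == 0.0)

    def test_modifier_scales_linearly(self, small_geometry):
        grid = CytosolGrid(small_geometry, ca=np.full((4, 21), 0.8))
        sr = SRState(small_geometry)
        base = serca_uptake(grid, sr, SercaParams())
        iso = serca_uptake(grid, sr, SercaParams().scaled(1.2))
        assert np.allclose(iso, 1.2 * base)

    def test_half_activation_at_km(self, small_geometry):
        p = SercaParams(vmax=10.0, km=0.5, hill=2.0)
        grid = CytosolGrid(small_geometry, ca=np.full((4, 21), p.km))
        sr = SRState(small_geometry)
        up = serca_uptake(grid, sr, p)
        assert np.allclose(up, 0.5 * p.vmax)


class TestNsrJsrTransfer:
    def test_equal_concentrations_no_transfer(self, small_geometry):
        sr = SRState(small_geometry, ca_jsr=np.full(4, 500.0), ca_nsr=np.full(4, 500.0))
        out = nsr_jsr_transfer(sr, 1.0, tau_tr=50.0)
        assert np.allclose(out.ca_jsr, 500.0)
        assert np.allclose(out.ca_nsr, 500.0)

    def test_relaxation_after_five_time_constants(self, small_geometry):
        sr = SRState(small_geometry, ca_jsr=np.full(4, 100.0), ca_nsr=np.full(4, 600.0))
        tau = 50.0
        out = nsr_jsr_transfer(sr, 5 * tau, tau_tr=tau)
        gap0 = 500.0
        gap = float(np.abs(out.ca_nsr - out.ca_jsr).max())
        assert gap < 0.01 * gap0

    def test_mass_conserved(self, small_geometry):
        sr = SRState(small_geometry, ca_jsr=np.full(4, 100.0), ca_nsr=np.full(4, 600.0))
        out = nsr_jsr_transfer(sr, 13.0, tau_tr=40.0)
        assert out.total_mass() == pytest.approx(sr.total_mass(), rel=1e-9)
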