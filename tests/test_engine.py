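import numpy as np
import pytest

from purkinje_ca import IonicParams, LeakParams, Model, RyRParams, simulate
from purkinje_ca.engine import default_initial_state
from purkinje_ca.transport import SercaParams


def total_ca_mass(state, geometry):
    cyto = float((state.ca * geometry.layer_volumes).sum())
    sr = float(state.ca_jsr.sum() * geometry.jsr_volume + state.ca_nsr.sum() * geometry.nsr_volume)
    return cyto + sr


def no_sarcolemmal_flux_model(**kw):
    base = dict(IonicParams().base)
    for k in ("g_cal", "g_cat", "g_cab", "k_ncx"):
        base[k] = 0.0
    return Model(ionic=IonicParams(base=base), **kw)


class TestReproducibility:
    def test_bit_identical_for_same_seed(self):
        m = Model(leak=LeakParams(enabled=True))
        tr1, s1 = simulate(m, 600.0, np.array([50.0]), seed=42)
        tr2, s2 = simulate(m, 600.0, np.array([50.0]), seed=42)
        assert np.array_equal(tr1.v, tr2.v)
        assert np.array_equal(tr1.ryr_flux, tr2.ryr_flux)
        assert np.array_equal(s1.ca, s2.ca)
        assert s1.v == s2.v

    def test_different_seed_differs(self):
        m = Model()
        tr1, _ = simulate(m, 600.0, np.array([50.0]), seed=1)
        tr2, _ = simulate(m, 600.0, np.array([50.0]), seed=2)
        assert not np.array_equal(tr1.ryr_flux, tr2.ryr_flux)

    def test_metadata_recorded(self):
        m = Model()
        tr, _ = simulate(m, 100.0, np.array([]), seed=9)
        assert tr.seed == 9
        assert tr.config_hash == m.config_hash()
        assert len(tr.config_hash) == 16


class TestConservation:
    def test_total_ca_constant_without_sarcolemmal_fluxes(self):
        """With all sarcolemmal Ca pathways off, total Ca (cytosol + JSR +
        NSR, volume weighted) drifts < 0.1% over 1 s."""
        m = no_sarcolemmal_flux_model()
        st0 = default_initial_state(m)
        before = total_ca_mass(st0, m.geometry)
        _, st = simulate(m, 1000.0, np.array([50.0]), seed=3, initial_state=st0)
        after = total_ca_mass(st, m.geometry)
        assert abs(after - before) / before < 1e-3


class TestSymmetry:
    def test_mirror_symmetric_evolution(self):
        """Deterministic transport preserves mirror symmetry along the cell."""
        m = no_sarcolemmal_flux_model(
            ryr=RyRParams(g_rel=0.0, k_open=1e-12),
            serca=SercaParams(vmax=0.0),
            g_sr_leak=0.0,
        )
        st = default_initial_state(m)
        nd = m.geometry.n_discs
        profile = np.linspace(1.0, 2.0, nd // 2)
        st.ca[: nd // 2, :] = profile[:, None]
        st.ca[nd // 2 :, :] = profile[::-1][:, None]
        _, out = simulate(m, 200.0, np.array([]), seed=5, initial_state=st)
        assert np.allclose(out.ca, out.ca[::-1, :], rtol=1e-10)


class TestChargeMassConsistency:
    def _run(self, t_total, stim):
        from purkinje_ca.currents import F_FARADAY, RTF
        from purkinje_ca.engine import NumericParams

        m = Model(
            ryr=RyRParams(g_rel=0.0, k_open=1e-12),
            serca=SercaParams(vmax=0.0),
            g_sr_leak=0.0,
            numeric=NumericParams(rec_dt=0.02),
        )
        st0 = default_initial_state(m)
        cyto0 = float((st0.ca * m.geometry.layer_volumes).sum())
        tr, st = simulate(m, t_total, stim, seed=1, initial_state=st0)
        cyto1 = float((st.ca * m.geometry.layer_volumes).sum())
        c = m.geometry.capacitance_pF
        # background Ca current reconstructed algebraically from V and sub-SL Ca
        g_cab = m.ionic.effective("g_cab")
        e_ca = 0.5 * RTF * np.log(1.8 / np.maximum(tr.ca_subsl * 1e-3, 1e-9))
        i_cab = g_cab * (tr.v - e_ca)
        # NCX carries one net charge per Ca ion; CaL/CaT/Cab carry two
        flux = c * 1e6 * (
            -(tr.i_cal + tr.i_cat + i_cab) / (2 * F_FARADAY) + tr.i_ncx / F_FARADAY
        )
        # left-Riemann sum matches the engine's forward-Euler deposition
        integral = float(np.sum(flux[:-1]) * tr.dt_rec)
        delivered = cyto1 - cyto0
        return integral, delivered

    def test_quiescent_bookkeeping_exact(self):
        """Without stimuli the current integral matches the deposited mass
        to < 0.5% (charge ↔ mass consistency)."""
        integral, delivered = self._run(400.0, np.array([]))
        scale = max(abs(integral), abs(delivered))
        assert abs(integral - delivered) / scale < 0.005

    def test_action_potential_bookkeeping(self):
        """With an AP the recorded-sample integral still matches the mass to
        a few %, limited only by the 0.02 ms sampling of the upstroke."""
        integral, delivered = self._run(400.0, np.array([50.0]))
        scale = max(abs(integral), abs(delivered))
        assert abs(integral - delivered) / scale < 0.03


class TestRestingStability:
    def test_quiescent_membrane_is_stable(self):
        """Without stimuli (and with stochastic release silenced) the
        membrane settles and dV/dt stays below 0.01 mV/ms."""
        m = Model(ryr=RyRParams(k_open=1e-12), leak=LeakParams(enabled=False))
        _, st = simulate(m, 5000.0, np.array([]), seed=1)
        tr, _ = simulate(m, 5000.0, np.array([]), seed=2, initial_state=st)
        dvdt = np.abs(np.diff(tr.v) / tr.dt_rec)
        assert dvdt[len(dvdt) // 2 :].max() < 0.01


class TestErrorHandling:
    def test_blowup_aborts_with_diagnostic(self):
        bad = IonicParams()
        bad.base["g_na"] = 1e8  # absurd conductance: guaranteed overflow
        with pytest.raises(FloatingPointError, match="blow-up"):
            simulate(Model(ionic=bad), 2000.0, np.array([50.0]), seed=1)
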