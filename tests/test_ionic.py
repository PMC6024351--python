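"""Cell-model unit and property tests: rest stability, Rush–Larsen
correctness, hypoxic current properties, pacing and APD measurement."""

import math

import numpy as np
import pytest

from cardiomaze import ionic, kernels
from cardiomaze.errors import (ConfigurationError, DomainError,
                               MeasurementError, NumericalStateError)


class TestRestingStability:
    @pytest.mark.parametrize("atp", [2.0, 3.5, 6.0])
    def test_unstimulated_rest_drifts_below_1mV_over_1s(self, atp, cell_params):
        rest = ionic.resting_state(atp, cell_params, equilibrate_ms=1000.0)
        y = kernels.integrate_cell(rest.as_vector(), atp, cell_params,
                                   0.02, 50_000)
        assert abs(y[0] - rest.V) < 1.0

    def test_reference_integrator_rest_fixed_point(self, cell_params):
        state = ionic.resting_state(6.0, cell_params, equilibrate_ms=1000.0)
        v0 = state.V
        for _ in range(2000):  # 40 ms through the readable path
            state = ionic.step_cell(state, 0.02, 0.0, cell_params)
        assert abs(state.V - v0) < 0.05

    def test_net_current_near_zero_at_rest_and_outward_under_hypoxia(
            self, cell_params):
        rest6 = ionic.resting_state(6.0, cell_params, equilibrate_ms=1000.0)
        i6 = ionic.total_ionic_current(rest6, cell_params)
        assert abs(i6) < 0.5
        hyp = ionic.CellState(V=rest6.V, gates=rest6.gates.copy(),
                              concentrations=rest6.concentrations.copy(),
                              atp=2.0)
        i2 = ionic.total_ionic_current(hyp, cell_params)
        assert i2 > i6  # K(ATP) activation makes the net current more outward

    def test_component_currents_retrievable(self, cell_params):
        rest = ionic.resting_state(6.0, cell_params)
        cur = ionic.ionic_currents(rest, cell_params)
        names = ["INa", "IK1", "Ito", "IKr", "IKs", "ICaL", "INaCa", "INaK",
                 "IpCa", "IpK", "IbCa", "IbNa", "IKatp"]
        assert math.isclose(sum(cur[n] for n in names), cur["Itot"],
                            rel_tol=1e-12, abs_tol=1e-12)


class TestRushLarsen:
    def test_single_step_matches_exact_exponential_relaxation(self, cell_params):
        state = ionic.resting_state(6.0, cell_params)
        dt = 0.02
        inf, tau = ionic.gate_rates(state.V, state.conc("CaSS"),
                                    state.conc("CaSR"), cell_params)
        expected = inf + (state.gates - inf) * np.exp(-dt / tau)
        stepped = ionic.step_cell(state, dt, 0.0, cell_params)
        np.testing.assert_allclose(stepped.gates, expected, rtol=1e-12,
                                   atol=1e-15)

    def test_gates_stay_in_unit_interval_through_an_AP(self, cell_params):
        state = ionic.resting_state(2.0, cell_params, equilibrate_ms=500.0)
        for k in range(2500):  # 50 ms, stimulated for 2 ms
            istim = 40.0 if k * 0.02 < 2.0 else 0.0
            state = ionic.step_cell(state, 0.02, istim, cell_params)
            assert np.all(state.gates >= 0.0) and np.all(state.gates <= 1.0)

    def test_kernel_agrees_with_reference_integrator(self, cell_params):
        """Table-driven production path vs exact-formula path over one AP."""
        dt = 0.02
        rest = ionic.resting_state(2.0, cell_params, equilibrate_ms=500.0)
        state = rest
        ref = []
        n = int(80 / dt)
        for k in range(n):
            istim = 40.0 if k * dt < 2.0 else 0.0
            state = ionic.step_cell(state, dt, istim, cell_params)
            if k % 50 == 0:
                ref.append(state.V)
        _, v = kernels.integrate_cell_trace(
            rest.as_vector(), 2.0, cell_params, dt, n,
            stim_amplitude=40.0, stim_duration=2.0, sample_every=50)
        assert np.max(np.abs(np.array(ref) - v[:len(ref)])) < 0.05

    def test_determinism_bit_identical(self, cell_params):
        rest = ionic.resting_state(4.0, cell_params)
        y1 = kernels.integrate_cell(rest.as_vector(), 4.0, cell_params,
                                    0.02, 5000, stim_amplitude=40.0,
                                    stim_duration=2.0)
        y2 = kernels.integrate_cell(rest.as_vector(), 4.0, cell_params,
                                    0.02, 5000, stim_amplitude=40.0,
                                    stim_duration=2.0)
        assert np.array_equal(y1, y2)


class TestHypoxicCurrents:
    def test_ikatp_zero_at_nernst_potential(self, cell_params):
        ek = ionic.RTONF * math.log(cell_params.Ko / 138.3)
        assert ionic.ikatp_current(ek, 2.0, params=cell_params, EK=ek) == 0.0

    def test_ikatp_outward_above_ek_and_monotone_in_atp(self, cell_params):
        ek = -86.0
        vals = [ionic.ikatp_current(-20.0, atp, params=cell_params, EK=ek)
                for atp in (2.0, 3.0, 4.0, 5.0, 6.0)]
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ikatp_vanishes_at_saturating_atp(self, cell_params):
        assert ionic.ikatp_current(-20.0, 1e6, params=cell_params,
                                   EK=-86.0) == pytest.approx(0.0, abs=1e-12)

    def test_ikatp_domain_error(self, cell_params):
        with pytest.raises(DomainError):
            ionic.ikatp_current(-20.0, 0.0, params=cell_params)

    def test_ical_factor_monotone_bounded_saturating(self, cell_params):
        f = [ionic.ical_atp_factor(a, cell_params)
             for a in (2.0, 3.0, 4.0, 5.0, 6.0, 1e6)]
        assert all(0.0 < x <= 1.0 for x in f)
        assert all(a <= b for a, b in zip(f, f[1:]))
        assert f[-1] == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(DomainError):
            ionic.ical_atp_factor(-1.0, cell_params)


class TestPacingAndAPD:
    def test_apd_strictly_increases_with_atp(self, apd_table):
        levels = sorted(apd_table)
        vals = [apd_table[a] for a in levels]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_normoxic_ap_has_long_plateau_hypoxic_is_abbreviated(self, apd_table):
        assert apd_table[6.0] > 200.0
        assert apd_table[2.0] < 40.0

    def test_zero_amplitude_stimulus_flags_capture_failure(self, cell_params):
        trace = ionic.run_paced_cell(6.0, n_beats=1, stim_amplitude=0.0,
                                     params=cell_params)
        assert not trace.captured
        with pytest.raises(MeasurementError):
            ionic.measure_apd(trace)

    def test_measure_apd_on_synthetic_triangle(self):
        # instant rise at t=0 from -85 to +35, linear fall hitting 90 %
        # repolarization (-73 mV) exactly at t = 100
        t = np.array([-1.0, 0.0, 0.5, 100.0, 150.0])
        v = np.array([-85.0, -85.0, 35.0, -73.0, -85.0])
        tr = ionic.APTrace(times=t, voltages=v)
        apd = ionic.measure_apd(tr, 0.9)
        assert apd == pytest.approx(100.0, abs=1.0)

    def test_measure_apd_fraction_validation(self):
        tr = ionic.APTrace(times=np.array([0.0, 1.0, 2.0]),
                           voltages=np.array([-85.0, 30.0, -85.0]))
        with pytest.raises(DomainError):
            ionic.measure_apd(tr, 1.5)

    def test_paced_trace_metadata_and_export(self, tmp_path, cell_params):
        tr = ionic.run_paced_cell(4.0, n_beats=1, stim_amplitude=40.0,
                                  params=cell_params)
        assert tr.cycle_length == 1000.0 and tr.atp == 4.0
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        body = path.read_text().splitlines()
        assert body[0].startswith("#") and "atp_mM=4.0" in body[0]
        assert body[1] == "time_ms,V_mV"


class TestValidation:
    def test_gate_out_of_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            ionic.CellState(V=-86.0, gates=np.full(13, 1.5),
                            concentrations=np.ones(5), atp=6.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            ionic.CellState(V=-86.0, gates=np.full(13, 0.5),
                            concentrations=np.array([1.0, 1.0, -1.0, 1.0, 1.0]),
                            atp=6.0)

    def test_unsupported_atp_rejected(self):
        with pytest.raises(ConfigurationError):
            ionic.CellState(V=-86.0, gates=np.full(13, 0.5),
                            concentrations=np.ones(5), atp=1.0)

    def test_nonfinite_state_raises_numerical_state_error(self):
        with pytest.raises(NumericalStateError):
            ionic.CellState(V=float("nan"), gates=np.full(13, 0.5),
                            concentrations=np.ones(5), atp=6.0)

    def test_nonpositive_dt_rejected(self, cell_params):
        state = ionic.resting_state(6.0, cell_params)
        with pytest.raises(DomainError):
            ionic.step_cell(state, 0.0, 0.0, cell_params)
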