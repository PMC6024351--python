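"""Monodomain solver: operator assembly, conservation/symmetry, operator
splitting, wave propagation and conduction-velocity measurement."""

import numpy as np
import pytest

from cardiomaze import ionic
from cardiomaze.errors import (ConfigurationError, DomainError,
                               MeasurementError)
from cardiomaze.geometry import FibrosisField, make_slab, sample_fibrosis
from cardiomaze.solver import (MonodomainParams, StimulusProtocol, TissueState,
                               advance_tissue, build_diffusion_operator,
                               measure_cv, planar_wave_cv, run_simulation,
                               wavelength)

from oracles import dense_face_laplacian


def full_field(geo):
    return FibrosisField(geometry=geo,
                         conductive=np.ones(geo.shape, bool), phi=0.0)


class TestDiffusionOperator:
    def test_single_cell_is_zero_operator(self, mono_params):
        geo = make_slab(0.01, 0.01, 1)
        op = build_diffusion_operator(full_field(geo), mono_params)
        assert op.matrix.shape == (1, 1)
        assert op.matrix.nnz == 0 or op.matrix.toarray()[0, 0] == 0.0

    def test_two_adjacent_cells_closed_form(self, mono_params):
        geo = make_slab(0.02, 0.01, 1)
        op = build_diffusion_operator(full_field(geo), mono_params)
        c = mono_params.sigma / mono_params.h ** 2
        np.testing.assert_allclose(op.matrix.toarray(),
                                   [[-c, c], [c, -c]])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_assembly_on_random_masks(self, seed,
                                                          mono_params):
        geo = make_slab(0.04, 0.04, 1, injured="all")
        fld = sample_fibrosis(geo, 0.4, seed=seed)
        op = build_diffusion_operator(fld, mono_params)
        dense = dense_face_laplacian(fld.conductive,
                                     mono_params.sigma / mono_params.h ** 2)
        np.testing.assert_allclose(op.matrix.toarray(), dense)

    def test_rows_sum_to_zero_and_symmetry(self, mono_params):
        geo = make_slab(0.05, 0.05, 3, injured="all")
        fld = sample_fibrosis(geo, 0.35, seed=9)
        m = build_diffusion_operator(fld, mono_params).matrix
        assert np.max(np.abs(m.sum(axis=1))) < 1e-9
        assert (m - m.T).nnz == 0 or np.max(np.abs((m - m.T).data)) < 1e-12

    def test_mismatched_h_rejected(self, mono_params):
        geo = make_slab(0.05, 0.05, 1, h=0.005)
        with pytest.raises(ConfigurationError):
            build_diffusion_operator(full_field(geo), mono_params)


class TestOperatorSplitting:
    def _passive_state(self, geo, v):
        fld = full_field(geo)
        state = TissueState.create(fld, geo.atp_map(6.0), ionic.CellParams(),
                                   0.02, equilibrate_ms=0.0)
        state.V[:] = v
        return fld, state

    def test_diffusion_annihilates_constant_fields(self, mono_params):
        geo = make_slab(0.05, 0.05, 1)
        fld, state = self._passive_state(geo, -70.0)
        op = build_diffusion_operator(fld, mono_params)
        advance_tissue(state, op, mono_params, passive=True)
        np.testing.assert_allclose(state.V, -70.0, atol=1e-12)

    def test_two_cell_exponential_relaxation(self, mono_params):
        geo = make_slab(0.02, 0.01, 1)
        fld, state = self._passive_state(geo, 0.0)
        state.V[:] = [-90.0, -70.0]
        op = build_diffusion_operator(fld, mono_params)
        rate = 2.0 * mono_params.sigma / mono_params.h ** 2 \
            / (mono_params.beta * mono_params.Cm)
        v1, v2 = state.V.copy()
        n = 200
        for _ in range(n):
            advance_tissue(state, op, mono_params, passive=True)
        # exact discrete solution of the explicit two-cell map
        decay = (1.0 - mono_params.dt * rate) ** n
        mean = 0.5 * (v1 + v2)
        np.testing.assert_allclose(
            state.V, [mean - 10.0 * decay, mean + 10.0 * decay], rtol=1e-10)

    def test_total_charge_conserved_by_diffusion(self, mono_params, rng):
        geo = make_slab(0.05, 0.05, 2, injured="all")
        fld = sample_fibrosis(geo, 0.3, seed=4)
        state = TissueState.create(fld, geo.atp_map(6.0), ionic.CellParams(),
                                   0.02, equilibrate_ms=0.0)
        state.V[:] = rng.uniform(-90.0, 20.0, state.n_cells)
        total0 = state.V.sum()
        op = build_diffusion_operator(fld, mono_params)
        for _ in range(50):
            advance_tissue(state, op, mono_params, passive=True)
        assert state.V.sum() == pytest.approx(total0, rel=1e-12)

    def test_reference_split_step_matches_kernel_on_small_tissue(self,
                                                                 mono_params):
        geo = make_slab(0.03, 0.01, 1)
        fld = full_field(geo)
        state_a = TissueState.create(fld, geo.atp_map(2.0), ionic.CellParams(),
                                     mono_params.dt)
        op = build_diffusion_operator(fld, mono_params)
        istim = np.array([80.0, 0.0, 0.0])
        n = 150  # 3 ms: stimulus + upstroke foot
        for k in range(n):
            drive = istim if k * mono_params.dt < 2.0 else np.zeros(3)
            advance_tissue(state_a, op, mono_params, istim=drive)
        rec_geo = geo
        mask = np.zeros(geo.shape, bool)
        mask[0] = True
        rec = run_simulation(
            rec_geo, fld, mono_params,
            StimulusProtocol(site=mask, amplitude=80.0, duration=2.0),
            atp_injured=2.0, duration_ms=n * mono_params.dt,
            stop_when_quiescent=False, frame_interval_ms=mono_params.dt)
        # final frame of the kernel path vs reference path
        assert rec.frames is not None
        np.testing.assert_allclose(state_a.V, rec.frames[-1], atol=0.25)

    def test_stability_bound_enforced(self):
        with pytest.raises(ConfigurationError):
            MonodomainParams(sigma=5.0)


class TestWavePropagation:
    def test_homogeneous_slab_single_planar_passage(self, mono_params):
        geo = make_slab(0.6, 0.1, 1, injured="all")
        fld = full_field(geo)
        rec = run_simulation(geo, fld, mono_params, StimulusProtocol("edge"),
                             atp_injured=6.0, duration_ms=80.0)
        assert np.all(rec.activation_counts == 1)
        times = np.full(geo.n_cells, np.nan)
        times[rec.cell_index[rec.event_cells]] = rec.event_times
        times = times.reshape(geo.shape)
        mean_by_x = times.mean(axis=(1, 2))
        assert np.all(np.diff(mean_by_x[1:-1]) > 0)
        # no-flux boundaries: isochrones stay planar within one cell
        spread = times[1:-1].max(axis=(1, 2)) - times[1:-1].min(axis=(1, 2))
        cell_time = mono_params.h / (30.0 / 1000.0)  # ~one cell at ~30 cm/s
        assert np.max(spread) < cell_time

    def test_fully_fibrotic_disc_never_activates(self, mono_params):
        geo = make_slab(0.8, 0.8, 1, injured=("disc", 0.2))
        fld = sample_fibrosis(geo, 1.0, seed=0)
        rec = run_simulation(geo, fld, mono_params, StimulusProtocol("edge"),
                             atp_injured=2.0, duration_ms=120.0)
        counts = rec.counts_grid()
        assert counts[geo.injured_mask].sum() == 0
        assert np.all(counts[fld.conductive] == 1)

    def test_cv_scales_as_sqrt_sigma(self):
        # lattice discreteness at h = 100 um drags the slow wave slightly
        # more than the fast one, so the ratio lands a few percent above 2
        lo = MonodomainParams(sigma=0.25)
        hi = MonodomainParams(sigma=1.0)
        cv_lo = planar_wave_cv(6.0, lo, strip_cm=1.6)
        cv_hi = planar_wave_cv(6.0, hi, strip_cm=1.6)
        assert cv_hi / cv_lo == pytest.approx(2.0, rel=0.12)

    def test_cv_grid_convergence(self, mono_params):
        # halving h at the calibrated continuum sigma moves CV by < 10 %
        # (dt is halved with h to stay inside the explicit stability bound)
        coarse = planar_wave_cv(6.0, mono_params, strip_cm=1.6)
        fine_params = MonodomainParams(sigma=mono_params.sigma, h=0.005,
                                       dt=0.01)
        fine = planar_wave_cv(6.0, fine_params, strip_cm=1.6)
        assert abs(fine - coarse) / coarse < 0.10

    def test_record_determinism(self, mono_params):
        geo = make_slab(0.5, 0.5, 1, injured="all")
        fld = sample_fibrosis(geo, 0.38, seed=3)
        kw = dict(atp_injured=2.0, duration_ms=150.0)
        r1 = run_simulation(geo, fld, mono_params, StimulusProtocol("edge"), **kw)
        r2 = run_simulation(geo, fld, mono_params, StimulusProtocol("edge"), **kw)
        assert np.array_equal(r1.event_times, r2.event_times)
        assert np.array_equal(r1.event_cells, r2.event_cells)


@pytest.fixture(scope="module")
def strip_record(mono_params):
    geo = make_slab(0.8, 0.02, 1, injured="all")
    fld = full_field(geo)
    return geo, run_simulation(geo, fld, mono_params,
                               StimulusProtocol("edge"),
                               atp_injured=6.0, duration_ms=80.0)


class TestMeasurements:

    def test_cv_positive_and_physiologic(self, strip_record):
        geo, rec = strip_record
        cv = measure_cv(rec, (20, 0, 0), (60, 0, 0))
        assert 25.0 < cv < 45.0

    def test_unactivated_probe_raises(self, mono_params):
        geo = make_slab(0.3, 0.02, 1, injured="all")
        fld = full_field(geo)
        rec = run_simulation(geo, fld, mono_params,
                             StimulusProtocol("edge", amplitude=0.001),
                             atp_injured=6.0, duration_ms=20.0)
        with pytest.raises(MeasurementError):
            measure_cv(rec, (5, 0, 0), (25, 0, 0))

    def test_symmetric_probes_undefined_velocity(self, mono_params):
        geo = make_slab(0.41, 0.05, 1, injured="all")
        fld = full_field(geo)
        mask = np.zeros(geo.shape, bool)
        mask[20, :, :] = True  # central column stimulus
        rec = run_simulation(geo, fld, mono_params,
                             StimulusProtocol(site=mask), atp_injured=6.0,
                             duration_ms=60.0)
        with pytest.raises(MeasurementError):
            measure_cv(rec, (10, 2, 0), (30, 2, 0))

    def test_wavelength_values(self):
        assert wavelength(21.0, 31.4) == pytest.approx(0.66, abs=0.005)
        assert wavelength(330.0, 34.2) == pytest.approx(11.3, abs=0.02)
        assert wavelength(0.0, 30.0) == 0.0
        with pytest.raises(DomainError):
            wavelength(100.0, -1.0)
        with pytest.raises(DomainError):
            wavelength(-5.0, 30.0)
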