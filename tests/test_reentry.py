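"""Reentry/ectopic detection rules and the Monte-Carlo pipeline
(scaled-down geometries; the acceptance suite runs the study-scale sweep)."""

import numpy as np
import pandas as pd
import pytest

from cardiomaze.errors import DomainError
from cardiomaze.geometry import make_cube, make_slab
from cardiomaze.reentry import (REFERENCE_AP_TABLE, ReentryCondition,
                                detect_ectopic_beat, detect_reentry,
                                minimum_size_search, probability_histogram,
                                quiescence_horizon, reentry_probability,
                                run_trial)
from cardiomaze.solver import SimulationRecord, StimulusProtocol


def synthetic_record(geometry, events, duration=1000.0, last_activity=None,
                     protocols=None, stop="quiescent"):
    """Build a record directly from an (cell, time) event list."""
    cells = np.array([c for c, _ in events], dtype=np.int64)
    times = np.array([t for _, t in events], dtype=float)
    n = geometry.n_cells
    counts = np.bincount(cells, minlength=n)
    prots = protocols or [{"site": "edge", "start": 0.0, "duration": 2.0,
                           "amplitude": 120.0}]
    return SimulationRecord(
        geometry=geometry, cell_index=np.arange(n),
        event_cells=cells, event_times=times,
        activation_counts=counts,
        last_activity_time=(last_activity if last_activity is not None
                            else (times.max() if times.size else 0.0)),
        duration_ms=duration, duration_done_ms=duration, stop_reason=stop,
        first_reactivation_ms=None,
        config={"protocols": prots})


class TestQuiescenceHorizon:
    def test_formula_components(self):
        geo = make_slab(2.0, 2.0, 1, injured="all")
        prot = StimulusProtocol("edge", start=0.0, duration=2.0)
        h = quiescence_horizon(geo, prot, margin_ms=100.0)
        diag = geo.h * np.linalg.norm(geo.shape)
        cv_min = min(cv for _, cv in REFERENCE_AP_TABLE.values())
        apd_max = max(apd for apd, _ in REFERENCE_AP_TABLE.values())
        assert h == pytest.approx(2.0 + diag / cv_min * 1000.0 + apd_max + 100.0)

    def test_grows_with_domain(self):
        small = quiescence_horizon(make_slab(1.0, 1.0, 1, injured="all"),
                                   StimulusProtocol("edge"))
        large = quiescence_horizon(make_slab(4.0, 4.0, 1, injured="all"),
                                   StimulusProtocol("edge"))
        assert large > small


class TestDetection:
    def test_double_activation_without_stimulus_is_reentry(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        rec = synthetic_record(geo, [(3, 10.0), (3, 900.0)])
        v = detect_reentry(rec, t_quiescence_expected=950.0)
        assert v.reentry and v.reactivation and not v.persistence
        assert v.n_multiply_activated_cells == 1
        assert "re-activated" in v.rationale

    def test_single_passage_is_not_reentry(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        rec = synthetic_record(geo, [(i, 1.0 + i) for i in range(10)])
        v = detect_reentry(rec, t_quiescence_expected=500.0)
        assert not v.reentry
        assert v.rationale == "single passage followed by quiescence"

    def test_persistent_activity_is_reentry(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        rec = synthetic_record(geo, [(1, 5.0)], last_activity=800.0)
        v = detect_reentry(rec, t_quiescence_expected=400.0)
        assert v.reentry and v.persistence

    def test_second_activation_inside_stimulus_window_not_counted(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        prots = [{"site": "edge", "start": 0.0, "duration": 2.0,
                  "amplitude": 120.0},
                 {"site": "edge", "start": 500.0, "duration": 2.0,
                  "amplitude": 120.0}]
        rec = synthetic_record(geo, [(3, 1.0), (3, 501.0)], protocols=prots)
        v = detect_reentry(rec, t_quiescence_expected=600.0)
        assert not v.reactivation

    def test_truncated_record_flags_indeterminate(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        rec = synthetic_record(geo, [(1, 5.0)], duration=100.0, stop="time-limit")
        v = detect_reentry(rec, t_quiescence_expected=400.0)
        assert v.indeterminate and not v.reentry

    def test_ectopic_not_applicable_without_healthy_region(self):
        geo = make_slab(0.05, 0.05, 1, injured="all")
        rec = synthetic_record(geo, [(1, 5.0), (1, 200.0)])
        assert detect_ectopic_beat(rec, geo) is None

    def test_ectopic_requires_healthy_reactivation(self):
        geo = make_slab(0.1, 0.1, 1, injured=("disc", 0.02))
        healthy_cells = np.flatnonzero(~geo.injured_mask.ravel())
        c = int(healthy_cells[0])
        rec = synthetic_record(geo, [(c, 5.0)])
        assert detect_ectopic_beat(rec, geo) is False
        rec2 = synthetic_record(geo, [(c, 5.0), (c, 300.0)])
        assert detect_ectopic_beat(rec2, geo) is True
        # short-coupled double counts as refractory-period noise, not ectopy
        rec3 = synthetic_record(geo, [(c, 5.0), (c, 30.0)])
        assert detect_ectopic_beat(rec3, geo) is False


class TestHomogeneousTissueNeverReenters:
    @pytest.mark.parametrize("faces", [1, 4, 6])
    def test_phi_zero_cube_all_protocols(self, faces, mono_params):
        # phi = 0 is seed-independent, so one run per protocol covers the
        # whole seed family
        cond = ReentryCondition(
            geometry=make_cube(0.2), protocols=[StimulusProtocol.faces(faces)],
            phi=0.0, atp=2.0, params=mono_params)
        verdict, rec, _ = run_trial(cond, seed=0)
        assert not verdict.reentry
        assert np.all(rec.activation_counts == 1)

    def test_phi_zero_slab_edge(self, mono_params):
        cond = ReentryCondition(
            geometry=make_slab(0.6, 0.6, 1, injured="all"),
            protocols=[StimulusProtocol("edge")], phi=0.0, atp=2.0,
            params=mono_params)
        verdict, rec, _ = run_trial(cond, seed=0)
        assert not verdict.reentry


@pytest.fixture(scope="module")
def small_condition(mono_params):
    return ReentryCondition(
        geometry=make_slab(0.8, 0.8, 1, injured="all"),
        protocols=[StimulusProtocol("edge")], phi=0.38, atp=2.0,
        params=mono_params, label="unit")


class TestMonteCarlo:

    def test_reproducible_from_master_seed(self, small_condition):
        r1 = reentry_probability(small_condition, trials=5, master_seed=77)
        r2 = reentry_probability(small_condition, trials=5, master_seed=77)
        assert np.array_equal(r1.seeds, r2.seeds)
        assert [v.reentry for v in r1.verdicts] == \
            [v.reentry for v in r2.verdicts]
        assert r1.probability == r2.probability

    def test_result_bookkeeping(self, small_condition):
        res = reentry_probability(small_condition, trials=5, master_seed=3)
        assert res.trials == len(res.verdicts) == 5
        assert res.probability == res.reentry_count / res.trials
        assert res.ci_low <= res.probability <= res.ci_high

    def test_histogram_rows_present_even_for_zero_probability(self, mono_params):
        conds = [ReentryCondition(
            geometry=make_slab(0.3, 0.3, 1, injured="all"),
            protocols=[StimulusProtocol("edge")], phi=phi, atp=2.0,
            params=mono_params) for phi in (0.0, 0.9)]
        frame = probability_histogram(conds, trials=2, master_seed=1)
        assert len(frame) == 2
        assert (frame["probability"] == 0.0).all()
        assert (frame["trials"] == 2).all()

    def test_trials_validation(self, small_condition):
        with pytest.raises(DomainError):
            reentry_probability(small_condition, trials=0)


class TestMinimumSize:
    def test_tiny_domains_cannot_sustain_reentry(self, mono_params):
        res = minimum_size_search("square", 1, [0.38], 2.0,
                                  trials_per_size=2, size_schedule=[2, 4],
                                  master_seed=5, params=mono_params)
        assert res.found_size is None
        assert isinstance(res.per_size, pd.DataFrame)
        assert len(res.per_size) == 2

    def test_non_monotone_schedule_rejected(self, mono_params):
        with pytest.raises(DomainError):
            minimum_size_search("square", 1, [0.38], 2.0, 1, [10, 10],
                                params=mono_params)
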