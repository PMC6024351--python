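"""Micro-reentry / ectopic-beat detection and Monte-Carlo probability sweeps.

The arrhythmia mechanism under study: a wave entering a hypoxic, diffusely
fibrotic region near its percolation threshold propagates slowly and
fractionates; source–sink mismatches create unidirectional blocks, the wave
re-enters recovered tissue inside the maze (micro-reentry) and can re-excite
the surrounding healthy tissue (an ectopic beat).  Detection uses two
complementary, individually logged criteria:

* **persistence** — electrical activity outlives the quiescence horizon
  expected for a single wave passage (stimulus end + domain transit at the
  slowest characterized CV + the longest characterized APD + margin), or
* **re-activation** — some cell fires a second time with no second external
  stimulus (counted only after the cell re-armed by repolarizing below the
  re-arm threshold).

Because fibrosis realizations are random, reentry probability per condition
(geometry, protocol, φ, [ATP]_i) is estimated by the Monte-Carlo method with
binomial error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ionic, percolation, solver
from .errors import DomainError
from .geometry import TissueGeometry, make_cube, make_slab, sample_fibrosis

__all__ = ["ReentryVerdict", "MCResult", "ReentryCondition", "detect_reentry",
           "detect_ectopic_beat", "reentry_probability",
           "probability_histogram", "minimum_size_search",
           "quiescence_horizon", "REFERENCE_AP_TABLE"]

#: Model characterization used by the quiescence-horizon formula:
#: [ATP]_i (mM) -> (APD90 ms, planar CV cm/s) measured on this package's
#: calibrated cell/tissue model (scripts in the repo regenerate them).
REFERENCE_AP_TABLE = {
    2.0: (21.0, 33.5),
    3.0: (48.1, 33.6),
    4.0: (139.1, 34.0),
    5.0: (282.8, 34.2),
    6.0: (300.9, 34.2),
}

QUIESCENCE_MARGIN_MS = 100.0


def quiescence_horizon(geometry: TissueGeometry,
                       protocols: "list | solver.StimulusProtocol",
                       margin_ms: float = QUIESCENCE_MARGIN_MS,
                       reference: dict | None = None) -> float:
    """Latest time (ms) a single non-reentrant passage can still be active.

    Computed, not guessed: last stimulus end, plus the domain diagonal
    traversed at the slowest characterized conduction velocity, plus the
    longest characterized APD, plus a margin.
    """
    if isinstance(protocols, solver.StimulusProtocol):
        protocols = [protocols]
    ref = reference or REFERENCE_AP_TABLE
    stim_end = max(p.start + p.duration for p in protocols)
    diag_cm = geometry.h * float(np.linalg.norm(geometry.shape))
    cv_min = min(cv for _, cv in ref.values())  # cm/s
    apd_max = max(apd for apd, _ in ref.values())  # ms
    return stim_end + diag_cm / cv_min * 1000.0 + apd_max + margin_ms


@dataclass
class ReentryVerdict:
    """Outcome of reentry detection on one simulation record."""

    reentry: bool
    ectopic: bool
    n_multiply_activated_cells: int
    last_activity_time: float
    rationale: str
    indeterminate: bool = False
    persistence: bool = False
    reactivation: bool = False
    t_quiescence_expected: float = float("nan")


def _second_events_outside_stimulus(record: solver.SimulationRecord,
                                    subset_mask: np.ndarray | None = None):
    """Times of non-first activations not attributable to an external stimulus."""
    prots = record.config.get("protocols", [])
    windows = [(p["start"], p["start"] + p["duration"]) for p in prots]
    order = np.argsort(record.event_times, kind="stable")
    seen = set()
    out = []
    for k in order:
        c = int(record.event_cells[k])
        t = float(record.event_times[k])
        if subset_mask is not None and not subset_mask[c]:
            continue
        if c not in seen:
            seen.add(c)
            continue
        if any(lo <= t <= hi for lo, hi in windows):
            continue
        out.append((c, t))
    return out


def detect_reentry(record: solver.SimulationRecord,
                   t_quiescence_expected: float | None = None,
                   geometry: TissueGeometry | None = None) -> ReentryVerdict:
    """Apply both reentry criteria to a completed simulation record."""
    geo = geometry or record.geometry
    if t_quiescence_expected is None:
        prots = [solver.StimulusProtocol(site="edge", start=p["start"],
                                         duration=p["duration"],
                                         amplitude=p["amplitude"])
                 for p in record.config.get("protocols", [])]
        t_quiescence_expected = quiescence_horizon(geo, prots)
    persistence = record.last_activity_time > t_quiescence_expected
    seconds = _second_events_outside_stimulus(record)
    reactivation = len(seconds) > 0
    n_multi = int(np.sum(record.activation_counts >= 2))
    truncated = (record.stop_reason == "time-limit"
                 and record.duration_done_ms < t_quiescence_expected
                 and not reactivation)
    reentry = bool(persistence or reactivation)
    if reactivation and persistence:
        rationale = "re-activation without stimulus and activity beyond horizon"
    elif reactivation:
        rationale = (f"cell re-activated without stimulus at "
                     f"t = {seconds[0][1]:.1f} ms")
    elif persistence:
        rationale = (f"activity at t = {record.last_activity_time:.1f} ms "
                     f"persists beyond horizon {t_quiescence_expected:.1f} ms")
    elif truncated:
        rationale = "record truncated before the quiescence horizon"
    else:
        rationale = "single passage followed by quiescence"
    ectopic = bool(detect_ectopic_beat(record, geo)) if reentry else False
    return ReentryVerdict(reentry=reentry, ectopic=ectopic,
                          n_multiply_activated_cells=n_multi,
                          last_activity_time=record.last_activity_time,
                          rationale=rationale, indeterminate=truncated,
                          persistence=bool(persistence),
                          reactivation=bool(reactivation),
                          t_quiescence_expected=t_quiescence_expected)


def detect_ectopic_beat(record: solver.SimulationRecord,
                        geometry: TissueGeometry | None = None,
                        refractory_ms: float = 50.0) -> bool | None:
    """True iff a healthy-region cell re-fires without an external stimulus.

    Returns ``None`` (not applicable) when the geometry has no healthy
    region.  The two activations must be separated by more than
    ``refractory_ms``.
    """
    geo = geometry or record.geometry
    healthy_grid = ~geo.injured_mask.ravel()
    if not healthy_grid.any():
        return None
    healthy = healthy_grid[record.cell_index]
    prots = record.config.get("protocols", [])
    windows = [(p["start"], p["start"] + p["duration"]) for p in prots]
    first = {}
    order = np.argsort(record.event_times, kind="stable")
    for k in order:
        c = int(record.event_cells[k])
        if not healthy[c]:
            continue
        t = float(record.event_times[k])
        if c not in first:
            first[c] = t
            continue
        if t - first[c] <= refractory_ms:
            continue
        if any(lo <= t <= hi for lo, hi in windows):
            continue
        return True
    return False


# ---------------------------------------------------------------------------
# Monte-Carlo sweeps


@dataclass
class ReentryCondition:
    """One Monte-Carlo condition: geometry, stimulation, φ and hypoxia level."""

    geometry: TissueGeometry
    protocols: list
    phi: float
    atp: float
    params: solver.MonodomainParams = field(default_factory=solver.MonodomainParams)
    cell_params: ionic.CellParams = field(default_factory=ionic.CellParams)
    margin_after_horizon_ms: float = 1000.0
    label: str = ""

    def __post_init__(self):
        if isinstance(self.protocols, solver.StimulusProtocol):
            self.protocols = [self.protocols]


@dataclass
class MCResult:
    """Aggregated reentry statistics for one condition."""

    condition: dict
    trials: int
    reentry_count: int
    probability: float
    ci_low: float
    ci_high: float
    seeds: np.ndarray
    verdicts: list
    failed_trials: list
    ectopic_count: int = 0

    def as_row(self) -> dict:
        return {**self.condition, "trials": self.trials,
                "reentries": self.reentry_count, "probability": self.probability,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "ectopics": self.ectopic_count,
                "failed": len(self.failed_trials)}


def run_trial(condition: ReentryCondition, seed: int,
              cross_checks: bool = True,
              stop_on_reactivation: bool = True):
    """One fibrosis realization through the solver and detector.

    Returns ``(verdict, record, field)``.  With ``cross_checks`` the trial
    asserts (a) far-face propagation implies graph percolation of the mask
    and (b) a reentry verdict implies the injured region was actually
    entered — guards against detector artifacts.
    """
    geo = condition.geometry
    fld = sample_fibrosis(geo, condition.phi, seed=seed)
    horizon = quiescence_horizon(geo, condition.protocols)
    duration = horizon + condition.margin_after_horizon_ms
    rec = solver.run_simulation(
        geo, fld, condition.params, condition.protocols,
        atp_injured=condition.atp, duration_ms=duration,
        cell_params=condition.cell_params,
        stop_when_quiescent=True, stop_on_reactivation=stop_on_reactivation)
    verdict = detect_reentry(rec, t_quiescence_expected=horizon, geometry=geo)
    if cross_checks:
        if rec.far_face_activated(axis=0) and not percolation.percolates(fld, axis=0):
            raise AssertionError(
                "propagation reached the far face of a non-percolating mask")
        if verdict.reentry:
            injured = geo.injured_mask.ravel()[rec.cell_index]
            if not np.any((rec.activation_counts > 0) & injured):
                raise AssertionError(
                    "reentry verdict with no activation inside the injured region")
    return verdict, rec, fld


def reentry_probability(condition: ReentryCondition, trials: int,
                        master_seed: int = 0,
                        cross_checks: bool = True) -> MCResult:
    """Monte-Carlo reentry probability with a binomial confidence interval.

    Every trial is reproducible from its logged per-trial seed.  Trials that
    fail numerically are excluded from both numerator and denominator and
    reported in ``failed_trials``.
    """
    if trials < 1:
        raise DomainError("trials must be >= 1")
    seeds = percolation._spawn_seeds(master_seed, trials)
    verdicts = []
    failed = []
    count = 0
    ectopic = 0
    for s in seeds:
        try:
            verdict, _, _ = run_trial(condition, int(s), cross_checks=cross_checks)
        except (solver.NumericalInstabilityError,) as exc:
            failed.append({"seed": int(s), "error": str(exc)})
            continue
        verdicts.append(verdict)
        count += verdict.reentry
        ectopic += bool(verdict.ectopic)
    n_ok = len(verdicts)
    prob = count / n_ok if n_ok else float("nan")
    lo, hi = percolation._binomial_ci(count, n_ok) if n_ok else (float("nan"),) * 2
    cond = {"label": condition.label, "phi": condition.phi,
            "atp": condition.atp, "nx": condition.geometry.nx,
            "ny": condition.geometry.ny, "nz": condition.geometry.nz}
    return MCResult(condition=cond, trials=n_ok, reentry_count=count,
                    probability=prob, ci_low=lo, ci_high=hi, seeds=seeds,
                    verdicts=verdicts, failed_trials=failed,
                    ectopic_count=ectopic)


def probability_histogram(conditions, trials: int, master_seed: int = 0,
                          plot_path=None) -> pd.DataFrame:
    """Long-format table of reentry percentages over a condition sweep.

    One row per (condition) bar with binomial CI columns; optionally writes a
    bar figure.
    """
    conditions = list(conditions)
    if not conditions:
        raise DomainError("condition sweep is empty")
    rows = []
    for j, cond in enumerate(conditions):
        res = reentry_probability(cond, trials=trials,
                                  master_seed=master_seed + 104729 * j)
        rows.append(res.as_row())
    frame = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(frame))
        ax.bar(x, 100 * frame["probability"],
               yerr=100 * (frame["probability"] - frame["ci_low"]),
               capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels([f"φ={r.phi:g}\nATP={r.atp:g}"
                            for r in frame.itertuples()], fontsize=7)
        ax.set_ylabel("reentries (%)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return frame


@dataclass
class MinimumSizeResult:
    """Outcome of a minimum-reentry-size search."""

    found_size: int | None
    per_size: pd.DataFrame
    family: str
    protocol_faces: int


def _family_geometry(family: str, n_side: int, h: float) -> TissueGeometry:
    if family == "square":
        return make_slab(n_side * h, n_side * h, 1, injured="all", h=h)
    if family == "slab10":
        return make_slab(n_side * h, n_side * h, 10, injured="all", h=h)
    if family == "cube":
        return make_cube(n_side * h, h=h)
    raise DomainError(f"unknown geometry family {family!r}")


def minimum_size_search(family: str, n_faces: int, phi_set, atp: float,
                        trials_per_size: int, size_schedule,
                        master_seed: int = 0,
                        params: solver.MonodomainParams | None = None,
                        cell_params: ionic.CellParams | None = None
                        ) -> MinimumSizeResult:
    """Smallest size (cells per side) in the schedule with >= 1 reentry.

    For every size, ``trials_per_size`` trials are run at each φ in
    ``phi_set``; the search reports the smallest size at which any trial
    shows reentry, with all per-size counts logged, or ``found_size=None``
    if the schedule floor is reached without one.
    """
    sizes = sorted(int(s) for s in size_schedule)
    diffs = np.diff(sizes)
    if np.any(diffs == 0):
        raise DomainError("size schedule must be strictly monotone")
    params = params or solver.MonodomainParams()
    cell_params = cell_params or ionic.CellParams()
    rows = []
    found = None
    for si, n_side in enumerate(sizes):
        geo = _family_geometry(family, n_side, params.h)
        total = 0
        for pj, phi in enumerate(phi_set):
            cond = ReentryCondition(
                geometry=geo,
                protocols=[solver.StimulusProtocol.faces(n_faces)],
                phi=float(phi), atp=atp, params=params,
                cell_params=cell_params,
                label=f"{family}-{n_side}")
            res = reentry_probability(
                cond, trials=trials_per_size,
                master_seed=master_seed + 15485863 * si + 32452843 * pj)
            total += res.reentry_count
            rows.append(res.as_row())
        if total > 0 and found is None:
            found = n_side
    return MinimumSizeResult(found_size=found, per_size=pd.DataFrame(rows),
                             family=family, protocol_faces=n_faces)
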