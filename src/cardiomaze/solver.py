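"""Monodomain reaction–diffusion solver on the regular finite-volume grid.

The transmembrane potential obeys

.. math:: \\beta C_m \\partial_t V + \\beta I_{ion}(V, \\eta) =
          \\nabla\\cdot(\\sigma \\nabla V) + I_{stim}, \\qquad
          \\partial_t \\eta = f(V, \\eta)

with isotropic conductivity σ, surface-to-volume ratio β, membrane
capacitance C_m, and no-flux (isolated) boundaries.  Space is discretized
with a 7-point face-flux finite-volume scheme on the (100 µm)³ grid: a face
conducts σ/h² iff both adjacent cells are conductive; faces on the domain
boundary or touching a fibrotic cell carry zero flux, so fibrotic cells are
completely disconnected and hold no state.  Time stepping is operator-split
(reaction by Rush–Larsen/Euler, then explicit diffusion) at a fixed dt.

σ, β and C_m enter the discrete dynamics only through D = σ/(β C_m); σ is
calibrated (see :func:`calibrate_sigma`) so a normoxic planar wave travels at
the tabulated conduction velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from . import ionic, kernels
from .errors import (ConfigurationError, DomainError, GeometryError,
                     MeasurementError, NumericalInstabilityError)
from .geometry import FibrosisField, TissueGeometry, make_slab

__all__ = [
    "MonodomainParams", "StimulusProtocol", "SimulationRecord", "TissueState",
    "DiffusionOperator", "build_diffusion_operator", "advance_tissue",
    "run_simulation", "measure_cv", "wavelength", "calibrate_sigma",
    "planar_wave_cv",
]

#: default isotropic conductivity (mS/cm), calibrated so that a planar wave
#: at [ATP]_i = 6 mM on the h = 100 µm grid travels at 34.2 cm/s
DEFAULT_SIGMA = 0.44785

STABILITY_SAFETY = 1.0  # fraction of the explicit diffusion limit allowed


@dataclass
class MonodomainParams:
    """Continuum and bookkeeping parameters of the tissue model."""

    sigma: float = DEFAULT_SIGMA  # mS/cm
    beta: float = 1400.0  # cm^-1
    Cm: float = 1.0  # uF/cm^2
    dt: float = 0.02  # ms
    h: float = 0.01  # cm
    act_threshold: float = -40.0  # mV, upward crossing records an activation
    rearm_threshold: float = -70.0  # mV, cell must repolarize below this
    refractory_ms: float = 10.0  # minimum separation of a cell's activations
    quiescent_v: float = -70.0  # mV, tissue counts as quiescent below this
    quiescent_ms: float = 20.0  # sustained quiescence needed to stop early

    def __post_init__(self):
        for name in ("sigma", "beta", "Cm", "dt", "h"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        limit = self.beta * self.Cm * self.h ** 2 / (6.0 * self.sigma)
        if self.dt > STABILITY_SAFETY * limit:
            raise ConfigurationError(
                f"dt = {self.dt} ms violates the explicit stability bound "
                f"beta*Cm*h^2/(6*sigma) = {limit:.4f} ms")

    @property
    def diffusivity(self) -> float:
        """D = sigma / (beta Cm) in cm^2/ms."""
        return self.sigma / (self.beta * self.Cm)

    def as_dict(self) -> dict:
        return asdict(self)


_FACES = {"x-", "x+", "y-", "y+", "z-", "z+"}


@dataclass
class StimulusProtocol:
    """External stimulus: a named site set, start/duration, and amplitude.

    ``site`` is one of the face names ``x-/x+/y-/y+/z-/z+`` (the full
    one-cell-thick conductive layer on that boundary; ``edge`` is an alias
    for ``x-``, the planar-edge strip), a comma-separated list of faces, or a
    boolean mask of grid shape.  Amplitude is in pA/pF, depolarizing
    positive.
    """

    site: object = "edge"
    start: float = 0.0  # ms
    duration: float = 2.0  # ms
    amplitude: float = 120.0  # pA/pF

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be positive")

    @staticmethod
    def faces(n: int, **kw) -> "StimulusProtocol":
        """Face sets used by the cube experiments: 1, 2 (adjacent), 4 or 6 faces."""
        sets = {1: "x-", 2: "x-,y-", 4: "x-,x+,y-,y+",
                6: "x-,x+,y-,y+,z-,z+"}
        if n not in sets:
            raise ConfigurationError("face count must be one of 1, 2, 4, 6")
        return StimulusProtocol(site=sets[n], **kw)

    def grid_mask(self, geometry: TissueGeometry) -> np.ndarray:
        if isinstance(self.site, np.ndarray):
            mask = np.asarray(self.site, dtype=bool)
            if mask.shape != geometry.shape:
                raise GeometryError("stimulus mask shape does not match grid")
            return mask
        spec = str(self.site)
        if spec == "edge":
            spec = "x-"
        mask = np.zeros(geometry.shape, dtype=bool)
        for name in spec.split(","):
            name = name.strip()
            if name not in _FACES:
                raise ConfigurationError(f"unknown stimulus site {name!r}")
            axis = "xyz".index(name[0])
            sl = [slice(None)] * 3
            sl[axis] = 0 if name[1] == "-" else -1
            mask[tuple(sl)] = True
        if not mask.any():
            raise ConfigurationError("stimulus site set is empty")
        return mask

    def as_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.site, np.ndarray):
            d["site"] = "custom-mask"
        return d


@dataclass
class DiffusionOperator:
    """Sparse face-flux operator over the conductive-cell subset.

    ``matrix`` rows/cols are indexed by position in ``cell_index``, which
    holds the flat (C-order) grid index of every conductive cell.  Entries
    are in units of σ/h²; divide by β·C_m when advancing V.
    """

    matrix: sp.csr_matrix
    cell_index: np.ndarray
    h: float
    sigma: float


def build_diffusion_operator(field: FibrosisField,
                             params: MonodomainParams) -> DiffusionOperator:
    """Assemble the 7-point operator with fibrotic/boundary faces removed.

    Rows sum to zero (no-flux/conservation) and the matrix is symmetric.
    """
    geo = field.geometry
    if abs(geo.h - params.h) > 1e-12:
        raise ConfigurationError(
            f"geometry spacing h={geo.h} differs from params h={params.h}")
    mask = field.conductive
    n = int(mask.sum())
    pos = -np.ones(geo.shape, dtype=np.int64)
    pos[mask] = np.arange(n)
    c = params.sigma / params.h ** 2
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = pos[tuple(sl_a)].ravel()
        b = pos[tuple(sl_b)].ravel()
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok]); cols.append(b[ok])
        rows.append(b[ok]); cols.append(a[ok])
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.full(rows.size, c)
    deg = np.bincount(rows, minlength=n).astype(float)
    diag_rows = np.arange(n)
    mat = sp.coo_matrix(
        (np.concatenate([data, -c * deg]),
         (np.concatenate([rows, diag_rows]), np.concatenate([cols, diag_rows]))),
        shape=(n, n)).tocsr()
    return DiffusionOperator(matrix=mat,
                             cell_index=np.flatnonzero(mask.ravel()),
                             h=params.h, sigma=params.sigma)


# ---------------------------------------------------------------------------
# tissue state


@dataclass
class TissueState:
    """Per-cell electrophysiological state over the conductive subset."""

    V: np.ndarray
    G: np.ndarray  # (n, 18): 13 gating variables then 5 concentrations
    atp: np.ndarray
    ek: np.ndarray
    ena: np.ndarray
    eks: np.ndarray
    eca: np.ndarray
    vrest: np.ndarray
    katp_g: np.ndarray
    ical_f: np.ndarray

    @classmethod
    def create(cls, field: FibrosisField, atp_map: np.ndarray,
               cell_params: ionic.CellParams, dt: float,
               equilibrate_ms: float = 1000.0) -> "TissueState":
        """Initialize every conductive cell at the equilibrated resting state
        of its own ATP level (computed once per distinct level)."""
        mask = field.conductive
        atp = np.asarray(atp_map, dtype=float)[mask]
        n = atp.size
        V = np.empty(n)
        G = np.empty((n, 18))
        katp_g = np.empty(n)
        ical_f = np.empty(n)
        for level in np.unique(atp):
            y = ionic.resting_state(float(level), cell_params,
                                    equilibrate_ms=equilibrate_ms,
                                    dt=dt).as_vector()
            sel = atp == level
            V[sel] = y[0]
            G[sel] = y[1:]
            kg, icf = kernels._atp_factors(float(level), cell_params)
            katp_g[sel] = kg
            ical_f[sel] = icf
        ek = np.empty(n); ena = np.empty(n); eks = np.empty(n); eca = np.empty(n)
        p = cell_params
        ek[:] = ionic.RTONF * np.log(p.Ko / G[:, 17])
        ena[:] = ionic.RTONF * np.log(p.Nao / G[:, 16])
        eks[:] = ionic.RTONF * np.log((p.Ko + p.p_KNa * p.Nao)
                                      / (G[:, 17] + p.p_KNa * G[:, 16]))
        eca[:] = 0.5 * ionic.RTONF * np.log(p.Cao / G[:, 13])
        return cls(V=V, G=G, atp=atp, ek=ek, ena=ena, eks=eks, eca=eca,
                   vrest=V.copy(), katp_g=katp_g, ical_f=ical_f)

    @property
    def n_cells(self) -> int:
        return self.V.size

    def cell_state(self, i: int) -> ionic.CellState:
        return ionic.CellState(V=float(self.V[i]), gates=self.G[i, :13].copy(),
                               concentrations=self.G[i, 13:].copy(),
                               atp=float(self.atp[i]))


def advance_tissue(state: TissueState, operator: DiffusionOperator,
                   params: MonodomainParams, istim: np.ndarray | None = None,
                   dt: float | None = None, passive: bool = False,
                   cell_params: ionic.CellParams | None = None) -> TissueState:
    """One operator-split step through the readable reference path.

    Reaction via :func:`cardiomaze.ionic.step_cell` per cell (skipped for
    ``passive=True``, which leaves a pure diffusion step), then explicit
    diffusion ``V <- V + dt (L V)/(beta Cm)``.  Intended for small systems
    and verification; production runs use :func:`run_simulation`.
    """
    dt = params.dt if dt is None else dt
    if dt <= 0:
        raise DomainError("dt must be positive")
    p = cell_params or ionic.CellParams()
    n = state.n_cells
    if istim is None:
        istim = np.zeros(n)
    if not passive:
        for i in range(n):
            cs = ionic.step_cell(state.cell_state(i), dt=dt,
                                 istim=float(istim[i]), params=p)
            state.V[i] = cs.V
            state.G[i, :13] = cs.gates
            state.G[i, 13:] = cs.concentrations
    lap = operator.matrix @ state.V
    state.V = state.V + dt * lap / (params.beta * params.Cm)
    bad = np.nonzero(np.abs(state.V) > ionic.V_DIVERGENCE_LIMIT)[0]
    if bad.size:
        raise NumericalInstabilityError(
            f"potential diverged at conductive cell {bad[0]}")
    return state


# ---------------------------------------------------------------------------
# full simulation


@dataclass
class SimulationRecord:
    """Per-cell activation bookkeeping and optional voltage frames.

    ``event_cells``/``event_times`` list every recorded activation (upward
    crossing of the activation threshold with re-arming below the rearm
    threshold); ``cell_index`` maps conductive-subset positions to flat grid
    indices.
    """

    geometry: TissueGeometry
    cell_index: np.ndarray
    event_cells: np.ndarray
    event_times: np.ndarray
    activation_counts: np.ndarray
    last_activity_time: float
    duration_ms: float
    duration_done_ms: float
    stop_reason: str
    first_reactivation_ms: float | None
    frames: np.ndarray | None = None
    frame_times: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.cell_index.size

    def activation_times_of(self, subset_index: int) -> np.ndarray:
        return self.event_times[self.event_cells == subset_index]

    @property
    def activation_times(self) -> list:
        """Per-cell activation-time arrays (conductive-subset order)."""
        order = np.argsort(self.event_times, kind="stable")
        cells = self.event_cells[order]
        times = self.event_times[order]
        out = [[] for _ in range(self.n_cells)]
        for c, t in zip(cells, times):
            out[c].append(t)
        return [np.asarray(v) for v in out]

    def counts_grid(self) -> np.ndarray:
        g = np.zeros(self.geometry.n_cells, dtype=np.int64)
        g[self.cell_index] = self.activation_counts
        return g.reshape(self.geometry.shape)

    def subset_of_grid_cell(self, ix: int, iy: int, iz: int) -> int:
        flat = (ix * self.geometry.ny + iy) * self.geometry.nz + iz
        pos = np.searchsorted(self.cell_index, flat)
        if pos >= self.cell_index.size or self.cell_index[pos] != flat:
            raise MeasurementError(f"grid cell {(ix, iy, iz)} is not conductive")
        return int(pos)

    def far_face_activated(self, axis: int = 0) -> bool:
        counts = self.counts_grid()
        sl = [slice(None)] * 3
        sl[axis] = -1
        return bool(np.any(counts[tuple(sl)] > 0))


_STOP_NAMES = {kernels.STOP_TIME: "time-limit",
               kernels.STOP_QUIESCENT: "quiescent",
               kernels.STOP_REACTIVATION: "reactivation",
               kernels.STOP_UNSTABLE: "unstable",
               kernels.STOP_EVENT_OVERFLOW: "event-overflow"}


def run_simulation(geometry: TissueGeometry, field_: FibrosisField,
                   params: MonodomainParams,
                   protocols: StimulusProtocol | list,
                   atp_injured: float = 6.0,
                   duration_ms: float = 500.0,
                   frame_interval_ms: float = 0.0,
                   cell_params: ionic.CellParams | None = None,
                   stop_when_quiescent: bool = True,
                   stop_on_reactivation: bool = False,
                   state: TissueState | None = None,
                   operator: DiffusionOperator | None = None) -> SimulationRecord:
    """Execute the full monodomain time loop and record activations.

    The run may stop early once the tissue is quiescent (no conductive cell
    above the quiescence threshold for a sustained window after all stimuli)
    or, with ``stop_on_reactivation``, at the first re-activation of any cell
    outside a stimulus window.  Deterministic and reproducible from the
    echoed configuration.
    """
    if isinstance(protocols, StimulusProtocol):
        protocols = [protocols]
    if not protocols:
        raise ConfigurationError("at least one stimulus protocol is required")
    p = cell_params or ionic.CellParams()
    if operator is None:
        operator = build_diffusion_operator(field_, params)
    if state is None:
        state = TissueState.create(field_, geometry.atp_map(atp_injured),
                                   p, params.dt)
    n = state.n_cells
    mat = operator.matrix
    VT, K1T, C = kernels.build_tables(p, params.dt)

    # resolve stimulus site sets to conductive-subset indices
    pos = -np.ones(geometry.n_cells, dtype=np.int64)
    pos[operator.cell_index] = np.arange(n)
    stim_cells, stim_ptr = [], [0]
    stim_start = np.empty(len(protocols))
    stim_end = np.empty(len(protocols))
    stim_amp = np.empty(len(protocols))
    for k, prot in enumerate(protocols):
        cells = pos[np.flatnonzero(prot.grid_mask(geometry).ravel())]
        cells = cells[cells >= 0]
        stim_cells.append(cells)
        stim_ptr.append(stim_ptr[-1] + cells.size)
        stim_start[k] = prot.start
        stim_end[k] = prot.start + prot.duration
        stim_amp[k] = prot.amplitude
    stim_cells = (np.concatenate(stim_cells) if stim_cells
                  else np.empty(0, dtype=np.int64))
    stim_ptr = np.asarray(stim_ptr, dtype=np.int64)

    n_steps = int(round(duration_ms / params.dt))
    active = np.zeros(n, dtype=bool)
    compute = np.zeros(n, dtype=bool)
    # cells whose neighborhood mixes ATP levels feel a flux from t = 0
    if np.unique(state.atp).size > 1:
        mixed = np.abs(mat @ state.vrest) > 1e-12
        compute |= mixed
        active |= mixed
    ev_cap = max(64, 8 * n)
    ev_cell = np.empty(ev_cap, dtype=np.int64)
    ev_time = np.empty(ev_cap)
    last_event = np.full(n, -1e9)
    act_count = np.zeros(n, dtype=np.int64)
    armed = np.ones(n, dtype=bool)
    if frame_interval_ms > 0:
        frame_every = max(1, int(round(frame_interval_ms / params.dt)))
        nf = n_steps // frame_every + 1
        frames = np.empty((nf, n))
    else:
        frame_every = 0
        frames = np.empty((0, n))
    out = np.zeros(8)
    quiescent_ms = params.quiescent_ms if stop_when_quiescent else 1e18
    kernels.run_tissue_kernel(
        state.V, state.G, state.katp_g, state.ical_f,
        state.ek, state.ena, state.eks, state.eca, state.vrest,
        active, compute, C, VT, K1T, params.dt, n_steps,
        25,  # reversal-potential refresh interval (steps)
        mat.indptr, mat.indices, mat.data, 1.0 / (params.beta * params.Cm),
        stim_cells, stim_ptr, stim_start, stim_end, stim_amp,
        params.act_threshold, params.rearm_threshold, params.refractory_ms,
        params.quiescent_v, quiescent_ms,
        stop_on_reactivation,
        ev_cell, ev_time, last_event, act_count, armed,
        frames, frame_every, out)
    steps_done, n_ev = int(out[0]), int(out[1])
    stop_code = int(out[3])
    if stop_code == kernels.STOP_UNSTABLE:
        raise NumericalInstabilityError(
            f"potential diverged at conductive cell {int(out[5])} "
            f"(grid index {int(operator.cell_index[int(out[5])])}) "
            f"at t = {steps_done * params.dt:.2f} ms")
    nf = int(out[4])
    first_re = float(out[6]) if out[6] >= 0 else None
    config = {
        "geometry": geometry.describe(),
        "phi": field_.phi, "field_seed": field_.seed,
        "atp_injured": atp_injured,
        "params": params.as_dict(),
        "protocols": [pr.as_dict() for pr in protocols],
        "cell": p.as_dict(),
        "duration_ms": duration_ms,
    }
    return SimulationRecord(
        geometry=geometry,
        cell_index=operator.cell_index,
        event_cells=ev_cell[:n_ev].copy(),
        event_times=ev_time[:n_ev].copy(),
        activation_counts=act_count,
        last_activity_time=float(out[2]),
        duration_ms=duration_ms,
        duration_done_ms=steps_done * params.dt,
        stop_reason=_STOP_NAMES[stop_code],
        first_reactivation_ms=first_re,
        frames=frames[:nf].copy() if frame_every > 0 else None,
        frame_times=(np.arange(nf) * frame_every * params.dt
                     if frame_every > 0 else None),
        config=config)


# ---------------------------------------------------------------------------
# measurements


def measure_cv(record: SimulationRecord, probe_a: tuple, probe_b: tuple) -> float:
    """Conduction velocity (cm/s) between two probes from activation times."""
    ia = record.subset_of_grid_cell(*probe_a)
    ib = record.subset_of_grid_cell(*probe_b)
    ta = record.activation_times_of(ia)
    tb = record.activation_times_of(ib)
    if ta.size != 1 or tb.size != 1:
        raise MeasurementError(
            f"probes must activate exactly once (got {ta.size} and {tb.size})")
    dt_ms = float(tb[0] - ta[0])
    if dt_ms == 0.0:
        raise MeasurementError("probes activated simultaneously; velocity undefined")
    h = record.geometry.h
    dist = h * math.dist(probe_a, probe_b)
    return abs(dist / dt_ms) * 1000.0


def wavelength(apd_ms: float, cv_cm_s: float) -> float:
    """Wavelength (cm) = APD x CV."""
    if apd_ms < 0 or cv_cm_s <= 0:
        raise DomainError("APD must be >= 0 and CV positive")
    return apd_ms * cv_cm_s / 1000.0


def planar_wave_cv(atp: float, params: MonodomainParams,
                   cell_params: ionic.CellParams | None = None,
                   strip_cm: float = 2.4,
                   stim: StimulusProtocol | None = None) -> float:
    """Planar conduction velocity on a homogeneous 1-cell-wide strip.

    The strip is uniformly at ``atp``; probes sit 1/4 and 3/4 along it, far
    from the stimulus and the no-flux ends.  Returns 0.0 if the wave fails to
    reach the far probe (used by the σ calibration to signal sub-threshold
    coupling).
    """
    geo = make_slab(strip_cm, params.h, 1, injured="all", h=params.h)
    fld = FibrosisField(geometry=geo,
                        conductive=np.ones(geo.shape, dtype=bool), phi=0.0)
    stim = stim or StimulusProtocol(site="x-")
    duration = strip_cm / 5.0 * 1000.0 / 4.0  # generous: 5 cm/s lower bound over 1/4
    rec = run_simulation(geo, fld, params, stim, atp_injured=atp,
                         duration_ms=min(duration, 600.0),
                         cell_params=cell_params, stop_when_quiescent=True)
    a = (geo.nx // 4, 0, 0)
    b = (3 * geo.nx // 4, 0, 0)
    try:
        return measure_cv(rec, a, b)
    except MeasurementError:
        return 0.0


def calibrate_sigma(target_cv: float = 34.2, atp: float = 6.0,
                    params: MonodomainParams | None = None,
                    cell_params: ionic.CellParams | None = None,
                    strip_cm: float = 2.4, tol: float = 0.05,
                    lo: float = 0.05, hi: float = 1.1) -> float:
    """Bisection on σ so the planar wave at ``atp`` travels at ``target_cv``.

    ``tol`` is the CV tolerance in cm/s.  Returns the calibrated σ (mS/cm).
    """
    base = (params or MonodomainParams()).as_dict()

    def cv_of(sig: float) -> float:
        base["sigma"] = sig
        return planar_wave_cv(atp, MonodomainParams(**base), cell_params,
                              strip_cm=strip_cm)

    cv_hi = cv_of(hi)
    if cv_hi < target_cv:
        raise ConfigurationError(
            f"upper bracket sigma={hi} gives CV={cv_hi:.1f} < target")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cv = cv_of(mid)
        if abs(cv - target_cv) <= tol:
            return mid
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
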