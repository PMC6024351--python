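"""Finite-size percolation of conductive-cell masks.

A fibrosis field "percolates" along an axis when a 6-connected (face
adjacency) path of conductive cells joins the two opposite boundary faces —
the same adjacency the finite-volume diffusion operator couples, so graph
connectivity is a necessary condition for wave propagation.  Crossing
probabilities are estimated over independent fibrosis realizations and the
percolation threshold φ_th is read off the crossing-probability curve by
linear interpolation at probability 1/2.

The graph test is the cheap primary oracle; a wave-based mode that actually
propagates an action potential through the mask is available for
cross-checks (connectivity can exist while source–sink mismatch still blocks
the wave, so both results are reported in that mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DomainError, RangeError
from .geometry import FibrosisField, TissueGeometry, make_cube, make_slab, \
    sample_fibrosis

__all__ = ["percolates", "crossing_probability", "estimate_threshold",
           "threshold_curve", "CrossingResult", "PercolationEstimate"]

_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-neighbor faces


def percolates(field: FibrosisField | np.ndarray, axis: int = 0) -> bool:
    """True iff a 6-connected conductive path joins the opposite faces along
    ``axis``.  Deterministic."""
    mask = field.conductive if isinstance(field, FibrosisField) else \
        np.asarray(field, dtype=bool)
    if mask.ndim != 3:
        raise DomainError("mask must be three-dimensional")
    labels, nlab = ndimage.label(mask, structure=_STRUCTURE)
    if nlab == 0:
        return False
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = 0
    sl_hi[axis] = -1
    lo = np.unique(labels[tuple(sl_lo)])
    hi = np.unique(labels[tuple(sl_hi)])
    lo = lo[lo > 0]
    hi = hi[hi > 0]
    return bool(np.intersect1d(lo, hi, assume_unique=True).size > 0)


@dataclass
class CrossingResult:
    """Monte-Carlo crossing probability at one (geometry, φ)."""

    phi: float
    trials: int
    crossings: int
    probability: float
    ci_low: float
    ci_high: float
    seeds: np.ndarray
    wave_crossings: int | None = None  # only in wave mode


def binomial_ci(k: int, n: int, method: str = "normal") -> tuple[float, float]:
    """Binomial interval for k successes in n trials.

    ``"normal"`` (default) is +-1 standard error of the normal
    approximation, matching how the Monte-Carlo error bars are defined;
    ``"wilson"`` is the 68 % Wilson score interval, which stays sensible at
    0 or n successes.
    """
    p = k / n
    if method == "normal":
        se = np.sqrt(p * (1.0 - p) / n)
        return max(0.0, p - se), min(1.0, p + se)
    if method == "wilson":
        z = 1.0  # one standard error worth of coverage
        denom = 1.0 + z * z / n
        center = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
        return max(0.0, center - half), min(1.0, center + half)
    raise DomainError(f"unknown CI method {method!r}")


_binomial_ci = binomial_ci


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def crossing_probability(geometry: TissueGeometry, phi: float,
                         trials: int = 100, seed: int = 0, axis: int = 0,
                         mode: str = "graph", wave_kwargs: dict | None = None
                         ) -> CrossingResult:
    """Fraction of random fields that percolate, with a binomial CI.

    ``mode="wave"`` additionally propagates a planar wave through each mask
    (monodomain run, stimulus on the low face of ``axis``) and counts
    wave-through crossings; the graph result is still reported.
    """
    if trials < 1:
        raise DomainError("trials must be >= 1")
    seeds = _spawn_seeds(seed, trials)
    crossings = 0
    wave_crossings = 0 if mode == "wave" else None
    for s in seeds:
        fld = sample_fibrosis(geometry, phi, seed=int(s))
        graph_ok = percolates(fld, axis=axis)
        crossings += graph_ok
        if mode == "wave":
            wave_crossings += _wave_crosses(fld, axis, wave_kwargs or {})
    lo, hi = _binomial_ci(crossings, trials)
    return CrossingResult(phi=phi, trials=trials, crossings=crossings,
                          probability=crossings / trials, ci_low=lo,
                          ci_high=hi, seeds=seeds,
                          wave_crossings=wave_crossings)


def _wave_crosses(field: FibrosisField, axis: int, kw: dict) -> bool:
    from . import solver
    geo = field.geometry
    if field.conductive.sum() == 0:
        return False
    params = kw.get("params") or solver.MonodomainParams()
    atp = kw.get("atp", 6.0)
    site = "xyz"[axis] + "-"
    diag = np.linalg.norm(np.array(geo.shape) * geo.h)
    duration = kw.get("duration_ms", diag / 5.0 * 1000.0 + 50.0)
    rec = solver.run_simulation(
        geo, field, params, solver.StimulusProtocol(site=site),
        atp_injured=atp, duration_ms=duration,
        cell_params=kw.get("cell_params"))
    return rec.far_face_activated(axis=axis)


@dataclass
class PercolationEstimate:
    """Crossing-probability curve and interpolated threshold for one geometry."""

    geometry: dict
    phi_grid: np.ndarray
    probabilities: np.ndarray
    trials: int
    phi_th: float
    results: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"phi": r.phi, "trials": r.trials, "crossings": r.crossings,
                 "probability": r.probability, "ci_low": r.ci_low,
                 "ci_high": r.ci_high} for r in self.results]
        return pd.DataFrame(rows)


def interpolate_threshold(phi_grid: np.ndarray, probs: np.ndarray) -> float:
    """Linear interpolation of the crossing curve at probability 1/2.

    Uses the first adjacent pair bracketing 0.5 on the (noisy, nominally
    non-increasing) curve; raises :class:`RangeError` if the grid does not
    straddle the crossing.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    probs = np.asarray(probs, dtype=float)
    for i in range(phi_grid.size - 1):
        p0, p1 = probs[i], probs[i + 1]
        if p0 >= 0.5 >= p1:
            if p0 == p1:
                return float(0.5 * (phi_grid[i] + phi_grid[i + 1]))
            return float(phi_grid[i]
                         + (p0 - 0.5) / (p0 - p1) * (phi_grid[i + 1] - phi_grid[i]))
    raise RangeError(
        "crossing-probability curve does not straddle 0.5; widen the phi grid "
        f"(probabilities ranged {probs.min():.2f}..{probs.max():.2f})")


def estimate_threshold(geometry: TissueGeometry, phi_grid, trials: int = 100,
                       seed: int = 0, axis: int = 0,
                       mode: str = "graph") -> PercolationEstimate:
    """Estimate φ_th for one geometry over an explicit φ grid."""
    phi_grid = np.asarray(phi_grid, dtype=float)
    if phi_grid.size < 2 or np.any(np.diff(phi_grid) <= 0):
        raise DomainError("phi grid must be strictly increasing with >= 2 points")
    results = []
    for j, phi in enumerate(phi_grid):
        results.append(crossing_probability(geometry, float(phi), trials=trials,
                                            seed=seed + 1000003 * j, axis=axis,
                                            mode=mode))
    probs = np.array([r.probability for r in results])
    phi_th = interpolate_threshold(phi_grid, probs)
    return PercolationEstimate(geometry=geometry.describe(),
                               phi_grid=phi_grid, probabilities=probs,
                               trials=trials, phi_th=phi_th, results=results)


def threshold_curve(N_values, family: str = "slab", trials: int = 100,
                    seed: int = 0, phi_grid=None, lateral_cm: float = 4.0,
                    h: float = 0.01, return_details: bool = False):
    """φ_th versus size N for slab (lateral x lateral x N layers, crossing
    in-plane) or cube (N x N x N) families.

    With ``return_details`` also returns the long-format crossing table
    (columns N, phi, trials, crossings, probability, ci_low, ci_high).
    """
    rows = []
    details = []
    for N in N_values:
        N = int(N)
        if family == "slab":
            if N < 1:
                raise DomainError("slab thickness must be >= 1 layer")
            geo = make_slab(lateral_cm, lateral_cm, N, injured="all", h=h)
            axis = 0
        elif family == "cube":
            if N < 2:
                raise DomainError("cube side must be >= 2 cells")
            geo = make_cube(N * h, h=h)
            axis = 0
        else:
            raise DomainError(f"unknown geometry family {family!r}")
        grid = np.asarray(phi_grid if phi_grid is not None
                          else np.arange(0.30, 0.76, 0.025))
        est = estimate_threshold(geo, grid, trials=trials,
                                 seed=seed + 7919 * N, axis=axis)
        rows.append({"N": N, "phi_th": est.phi_th})
        detail = est.to_frame()
        detail.insert(0, "N", N)
        details.append(detail)
    curve = pd.DataFrame(rows)
    if return_details:
        return curve, pd.concat(details, ignore_index=True)
    return curve
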