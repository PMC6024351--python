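"""Study geometries and the stochastic diffuse-fibrosis generator.

Tissue is a regular axis-aligned grid of (100 µm)³ finite volumes — roughly
one myocyte per volume.  Diffuse fibrosis is modeled by removing volumes
independently: inside the injured region each cell is made non-conducting
(fibrotic, σ = 0) with probability φ, a per-cell Bernoulli draw.  This is the
stochastic "data" of the study; all downstream stages (monodomain runs,
percolation, Monte-Carlo reentry counts) consume fields sampled here.

Grid indexing is 0-based with x fastest; flat indices follow C order of the
``(nx, ny, nz)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError

__all__ = ["TissueGeometry", "FibrosisField", "make_slab", "make_cube",
           "sample_fibrosis"]

DEFAULT_H = 0.01  # cm = 100 µm
ATP_NORMAL = 6.0  # mM


@dataclass
class TissueGeometry:
    """Grid dimensions, spacing and region labels.

    ``injured_mask`` marks the cells that belong to the injured (hypoxic,
    potentially fibrotic) region; everything else is healthy tissue at normal
    ATP.
    """

    nx: int
    ny: int
    nz: int
    h: float = DEFAULT_H
    injured_mask: np.ndarray | None = None

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise GeometryError("grid dimensions must be >= 1")
        if self.h <= 0:
            raise GeometryError("cell edge length h must be positive")
        if self.injured_mask is None:
            self.injured_mask = np.zeros(self.shape, dtype=bool)
        else:
            self.injured_mask = np.asarray(self.injured_mask, dtype=bool)
            if self.injured_mask.shape != self.shape:
                raise GeometryError(
                    f"injured_mask shape {self.injured_mask.shape} does not "
                    f"match grid shape {self.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def volume_cm3(self) -> float:
        return self.n_cells * self.h ** 3

    @property
    def n_injured(self) -> int:
        return int(self.injured_mask.sum())

    def atp_map(self, atp_injured: float, atp_normal: float = ATP_NORMAL) -> np.ndarray:
        """Per-cell [ATP]_i (mM): ``atp_injured`` inside the injured region,
        ``atp_normal`` outside."""
        out = np.full(self.shape, float(atp_normal))
        out[self.injured_mask] = float(atp_injured)
        return out

    def describe(self) -> dict:
        return {"nx": self.nx, "ny": self.ny, "nz": self.nz, "h_cm": self.h,
                "n_cells": self.n_cells, "n_injured": self.n_injured}


@dataclass
class FibrosisField:
    """Boolean conductive mask over a geometry (False = fibrotic, σ = 0)."""

    geometry: TissueGeometry
    conductive: np.ndarray
    phi: float
    seed: int | None = None

    def __post_init__(self):
        self.conductive = np.asarray(self.conductive, dtype=bool)
        if self.conductive.shape != self.geometry.shape:
            raise GeometryError("conductive mask shape does not match geometry")
        if np.any(~self.conductive & ~self.geometry.injured_mask):
            raise GeometryError("fibrotic cells outside the injured region")

    @property
    def n_conductive(self) -> int:
        return int(self.conductive.sum())

    @property
    def realized_fraction(self) -> float:
        """Realized fibrotic fraction within the injured region."""
        n_inj = self.geometry.n_injured
        if n_inj == 0:
            return 0.0
        return float((~self.conductive[self.geometry.injured_mask]).sum() / n_inj)


def _cells_from_length(length_cm: float, h: float, what: str) -> int:
    n = round(length_cm / h)
    if n < 1:
        raise GeometryError(f"{what} = {length_cm} cm is below one cell ({h} cm)")
    if abs(n * h - length_cm) > 1e-6 * max(1.0, length_cm):
        raise GeometryError(
            f"{what} = {length_cm} cm is not divisible by h = {h} cm")
    return int(n)


def make_slab(width_cm: float, height_cm: float, n_layers: int,
              injured: str | tuple = "all", h: float = DEFAULT_H) -> TissueGeometry:
    """Rectangular slab of ``round(width/h) x round(height/h) x n_layers`` cells.

    ``injured`` is ``"all"`` (whole slab injured), ``"none"`` (healthy slab),
    or ``("disc", radius_cm)``: cells whose in-plane center lies within
    ``radius_cm`` of the slab center are injured, through all layers
    (cell-center inclusion rule).
    """
    nx = _cells_from_length(width_cm, h, "width")
    ny = _cells_from_length(height_cm, h, "height")
    if n_layers < 1:
        raise GeometryError("n_layers must be >= 1")
    geo = TissueGeometry(nx=nx, ny=ny, nz=int(n_layers), h=h)
    if injured == "all":
        geo.injured_mask[:] = True
    elif injured == "none" or injured is None:
        pass
    elif isinstance(injured, tuple) and len(injured) == 2 and injured[0] == "disc":
        radius = float(injured[1])
        if radius > min(width_cm, height_cm) / 2.0:
            raise GeometryError(
                f"disc radius {radius} cm exceeds half the slab extent")
        # cell centers at (i + 1/2) h; slab center at (nx h / 2, ny h / 2)
        cx = (np.arange(nx) + 0.5) * h - width_cm / 2.0
        cy = (np.arange(ny) + 0.5) * h - height_cm / 2.0
        disc = (cx[:, None] ** 2 + cy[None, :] ** 2) <= radius ** 2
        geo.injured_mask[:] = disc[:, :, None]
    else:
        raise GeometryError(f"unknown injured-region spec: {injured!r}")
    return geo


def make_cube(side_cm: float, h: float = DEFAULT_H) -> TissueGeometry:
    """Cube of ``round(side/h)^3`` cells, all injured."""
    if side_cm <= 0:
        raise GeometryError("cube side must be positive")
    n = _cells_from_length(side_cm, h, "side")
    geo = TissueGeometry(nx=n, ny=n, nz=n, h=h)
    geo.injured_mask[:] = True
    return geo


def sample_fibrosis(geometry: TissueGeometry, phi: float,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> FibrosisField:
    """Draw one diffuse-fibrosis realization.

    Each injured cell becomes fibrotic independently with probability φ;
    healthy-region cells are always conductive.  Reproducible from ``seed``
    (PCG64).  A uniform variate is drawn for every grid cell in fixed order,
    so for a common seed the fibrotic sets are nested across φ (common random
    numbers): φ₂ > φ₁ implies fibrotic(φ₁) ⊆ fibrotic(φ₂).
    """
    if not (0.0 <= phi <= 1.0):
        raise DomainError(f"fibrosis fraction must lie in [0, 1], got {phi}")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(geometry.shape)
    fibrotic = geometry.injured_mask & (u < phi)
    return FibrosisField(geometry=geometry, conductive=~fibrotic, phi=phi,
                         seed=seed)
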