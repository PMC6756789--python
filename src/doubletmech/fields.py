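"""Gridded vector and tensor field containers shared across the pipeline.

All fields live on regular, axis-aligned grids in a row-major layout:
``x`` runs along columns, ``y`` along rows, the origin sits at the centre
of the top-left node, indices are 0-based and angles are measured in
degrees counter-clockwise from +x.  Lengths are micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DisplacementField", "TractionField", "StressField"]


def _as_vector_grid(vectors: np.ndarray) -> np.ndarray:
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3 or vectors.shape[-1] != 2:
        raise ValueError(f"expected a (rows, cols, 2) vector grid, got {vectors.shape}")
    return vectors


@dataclass
class DisplacementField:
    """In-plane substrate displacement vectors on a regular grid.

    Parameters
    ----------
    vectors:
        ``(rows, cols, 2)`` array of (ux, uy) in µm.
    grid_spacing:
        Node spacing in µm (> 0).
    origin:
        (x0, y0) position of the first node in µm.
    valid:
        Boolean grid marking nodes whose value came from a trusted
        measurement.  Invalid nodes may carry an interpolated replacement
        or NaN.
    """

    vectors: np.ndarray
    grid_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = _as_vector_grid(self.vectors)
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.vectors.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.vectors.shape[:2]:
                raise ValueError("valid mask shape must match the vector grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    @property
    def ux(self) -> np.ndarray:
        return self.vectors[..., 0]

    @property
    def uy(self) -> np.ndarray:
        return self.vectors[..., 1]

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) node coordinate grids in µm."""
        ny, nx = self.shape
        x = self.origin[0] + self.grid_spacing * np.arange(nx)
        y = self.origin[1] + self.grid_spacing * np.arange(ny)
        return np.meshgrid(x, y)


@dataclass
class TractionField:
    """Traction vectors (Pa) the cell exerts on the substrate.

    The zero-frequency (net) component of a physically valid field is
    zero: an isolated cell or doublet exerts no net force on its
    substrate.
    """

    vectors: np.ndarray
    grid_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = _as_vector_grid(self.vectors)
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    @property
    def tx(self) -> np.ndarray:
        return self.vectors[..., 0]

    @property
    def ty(self) -> np.ndarray:
        return self.vectors[..., 1]

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    @property
    def pixel_area(self) -> float:
        """Area of one grid cell in µm²."""
        return self.grid_spacing**2

    def net_force(self) -> np.ndarray:
        """Vector sum of traction times pixel area, in pN (Pa·µm²)."""
        return self.vectors.sum(axis=(0, 1)) * self.pixel_area

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x = self.origin[0] + self.grid_spacing * np.arange(nx)
        y = self.origin[1] + self.grid_spacing * np.arange(ny)
        return np.meshgrid(x, y)


@dataclass
class StressField:
    """Symmetric 2D internal stress tensor field in Pa·µm.

    A single ``sigma_xy`` grid stores both off-diagonal entries, so the
    tensor is symmetric by construction.  Positive normal components
    denote tension, negative compression.
    """

    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    grid_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigma_xx = np.asarray(self.sigma_xx, dtype=float)
        self.sigma_yy = np.asarray(self.sigma_yy, dtype=float)
        self.sigma_xy = np.asarray(self.sigma_xy, dtype=float)
        if not (self.sigma_xx.shape == self.sigma_yy.shape == self.sigma_xy.shape):
            raise ValueError("stress component grids must share one shape")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sigma_xx.shape

    @property
    def trace(self) -> np.ndarray:
        return self.sigma_xx + self.sigma_yy

    def max_abs(self) -> float:
        return max(
            float(np.abs(self.sigma_xx).max()),
            float(np.abs(self.sigma_yy).max()),
            float(np.abs(self.sigma_xy).max()),
        )
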