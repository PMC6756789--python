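"""Bayesian inversion stress microscopy (BISM) on a rectangular domain.

Estimates the 2D internal stress tensor σ = (σxx, σyy, σxy), in Pa·µm,
whose divergence balances the measured traction t (Pa, the traction the
cell exerts on the substrate):

    ∂x σxx + ∂y σxy = tx
    ∂x σxy + ∂y σyy = ty

With this sign convention contractile cells carry positive (tensile)
normal stress.  The MAP point estimate minimizes

    ‖D σ − t‖² + Λ s² ‖σ‖²,

where D is the centered finite-difference divergence operator
(second-order one-sided stencils at domain edges), Λ the dimensionless
regularization parameter (default 10⁵) and s² = 1 / (Λ_scale · h²) a
nondimensionalizing scale (h the grid spacing in µm; Λ_scale = 10⁹ a
fixed calibration constant recorded in the output metadata).  Free
stress boundary conditions σ·n = 0 are imposed on the straight edges of
the rectangular analysis domain — the smallest rectangle encompassing
the cell doublet — by default through exact elimination of the
constrained components (a soft quadratic penalty is available via
``boundary="soft"``).

Height variations within the doublet are neglected: the stress is a 2D
tensor with units of a surface tension (Pa·µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .fields import StressField, TractionField

__all__ = [
    "BismConfig",
    "stress_domain",
    "infer_stress",
    "principal_stress",
    "divergence",
    "build_divergence_operator",
]

#: Fixed calibration constant of the dimensionless ridge; see module
#: docstring and docs/methods.md.
LAMBDA_SCALE = 1.0e9


@dataclass(frozen=True)
class BismConfig:
    """Regularization and boundary handling for the stress inversion."""

    Lambda: float = 1.0e5
    boundary: str = "hard"  # "hard" (eliminate) or "soft" (penalty)
    boundary_weight: float = 1.0e3  # dimensionless penalty, soft mode only

    def __post_init__(self) -> None:
        if self.Lambda <= 0:
            raise ValueError("Lambda must be > 0")
        if self.boundary not in ("hard", "soft"):
            raise ValueError("boundary must be 'hard' or 'soft'")


def stress_domain(
    cell_masks: np.ndarray | list[np.ndarray], margin: int = 2
) -> tuple[slice, slice]:
    """Smallest axis-aligned rectangle encompassing the cell doublet.

    Returns (row_slice, col_slice) of the mask union's bounding box
    expanded by ``margin`` nodes and clipped to the grid.
    """
    masks = np.asarray(cell_masks, dtype=bool)
    union = masks.any(axis=0) if masks.ndim == 3 else masks
    if not union.any():
        raise ValueError("empty cell masks: no domain to bound")
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    ny, nx = union.shape
    return (
        slice(max(rows[0] - margin, 0), min(rows[-1] + margin + 1, ny)),
        slice(max(cols[0] - margin, 0), min(cols[-1] + margin + 1, nx)),
    )


def _derivative_matrix(n: int, h: float) -> sparse.csr_matrix:
    """Second-order first-derivative matrix on n nodes with spacing h."""
    d = sparse.lil_matrix((n, n))
    for i in range(1, n - 1):
        d[i, i - 1] = -0.5 / h
        d[i, i + 1] = 0.5 / h
    d[0, 0], d[0, 1], d[0, 2] = -1.5 / h, 2.0 / h, -0.5 / h
    d[n - 1, n - 1], d[n - 1, n - 2], d[n - 1, n - 3] = 1.5 / h, -2.0 / h, 0.5 / h
    return d.tocsr()


def build_divergence_operator(ny: int, nx: int, h: float) -> sparse.csr_matrix:
    """Sparse divergence operator D mapping (σxx, σyy, σxy) to (tx, ty).

    Unknown ordering: the three component grids flattened row-major and
    concatenated.  Equation ordering: all tx rows, then all ty rows.
    """
    dx1 = _derivative_matrix(nx, h)
    dy1 = _derivative_matrix(ny, h)
    eye_x = sparse.identity(nx, format="csr")
    eye_y = sparse.identity(ny, format="csr")
    Dx = sparse.kron(eye_y, dx1, format="csr")
    Dy = sparse.kron(dy1, eye_x, format="csr")
    n = ny * nx
    zero = sparse.csr_matrix((n, n))
    return sparse.bmat([[Dx, zero, Dy], [zero, Dy, Dx]], format="csr")


def _boundary_constraints(ny: int, nx: int) -> np.ndarray:
    """Boolean vector marking σ components constrained to 0 (σ·n = 0).

    Left/right edges (normal ±x): σxx = σxy = 0; top/bottom edges
    (normal ±y): σyy = σxy = 0.
    """
    n = ny * nx
    constrained = np.zeros(3 * n, dtype=bool)
    idx = np.arange(n).reshape(ny, nx)
    lr = np.zeros((ny, nx), dtype=bool)
    lr[:, 0] = lr[:, -1] = True
    tb = np.zeros((ny, nx), dtype=bool)
    tb[0, :] = tb[-1, :] = True
    constrained[idx[lr]] = True            # σxx on left/right
    constrained[n + idx[tb]] = True        # σyy on top/bottom
    constrained[2 * n + idx[lr | tb]] = True  # σxy on any edge
    return constrained


def infer_stress(
    traction: TractionField,
    config: BismConfig = BismConfig(),
    domain: tuple[slice, slice] | None = None,
) -> StressField:
    """MAP estimate of the internal stress field on a rectangular domain.

    ``domain`` is a (row_slice, col_slice) rectangle (e.g. from
    :func:`stress_domain`); by default the full traction grid is used.
    The returned field covers the domain only, with ``origin`` set
    accordingly; solver diagnostics (ridge weight, divergence residual,
    boundary residual) are stored in ``StressField.meta``.
    """
    if domain is not None:
        rows, cols = domain
        vec = traction.vectors[rows, cols]
        origin = (
            traction.origin[0] + traction.grid_spacing * (cols.start or 0),
            traction.origin[1] + traction.grid_spacing * (rows.start or 0),
        )
    else:
        vec = traction.vectors
        origin = traction.origin
    ny, nx = vec.shape[:2]
    if ny < 3 or nx < 3:
        raise ValueError("stress domain must be at least 3×3 nodes")
    h = traction.grid_spacing
    n = ny * nx

    D = build_divergence_operator(ny, nx, h)
    t = np.concatenate([vec[..., 0].ravel(), vec[..., 1].ravel()])
    ridge = config.Lambda / (LAMBDA_SCALE * h * h)
    constrained = _boundary_constraints(ny, nx)

    if config.boundary == "hard":
        keep = ~constrained
        Dk = D[:, keep]
        A = (Dk.T @ Dk + ridge * sparse.identity(int(keep.sum()))).tocsc()
        sol_k = spsolve(A, Dk.T @ t)
        sol = np.zeros(3 * n)
        sol[keep] = sol_k
    else:
        w = config.boundary_weight / h
        rows_b = np.flatnonzero(constrained)
        B = sparse.csr_matrix(
            (np.full(rows_b.size, w), (np.arange(rows_b.size), rows_b)),
            shape=(rows_b.size, 3 * n),
        )
        A = (D.T @ D + B.T @ B + ridge * sparse.identity(3 * n)).tocsc()
        sol = spsolve(A, D.T @ t)

    sxx = sol[:n].reshape(ny, nx)
    syy = sol[n:2 * n].reshape(ny, nx)
    sxy = sol[2 * n:].reshape(ny, nx)
    residual = float(np.linalg.norm(D @ sol - t))
    tnorm = float(np.linalg.norm(t))
    max_abs = max(np.abs(sol).max(), np.finfo(float).tiny)
    boundary_residual = float(np.abs(sol[constrained]).max() / max_abs)
    meta = {
        "Lambda": config.Lambda,
        "lambda_scale": LAMBDA_SCALE,
        "ridge_weight": ridge,
        "boundary": config.boundary,
        "divergence_residual": residual,
        "divergence_residual_relative": residual / tnorm if tnorm else 0.0,
        "boundary_residual_relative": boundary_residual,
    }
    return StressField(sxx, syy, sxy, grid_spacing=h, origin=origin, meta=meta)


def divergence(stress: StressField) -> np.ndarray:
    """Divergence of a stress field, (rows, cols, 2) in Pa.

    Uses the same discrete operator as the inversion, so
    ``divergence(infer_stress(t)) ≈ t`` up to the regularization
    residual.
    """
    ny, nx = stress.shape
    D = build_divergence_operator(ny, nx, stress.grid_spacing)
    sol = np.concatenate([
        stress.sigma_xx.ravel(), stress.sigma_yy.ravel(),
        stress.sigma_xy.ravel(),
    ])
    t = D @ sol
    n = ny * nx
    return np.stack([t[:n].reshape(ny, nx), t[n:].reshape(ny, nx)], axis=-1)


def principal_stress(
    stress: StressField, iso_tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-node eigen-decomposition of the stress tensor.

    Returns ``(lambda1, lambda2, angle_deg, isotropic)`` with
    λ₁ ≥ λ₂ the principal stresses (Pa·µm), ``angle_deg`` the
    orientation of the λ₁ eigenvector in degrees CCW from +x (in
    (−90, 90]), and ``isotropic`` a boolean grid flagging nodes where
    the direction is undefined (λ₁ ≈ λ₂).  Suitable for the ellipse
    representation of doublet stress (tension positive, drawn red by
    convention; compression negative, blue).
    """
    sxx, syy, sxy = stress.sigma_xx, stress.sigma_yy, stress.sigma_xy
    mean = 0.5 * (sxx + syy)
    half_diff = 0.5 * (sxx - syy)
    radius = np.sqrt(half_diff**2 + sxy**2)
    lam1 = mean + radius
    lam2 = mean - radius
    angle = np.degrees(0.5 * np.arctan2(2.0 * sxy, sxx - syy))
    angle = np.where(angle <= -90.0, angle + 180.0, angle)
    angle = np.where(angle > 90.0, angle - 180.0, angle)
    scale = np.maximum(np.abs(lam1), np.abs(lam2)) + np.finfo(float).tiny
    isotropic = radius / scale < iso_tol
    return lam1, lam2, angle, isotropic
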