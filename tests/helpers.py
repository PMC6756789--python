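"""Independent (hand-assembled, dense) oracles shared by the test suite."""

import numpy as np

from doubletmech.bism import LAMBDA_SCALE


def dense_bism_solution(vec: np.ndarray, Lambda: float, h: float = 1.0):
    """Dense least-squares stress solution with explicitly written stencils.

    Assembles the centered/one-sided divergence operator with plain
    Python loops, eliminates the free-boundary components and solves the
    ridge system with ``np.linalg.lstsq`` — fully independent of the
    package's sparse path.  Returns the full (3·n,) component vector.
    """
    ny, nx = vec.shape[:2]
    n = ny * nx
    D = np.zeros((2 * n, 3 * n))

    def idx(r, c):
        return r * nx + c

    def add_deriv(row, base, r, c, axis):
        if axis == 0:  # d/dx along columns
            if 0 < c < nx - 1:
                D[row, base + idx(r, c - 1)] += -0.5 / h
                D[row, base + idx(r, c + 1)] += 0.5 / h
            elif c == 0:
                D[row, base + idx(r, 0)] += -1.5 / h
                D[row, base + idx(r, 1)] += 2.0 / h
                D[row, base + idx(r, 2)] += -0.5 / h
            else:
                D[row, base + idx(r, nx - 1)] += 1.5 / h
                D[row, base + idx(r, nx - 2)] += -2.0 / h
                D[row, base + idx(r, nx - 3)] += 0.5 / h
        else:  # d/dy along rows
            if 0 < r < ny - 1:
                D[row, base + idx(r - 1, c)] += -0.5 / h
                D[row, base + idx(r + 1, c)] += 0.5 / h
            elif r == 0:
                D[row, base + idx(0, c)] += -1.5 / h
                D[row, base + idx(1, c)] += 2.0 / h
                D[row, base + idx(2, c)] += -0.5 / h
            else:
                D[row, base + idx(ny - 1, c)] += 1.5 / h
                D[row, base + idx(ny - 2, c)] += -2.0 / h
                D[row, base + idx(ny - 3, c)] += 0.5 / h

    for r in range(ny):
        for c in range(nx):
            add_deriv(idx(r, c), 0, r, c, axis=0)           # ∂x σxx
            add_deriv(idx(r, c), 2 * n, r, c, axis=1)       # ∂y σxy
            add_deriv(n + idx(r, c), n, r, c, axis=1)       # ∂y σyy
            add_deriv(n + idx(r, c), 2 * n, r, c, axis=0)   # ∂x σxy

    constrained = np.zeros(3 * n, bool)
    for r in range(ny):
        for c in range(nx):
            if c in (0, nx - 1):
                constrained[idx(r, c)] = True
                constrained[2 * n + idx(r, c)] = True
            if r in (0, ny - 1):
                constrained[n + idx(r, c)] = True
                constrained[2 * n + idx(r, c)] = True
    keep = ~constrained
    ridge = Lambda / (LAMBDA_SCALE * h * h)
    A = np.vstack([D[:, keep], np.sqrt(ridge) * np.eye(int(keep.sum()))])
    b = np.concatenate([vec[..., 0].ravel(), vec[..., 1].ravel(),
                        np.zeros(int(keep.sum()))])
    sol_k, *_ = np.linalg.lstsq(A, b, rcond=None)
    dense = np.zeros(3 * n)
    dense[keep] = sol_k
    return dense
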