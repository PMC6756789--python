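"""Particle image velocimetry on bead image pairs.

Single-pass windowed cross-correlation with subpixel peak localization:
each interrogation window of the reference (relaxed) image is correlated
against the corresponding window of the deformed image; the correlation
peak gives the local bead displacement.  Subpixel refinement uses the
three-point Gaussian estimator (with a parabolic fallback when a log of
a non-positive correlation value would occur).  Windows failing the
peak-to-second-peak signal-to-noise test, or exceeding the displacement
bound, are marked invalid and replaced by the median of their valid
8-neighbours; nodes with no valid neighbour are left as NaN with
``valid = False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DisplacementField

__all__ = ["PivConfig", "compute_piv", "correct_drift"]


@dataclass(frozen=True)
class PivConfig:
    """Interrogation parameters for windowed cross-correlation.

    ``window_size`` must be a power of two ≥ 16; ``overlap_fraction``
    sets the node spacing to ``window_size × (1 − overlap)`` pixels.
    ``max_displacement`` defaults to a quarter window, the classical
    validity bound of single-pass PIV.
    """

    window_size: int = 32
    overlap_fraction: float = 0.5
    snr_threshold: float = 1.3
    max_displacement: float | None = None
    #: Interrogation-window weighting: "gaussian" (σ = w/4, default),
    #: "hann", or "uniform".  Weighting suppresses beads clipped at the
    #: window border, whose truncated images otherwise bias the
    #: subpixel peak fit toward zero.
    weighting: str = "gaussian"

    def __post_init__(self) -> None:
        w = self.window_size
        if w < 16 or (w & (w - 1)) != 0:
            raise ValueError("window_size must be a power of two >= 16")
        if not 0.0 <= self.overlap_fraction <= 0.75:
            raise ValueError("overlap_fraction must lie in [0, 0.75]")
        if self.snr_threshold <= 1.0:
            raise ValueError("snr_threshold must be > 1")
        if self.weighting not in ("gaussian", "hann", "uniform"):
            raise ValueError("weighting must be 'gaussian', 'hann' or 'uniform'")

    @property
    def step(self) -> int:
        return int(round(self.window_size * (1.0 - self.overlap_fraction)))

    @property
    def search_radius(self) -> float:
        if self.max_displacement is not None:
            return float(self.max_displacement)
        return self.window_size / 4.0


def compute_piv(
    reference_image: np.ndarray,
    deformed_image: np.ndarray,
    config: PivConfig = PivConfig(),
    pixel_size: float = 1.0,
) -> DisplacementField:
    """Recover the displacement field from a reference/deformed pair.

    Parameters
    ----------
    reference_image, deformed_image:
        Single-channel images of identical shape.  The reference is the
        relaxed (post-lysis) bead image.
    pixel_size:
        µm per pixel; output vectors and node geometry are in µm.

    Raises
    ------
    ValueError
        On shape mismatch or if the window does not fit at least four
        times in each image dimension.
    RuntimeError
        If every window fails validation ("no recoverable displacement").
    """
    ref = np.asarray(reference_image, dtype=float)
    def_ = np.asarray(deformed_image, dtype=float)
    if ref.shape != def_.shape:
        raise ValueError("reference and deformed images must have the same shape")
    if ref.ndim != 2:
        raise ValueError("images must be single-channel (2D)")
    w = config.window_size
    if ref.shape[0] < 4 * w or ref.shape[1] < 4 * w:
        raise ValueError("window must fit at least 4 times in each dimension")

    step = config.step
    rows = np.arange(0, ref.shape[0] - w + 1, step)
    cols = np.arange(0, ref.shape[1] - w + 1, step)
    vectors = np.full((rows.size, cols.size, 2), np.nan)
    valid = np.zeros((rows.size, cols.size), dtype=bool)

    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            a = ref[r0:r0 + w, c0:c0 + w]
            b = def_[r0:r0 + w, c0:c0 + w]
            d = _window_displacement(a, b, config)
            if d is None:
                continue
            # Discrete window offset: re-interrogate the deformed window
            # at the integer peak so matching content aligns, removing
            # the edge bias of the first pass.
            dc, dr = int(round(d[0])), int(round(d[1]))
            offset = _offset_windows(ref, def_, r0, c0, dr, dc, w)
            if offset is not None:
                a2, b2 = offset
                d2 = _window_displacement(a2, b2, config)
                if d2 is not None and np.abs(d2).max() <= config.search_radius:
                    d = d2 + np.array([dc, dr])
            vectors[i, j] = d
            valid[i, j] = True

    if not valid.any():
        raise RuntimeError("no recoverable displacement: all windows invalid")
    vectors, valid = _replace_invalid(vectors, valid)

    origin = ((w - 1) / 2.0 * pixel_size, (w - 1) / 2.0 * pixel_size)
    return DisplacementField(
        vectors * pixel_size,
        grid_spacing=step * pixel_size,
        origin=origin,
        valid=valid,
    )


def _window_displacement(
    a: np.ndarray, b: np.ndarray, config: PivConfig
) -> np.ndarray | None:
    """Displacement (dx, dy) in pixels for one window pair, or None."""
    if a.std() < 1e-12 or b.std() < 1e-12:
        return None
    weight = _window_weight(a.shape[0], config.weighting)
    a = (a - a.mean()) * weight
    b = (b - b.mean()) * weight
    # Circular cross-correlation C(s) = Σ_x a(x) b(x+s); valid because
    # displacements are bounded by a quarter window.
    corr = np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)).real
    corr = np.fft.fftshift(corr)
    w = a.shape[0]
    center = w // 2

    dy, dx = np.meshgrid(np.arange(w) - center, np.arange(w) - center,
                         indexing="ij")
    radius = config.search_radius
    search = (np.abs(dx) <= radius) & (np.abs(dy) <= radius)
    masked = np.where(search, corr, -np.inf)
    peak_flat = int(np.argmax(masked))
    pr, pc = np.unravel_index(peak_flat, corr.shape)
    peak = corr[pr, pc]
    if peak <= 0:
        return None

    # Signal-to-noise: ratio of the peak to the highest value outside a
    # 3×3 exclusion zone around it.
    excl = masked.copy()
    excl[max(pr - 1, 0):pr + 2, max(pc - 1, 0):pc + 2] = -np.inf
    second = float(excl.max())
    if second > 0 and peak / second < config.snr_threshold:
        return None

    # The peak rides on a background pedestal (mean subtraction forces
    # the correlation plane to sum to ~0); remove it before the
    # log-Gaussian fit, which is exact only for a pure Gaussian peak.
    corr = corr - np.median(corr)
    sub_c = _subpixel_offset(corr, pr, pc, axis=1)
    sub_r = _subpixel_offset(corr, pr, pc, axis=0)
    return np.array([pc - center + sub_c, pr - center + sub_r])


def _window_weight(w: int, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.ones((w, w))
    if kind == "hann":
        win = np.hanning(w)
    else:  # gaussian
        x = np.arange(w) - (w - 1) / 2.0
        win = np.exp(-(x**2) / (2.0 * (w / 4.0) ** 2))
    return np.outer(win, win)


def _offset_windows(
    ref: np.ndarray, def_: np.ndarray, r0: int, c0: int, dr: int, dc: int,
    w: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Extract window pairs offset by the integer displacement (dr, dc).

    Shifts the deformed window by the displacement where the image
    allows, sliding the reference window instead near the border, so the
    interrogated contents align and the residual correlation is
    unbiased.  Returns None when the offset exceeds the image.
    """

    def _starts(p0: int, d: int, size: int) -> tuple[int, int] | None:
        if abs(d) > size - w:
            return None
        lo, hi = (0, size - w - d) if d >= 0 else (-d, size - w)
        t = min(max(p0, lo), hi)
        return t, t + d

    rows = _starts(r0, dr, ref.shape[0])
    cols = _starts(c0, dc, ref.shape[1])
    if rows is None or cols is None:
        return None
    (tr, br), (tc, bc) = rows, cols
    return ref[tr:tr + w, tc:tc + w], def_[br:br + w, bc:bc + w]


def _subpixel_offset(corr: np.ndarray, pr: int, pc: int, axis: int) -> float:
    """Three-point Gaussian peak fit along one axis (parabolic fallback)."""
    n = corr.shape[axis]
    idx = pc if axis == 1 else pr
    if idx <= 0 or idx >= n - 1:
        return 0.0
    if axis == 1:
        cm, c0, cp = corr[pr, pc - 1], corr[pr, pc], corr[pr, pc + 1]
    else:
        cm, c0, cp = corr[pr - 1, pc], corr[pr, pc], corr[pr + 1, pc]
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        if denom != 0:
            return float((lm - lp) / denom)
    denom = cm - 2.0 * c0 + cp
    if denom != 0:
        return float(0.5 * (cm - cp) / denom)
    return 0.0


def _replace_invalid(
    vectors: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-pass local-median replacement of invalid nodes."""
    out = vectors.copy()
    ny, nx = valid.shape
    for i in range(ny):
        for j in range(nx):
            if valid[i, j]:
                continue
            r0, r1 = max(i - 1, 0), min(i + 2, ny)
            c0, c1 = max(j - 1, 0), min(j + 2, nx)
            neigh_valid = valid[r0:r1, c0:c1]
            if neigh_valid.any():
                neigh = vectors[r0:r1, c0:c1][neigh_valid]
                out[i, j] = np.median(neigh, axis=0)
            # else: left as NaN with valid = False
    return out, valid


def correct_drift(
    field: DisplacementField, background_mask: np.ndarray
) -> DisplacementField:
    """Remove rigid stage drift using a cell-free background region.

    Subtracts the median displacement over valid background nodes from
    every node.  The background mask must cover at least 5% of the grid.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != field.shape:
        raise ValueError("background mask shape must match the field grid")
    if not mask.any():
        raise ValueError("background mask is empty")
    if mask.sum() < 0.05 * mask.size:
        raise ValueError("background mask must cover at least 5% of nodes")
    use = mask & field.valid & np.isfinite(field.vectors).all(axis=-1)
    if not use.any():
        raise ValueError("no valid background nodes to estimate drift from")
    drift = np.median(field.vectors[use], axis=0)
    return DisplacementField(
        field.vectors - drift,
        grid_spacing=field.grid_spacing,
        origin=field.origin,
        valid=field.valid.copy(),
    )
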