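"""Junction-relative decomposition of traction and stress.

The cell–cell junction domain is the overlap of the two (optionally
dilated) cell masks; its skeleton midline defines the mean junction
orientation θ (total-least-squares line through the midline points).
Traction vectors inside the junction mask are projected onto the
directions parallel and perpendicular to θ and averaged (absolute
values) over centre and periphery subdomains — the mask split into four
quarters of equal node count along the θ-axis, the middle two being the
centre.  Stress tensors are rotated into the junction frame:

    σ∥ = σxx cos²θ + σyy sin²θ + 2 σxy sinθ cosθ,
    σ⊥ = σxx sin²θ + σyy cos²θ − 2 σxy sinθ cosθ,

and spatially averaged over the junction mask.  The inequality σ∥ > σ⊥
quantifies junctional stress anisotropy; isolated doublets of control
epithelial cells build up a predominantly junction-parallel tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.special import cosdg, sindg
from skimage.morphology import disk, skeletonize

from .fields import StressField, TractionField
from .fttc import summarize_mask_force

__all__ = [
    "JunctionDomain",
    "JunctionForceSummary",
    "JunctionStressSummary",
    "build_junction_domain",
    "crop_junction_domain",
    "expand_cell_masks",
    "downsample_mask",
    "quarter_split",
    "decompose_junction_forces",
    "junction_stress_components",
    "anisotropy_report",
]


@dataclass
class JunctionDomain:
    """Junction mask, ordered midline (µm) and mean orientation θ (deg).

    θ lies in (−90, 90], measured CCW from +x; it is the frame of
    reference for every junction-relative quantity.
    """

    mask: np.ndarray
    midline: np.ndarray  # (n, 2) ordered (x, y) µm
    theta: float
    grid_spacing: float = 1.0


@dataclass
class JunctionForceSummary:
    """Averaged absolute traction projections per junction subdomain (Pa)."""

    T_par_center: float
    T_perp_center: float
    T_par_periph: float
    T_perp_periph: float
    ratio_par_perp_center: float
    ratio_par_perp_periph: float


@dataclass
class JunctionStressSummary:
    """Junction-frame normal stress averages over the junction mask (Pa·µm)."""

    sigma_par: float
    sigma_perp: float


def build_junction_domain(
    mask1: np.ndarray,
    mask2: np.ndarray,
    dilation_radius: int = 2,
    grid_spacing: float = 1.0,
    orientation: str = "tls",
) -> JunctionDomain | None:
    """Junction domain from the overlap of two (dilated) cell masks.

    Each mask is dilated by a disk of ``dilation_radius`` pixels before
    intersecting, so per-cell segmentations that touch without
    overlapping still produce a junction band.  Returns ``None`` when
    the dilated masks do not intersect — the "no contact" state, as
    distinct from an error.

    ``orientation`` selects the θ estimator: ``"tls"`` (total least
    squares through the midline points, the default) or ``"chord"``
    (endpoint chord of the ordered midline).
    """
    m1 = np.asarray(mask1, dtype=bool)
    m2 = np.asarray(mask2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("cell masks must share one grid")
    if dilation_radius > 0:
        footprint = disk(dilation_radius).astype(bool)
        m1 = binary_dilation(m1, structure=footprint)
        m2 = binary_dilation(m2, structure=footprint)
    overlap = m1 & m2
    if not overlap.any():
        return None

    skel = skeletonize(overlap)
    pts_rc = np.argwhere(skel if skel.any() else overlap)
    pts = np.stack([pts_rc[:, 1], pts_rc[:, 0]], axis=1).astype(float)
    pts *= grid_spacing

    axis, theta = _tls_axis(pts)
    # Order the midline end-to-end by projection on the TLS axis; for
    # roughly straight junctions this reproduces the path order.
    proj = (pts - pts.mean(axis=0)) @ axis
    midline = pts[np.argsort(proj)]
    if orientation == "chord":
        chord = midline[-1] - midline[0]
        theta = _wrap_axis_angle(np.degrees(np.arctan2(chord[1], chord[0])))
    elif orientation != "tls":
        raise ValueError("orientation must be 'tls' or 'chord'")
    return JunctionDomain(mask=overlap, midline=midline, theta=theta,
                          grid_spacing=grid_spacing)


def _tls_axis(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares direction of a point cloud and its angle."""
    centered = pts - pts.mean(axis=0)
    if len(pts) < 2:
        return np.array([1.0, 0.0]), 0.0
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    theta = _wrap_axis_angle(np.degrees(np.arctan2(axis[1], axis[0])))
    return axis, theta


def _wrap_axis_angle(angle: float) -> float:
    """Wrap an axial (headless) angle into (−90, 90]."""
    angle = ((angle + 90.0) % 180.0) - 90.0
    if angle == -90.0:
        angle = 90.0
    return float(angle)


def quarter_split(
    jd: JunctionDomain,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node indices (rows, cols) of the junction mask split into
    centre / periphery along the junction axis.

    Nodes are ranked by their coordinate along θ and divided into four
    quarters of equal node count; remainder nodes are assigned from the
    centre outward.  Returns (node_rc, center_sel, periph_sel) where the
    selectors are boolean over the node list.
    """
    node_rc = np.argwhere(jd.mask)
    n = len(node_rc)
    axis = np.array([cosdg(jd.theta), sindg(jd.theta)])
    coords = np.stack([node_rc[:, 1], node_rc[:, 0]], axis=1) * jd.grid_spacing
    order = np.argsort(coords @ axis, kind="stable")
    base, rem = divmod(n, 4)
    sizes = np.full(4, base)
    for q in (1, 2, 0, 3):  # centre quarters first
        if rem == 0:
            break
        sizes[q] += 1
        rem -= 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    quarter = np.empty(n, dtype=int)
    for q in range(4):
        quarter[order[bounds[q]:bounds[q + 1]]] = q
    center = (quarter == 1) | (quarter == 2)
    return node_rc, center, ~center


def decompose_junction_forces(
    traction: TractionField, jd: JunctionDomain
) -> JunctionForceSummary:
    """Junction-frame traction averages over centre/periphery subdomains.

    Every in-mask traction vector is projected onto the junction
    direction (cos θ, sin θ) and its normal; the summary holds the means
    of the absolute projections per subdomain and the
    parallel/perpendicular ratios (inf when the perpendicular average
    vanishes).
    """
    if jd.mask.shape != traction.shape:
        raise ValueError("traction and junction domain must share one grid")
    node_rc, center, periph = quarter_split(jd)
    if len(node_rc) < 4:
        raise ValueError("junction mask must contain at least 4 nodes")
    # degree-exact trig keeps axis-aligned junctions free of round-off
    e_par = np.array([cosdg(jd.theta), sindg(jd.theta)])
    e_perp = np.array([-sindg(jd.theta), cosdg(jd.theta)])
    vec = traction.vectors[node_rc[:, 0], node_rc[:, 1]]
    t_par = np.abs(vec @ e_par)
    t_perp = np.abs(vec @ e_perp)

    def _ratio(p: float, q: float) -> float:
        return float(p / q) if q > 0 else float("inf")

    tpc = float(t_par[center].mean())
    tqc = float(t_perp[center].mean())
    tpp = float(t_par[periph].mean())
    tqp = float(t_perp[periph].mean())
    return JunctionForceSummary(
        T_par_center=tpc,
        T_perp_center=tqc,
        T_par_periph=tpp,
        T_perp_periph=tqp,
        ratio_par_perp_center=_ratio(tpc, tqc),
        ratio_par_perp_periph=_ratio(tpp, tqp),
    )


def junction_stress_components(
    stress: StressField, jd: JunctionDomain
) -> JunctionStressSummary:
    """Spatial averages of the junction-frame normal stresses.

    Rotates the tensor into the junction frame at the single mean
    orientation θ (the junction is treated as straight; a per-segment
    rotation changes the estimates negligibly for roughly straight
    junctions) and averages σ∥ and σ⊥ over the junction mask.
    """
    if jd.mask.shape != stress.shape:
        raise ValueError("stress and junction domain must share one grid")
    if not jd.mask.any():
        raise ValueError("junction mask is empty")
    c, s = cosdg(jd.theta), sindg(jd.theta)
    sxx = stress.sigma_xx[jd.mask]
    syy = stress.sigma_yy[jd.mask]
    sxy = stress.sigma_xy[jd.mask]
    sig_par = sxx * c * c + syy * s * s + 2.0 * sxy * s * c
    sig_perp = sxx * s * s + syy * c * c - 2.0 * sxy * s * c
    return JunctionStressSummary(
        sigma_par=float(sig_par.mean()), sigma_perp=float(sig_perp.mean())
    )


def anisotropy_report(
    stress_series: list[StressField],
    traction_series: list[TractionField],
    jd_series: list[JunctionDomain],
    times_min: np.ndarray,
    contact_index: int,
    interval_min: float = 30.0,
    n_marks: int = 6,
    window_min: float = 180.0,
):
    """Junction anisotropy table resampled at fixed marks after contact.

    For each of ``n_marks`` marks at ``interval_min`` steps after the
    contact frame (30-min marks over the first 3 h by default), the
    nearest frame (within half an interval) contributes one row with the
    junction-frame stress components, their ratio, and the
    centre/periphery traction summary.  Returns a pandas DataFrame.
    """
    import pandas as pd

    times = np.asarray(times_min, dtype=float)
    n = len(stress_series)
    if not (len(traction_series) == len(jd_series) == times.size == n):
        raise ValueError("series must be aligned and of equal length")
    if not 0 <= contact_index < n:
        raise ValueError("contact frame outside the series")

    t0 = times[contact_index]
    rows = []
    for m in range(1, n_marks + 1):
        mark = t0 + m * interval_min
        if mark - t0 > window_min:
            break
        idx = int(np.argmin(np.abs(times - mark)))
        if abs(times[idx] - mark) > interval_min / 2.0:
            continue
        ss = junction_stress_components(stress_series[idx], jd_series[idx])
        fs = decompose_junction_forces(traction_series[idx], jd_series[idx])
        ratio = ss.sigma_par / ss.sigma_perp if ss.sigma_perp != 0 else np.inf
        rows.append({
            "mark_min": mark - t0,
            "frame": idx,
            "time_min": times[idx],
            "sigma_par": ss.sigma_par,
            "sigma_perp": ss.sigma_perp,
            "ratio_par_perp": ratio,
            "T_par_center": fs.T_par_center,
            "T_perp_center": fs.T_perp_center,
            "T_par_periph": fs.T_par_periph,
            "T_perp_periph": fs.T_perp_periph,
        })
    return pd.DataFrame(rows)


def crop_junction_domain(
    jd: JunctionDomain, domain: tuple[slice, slice]
) -> JunctionDomain:
    """Restrict a junction domain to a (row_slice, col_slice) rectangle."""
    rows, cols = domain
    return JunctionDomain(mask=jd.mask[rows, cols], midline=jd.midline,
                          theta=jd.theta, grid_spacing=jd.grid_spacing)


def expand_cell_masks(
    mask1: np.ndarray, mask2: np.ndarray, margin_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Generous per-cell territories for mask-restricted force sums.

    Grows the doublet footprint by ``margin_px`` and assigns every pixel
    to the nearest cell (the junction bisector splits ties), emulating
    the generous manually drawn masks used in practice: reconstructed
    traction is spatially low-passed by the measurement chain, so a
    tight cell outline clips part of each cell's force budget.
    """
    from scipy.ndimage import distance_transform_edt

    m1 = np.asarray(mask1, dtype=bool)
    m2 = np.asarray(mask2, dtype=bool)
    d1 = distance_transform_edt(~m1)
    d2 = distance_transform_edt(~m2)
    near = np.minimum(d1, d2) <= margin_px
    return near & (d1 < d2), near & (d2 <= d1)


def downsample_mask(mask: np.ndarray, field_shape: tuple[int, int],
                    image_shape: tuple[int, int],
                    origin_px: tuple[float, float],
                    spacing_px: float) -> np.ndarray:
    """Sample a pixel-resolution mask at field node centres.

    Utility for carrying image-resolution cell masks onto the coarser
    PIV/traction node grid: node (i, j) takes the mask value at pixel
    ``origin + spacing × (j, i)`` (nearest neighbour).
    """
    mask = np.asarray(mask, dtype=bool)
    ny, nx = field_shape
    rows = np.clip(np.round(origin_px[1] + spacing_px * np.arange(ny)),
                   0, image_shape[0] - 1).astype(int)
    cols = np.clip(np.round(origin_px[0] + spacing_px * np.arange(nx)),
                   0, image_shape[1] - 1).astype(int)
    return mask[np.ix_(rows, cols)]
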