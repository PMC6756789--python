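"""Ground-truth synthetic scenes for the doublet mechanics pipeline.

This module fabricates everything the downstream stages consume, with a
known answer attached: contractile doublet traction fields that satisfy
Newton's third law exactly (zero net force; per-cell resultants equal
and opposite, of magnitude ``f_tug``), forward-modelled substrate
displacements on an elastic half-space, noisy bead image pairs, wavy
drifting junction polylines, and two-channel images with a prescribed
Pearson correlation.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, TractionField
from .substrate import SubstrateModel, greens_tensor_fourier

__all__ = [
    "SceneParams",
    "GroundTruthScene",
    "make_doublet_scene",
    "make_smooth_traction",
    "forward_displacement",
    "render_bead_images",
    "make_junction_series",
    "make_coloc_pair",
]

#: Conversion: 1 nN = 1000 pN; tractions are Pa = pN/µm².
PN_PER_NN = 1000.0


@dataclass
class SceneParams:
    """Geometry and traction parameters of a synthetic cell doublet.

    Defaults describe an MDCK-sized doublet (15 µm cell radius) on a
    128 µm field of view sampled at 0.5 µm/pixel, with peripheral
    contractile hotspots of a few hundred Pa — the regime in which
    epithelial doublets on ~30 kPa silicone gels operate.

    ``f_tug`` is the intercellular tugging force in nN transmitted
    across the junction; 0 encodes the pre-contact state.
    ``junction_angle`` is the orientation of the junction line in
    degrees CCW from +x (90° = vertical junction, cells side by side).
    """

    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5  # µm / pixel
    cell_centers: tuple[tuple[float, float], tuple[float, float]] | None = None
    cell_radius: float = 15.0  # µm
    n_hotspots_per_cell: int = 6
    hotspot_sigma: float = 3.0  # µm
    hotspot_magnitude: float = 400.0  # Pa
    f_tug: float = 0.0  # nN
    junction_angle: float = 90.0  # degrees CCW from +x
    center_separation: float | None = None  # µm; default 1.8 × radius
    seed: int = 0


@dataclass
class GroundTruthScene:
    """A doublet traction field with its exactly known decomposition."""

    traction: TractionField
    cell_masks: np.ndarray  # (2, rows, cols) bool, disjoint
    junction_polyline: np.ndarray  # (n, 2) ordered (x, y) in µm
    per_cell_resultant: np.ndarray  # (2, 2) nN; row i = cell i
    params: SceneParams = field(repr=False, default_factory=SceneParams)

    @property
    def doublet_mask(self) -> np.ndarray:
        return self.cell_masks[0] | self.cell_masks[1]


def make_doublet_scene(params: SceneParams) -> GroundTruthScene:
    """Generate a contractile doublet traction field with known resultants.

    Each cell carries ``n_hotspots_per_cell`` Gaussian traction hotspots
    pointing inward toward its own centre (contraction), clipped to the
    cell's territory and balanced per cell by a uniform compensation so
    that, before tugging, each cell's resultant is exactly zero.  When
    ``f_tug > 0`` a uniform transjunctional pair is added: cell 1's
    traction budget is shifted by −f_tug/area₁ along the junction
    normal (pointing from cell 1 to cell 2) and cell 2's by the
    opposite, so the per-cell resultants are exactly ±f_tug and the
    global sum is zero to round-off.

    Raises
    ------
    ValueError
        If ``f_tug < 0``, the cells overlap beyond the junction
        tolerance (centre separation below one cell radius), or the
        doublet plus a 10-pixel margin does not fit the grid.
    """
    if params.f_tug < 0:
        raise ValueError("f_tug must be >= 0")
    ny, nx = params.grid_shape
    h = params.pixel_size
    r = params.cell_radius
    sep = params.center_separation if params.center_separation is not None \
        else 1.8 * r

    theta_j = np.deg2rad(params.junction_angle)
    j_hat = np.array([np.cos(theta_j), np.sin(theta_j)])  # junction direction
    n_hat = np.array([np.sin(theta_j), -np.cos(theta_j)])  # junction normal

    if params.cell_centers is None:
        c0 = np.array([(nx - 1) * h / 2.0, (ny - 1) * h / 2.0])
        centers = np.array([c0 - 0.5 * sep * n_hat, c0 + 0.5 * sep * n_hat])
    else:
        centers = np.asarray(params.cell_centers, dtype=float)
        sep = float(np.linalg.norm(centers[1] - centers[0]))
        n_hat = (centers[1] - centers[0]) / sep
        j_hat = np.array([-n_hat[1], n_hat[0]])

    if sep < r:
        raise ValueError(
            "cells overlap beyond the junction tolerance "
            f"(centre separation {sep:.1f} µm < cell radius {r:.1f} µm)"
        )
    margin = 10.0 * h
    for c in centers:
        if (c[0] - r < margin or c[1] - r < margin
                or c[0] + r > (nx - 1) * h - margin
                or c[1] + r > (ny - 1) * h - margin):
            raise ValueError("doublet plus a 10-pixel margin does not fit the grid")

    X, Y = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h)
    d2 = [(X - c[0]) ** 2 + (Y - c[1]) ** 2 for c in centers]
    # Disks split along the perpendicular bisector so territories are disjoint.
    side = d2[0] - d2[1]
    masks = np.array([
        (d2[0] <= r**2) & (side < 0),
        (d2[1] <= r**2) & (side >= 0),
    ])

    rng = np.random.default_rng(params.seed)
    pixel_area = h * h
    vectors = np.zeros((ny, nx, 2))
    resultants = np.zeros((2, 2))
    # Each cell leans on the substrate against the junction pull, so its
    # resultant traction points toward the other cell; across the
    # junction this builds tension (positive σ⊥), as in a contractile
    # doublet whose peripheral tractions point inward.
    tug_dirs = (n_hat, -n_hat)
    for i, (c, mask) in enumerate(zip(centers, masks)):
        cell = np.zeros((ny, nx, 2))
        # Hotspots sit on the cell's outward-facing side: traction
        # hotspots of a doublet arise at the periphery where lamellipodia
        # form, not under the junction.
        away = c - centers.mean(axis=0)
        outward = np.arctan2(away[1], away[0])
        for _ in range(params.n_hotspots_per_cell):
            frac = rng.uniform(0.4, 0.8)
            ang = outward + rng.uniform(-0.55 * np.pi, 0.55 * np.pi)
            p = c + frac * r * np.array([np.cos(ang), np.sin(ang)])
            g = params.hotspot_magnitude * np.exp(
                -((X - p[0]) ** 2 + (Y - p[1]) ** 2)
                / (2.0 * params.hotspot_sigma**2)
            )
            direction = c - p
            direction /= np.linalg.norm(direction)
            cell[..., 0] += g * direction[0]
            cell[..., 1] += g * direction[1]
        cell *= mask[..., None]
        area = mask.sum() * pixel_area  # µm²
        net = cell.sum(axis=(0, 1)) * pixel_area  # pN
        # Per-cell balance, then the uniform transjunctional shift.
        shift = (-net + tug_dirs[i] * params.f_tug * PN_PER_NN) / area
        cell += (mask[..., None] * shift)
        vectors += cell
        resultants[i] = tug_dirs[i] * params.f_tug
    # Null the residual zero mode (round-off only; shifts per-cell
    # resultants at machine level).
    vectors -= vectors.mean(axis=(0, 1))

    half_chord = np.sqrt(max(r**2 - (sep / 2.0) ** 2, (0.25 * r) ** 2))
    mid = centers.mean(axis=0)
    s = np.linspace(-half_chord, half_chord, 33)
    polyline = mid[None, :] + s[:, None] * j_hat[None, :]

    return GroundTruthScene(
        traction=TractionField(vectors, grid_spacing=h),
        cell_masks=masks,
        junction_polyline=polyline,
        per_cell_resultant=resultants,
        params=params,
    )


def make_smooth_traction(
    grid_shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    n_pairs: int = 6,
    sigma: float = 5.0,
    magnitude: float = 300.0,
    seed: int = 0,
) -> TractionField:
    """A C∞ zero-net-force traction field built from Gaussian dipole pairs.

    Each pair places two Gaussian blobs of opposite vector amplitude at
    random positions inside the central half of the field, so the field
    is smooth, compactly supported away from the border and integrates
    to zero exactly.  Used for round-trip benchmarking of the spectral
    forward/inverse operators, where discontinuous mask-clipped fields
    would conflate reconstruction error with Gibbs ringing.
    """
    ny, nx = grid_shape
    h = pixel_size
    rng = np.random.default_rng(seed)
    X, Y = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h)
    lo = np.array([0.3 * (nx - 1) * h, 0.3 * (ny - 1) * h])
    hi = np.array([0.7 * (nx - 1) * h, 0.7 * (ny - 1) * h])
    pair_separation = 3.0 * sigma  # keeps each dipole compact (1/r² far field)
    vectors = np.zeros((ny, nx, 2))
    for _ in range(n_pairs):
        p = rng.uniform(lo, hi)
        q = p + pair_separation * _random_unit(rng)
        amp = magnitude * _random_unit(rng)
        for point, sgn in ((p, 1.0), (q, -1.0)):
            g = np.exp(-((X - point[0]) ** 2 + (Y - point[1]) ** 2)
                       / (2.0 * sigma**2))
            vectors += sgn * g[..., None] * amp[None, None, :]
    vectors -= vectors.mean(axis=(0, 1))
    return TractionField(vectors, grid_spacing=h)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(a), np.sin(a)])


def forward_displacement(
    traction: TractionField, substrate: SubstrateModel
) -> DisplacementField:
    """Substrate surface displacement produced by a traction field.

    Spectral Boussinesq forward model û(k) = Ĝ(k)·T̂(k) on a grid
    zero-padded to twice its size (wrap-around suppression); the padding
    is trimmed before return.  The zero mode is nulled: a rigid
    translation of the half-space surface is not observable.

    Raises
    ------
    ValueError
        If the traction field has a non-zero mean (subtract the mean
        first: only zero-net-force fields are physical) or E ≤ 0.
    """
    vec = traction.vectors
    scale = np.abs(vec).sum()
    if scale > 0 and np.abs(vec.sum(axis=(0, 1))).max() / scale > 1e-9:
        raise ValueError(
            "traction field has a non-zero mean; subtract the mean "
            "traction before calling forward_displacement"
        )
    ny, nx = traction.shape
    h = traction.grid_spacing
    pad = np.zeros((2 * ny, 2 * nx, 2))
    pad[:ny, :nx] = vec
    kx = 2.0 * np.pi * np.fft.fftfreq(2 * nx, d=h)
    ky = 2.0 * np.pi * np.fft.fftfreq(2 * ny, d=h)
    KX, KY = np.meshgrid(kx, ky)
    gxx, gxy, gyy = greens_tensor_fourier(
        KX, KY, substrate.youngs_modulus, substrate.poisson_ratio
    )
    tx_hat = np.fft.fft2(pad[..., 0])
    ty_hat = np.fft.fft2(pad[..., 1])
    ux_hat = gxx * tx_hat + gxy * ty_hat
    uy_hat = gxy * tx_hat + gyy * ty_hat
    ux = np.fft.ifft2(ux_hat).real[:ny, :nx]
    uy = np.fft.ifft2(uy_hat).real[:ny, :nx]
    return DisplacementField(
        np.stack([ux, uy], axis=-1), grid_spacing=h, origin=traction.origin
    )


def render_bead_images(
    displacement: DisplacementField,
    bead_density: float,
    psf_sigma: float,
    noise_sd: float,
    seed: int,
    amplitude: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a (reference, deformed) fluorescent-bead image pair.

    Beads are placed uniformly at random at continuous coordinates (so
    subpixel recovery is testable), rendered as analytic Gaussians of
    width ``psf_sigma`` (µm), and the deformed image shifts each bead by
    the locally interpolated displacement.  The reference image is the
    relaxed (cell-free) state.  Additive Gaussian noise is drawn
    independently for the two images; output is clipped at zero.

    Parameters
    ----------
    bead_density:
        Beads per µm² (> 0).
    psf_sigma:
        Gaussian point-spread width in µm; must be at least half a pixel
        or the render aliases.
    """
    if bead_density <= 0:
        raise ValueError("bead_density must be > 0")
    h = displacement.grid_spacing
    if psf_sigma < 0.5 * h:
        raise ValueError("psf_sigma must be at least 0.5 pixel")
    mean_spacing = 1.0 / np.sqrt(bead_density)
    if mean_spacing < 2.0 * psf_sigma:
        warnings.warn(
            "mean bead spacing below 2·psf_sigma: bead images will "
            "overlap heavily and PIV becomes ill-posed",
            stacklevel=2,
        )
    ny, nx = displacement.shape
    area = (ny * h) * (nx * h)
    n_beads = int(round(bead_density * area))
    rng = np.random.default_rng(seed)
    # Continuous pixel coordinates (col, row).
    pos = rng.uniform(0.0, 1.0, size=(n_beads, 2)) * np.array([nx, ny])
    ux = ndimage.map_coordinates(
        displacement.ux, [pos[:, 1], pos[:, 0]], order=1, mode="nearest"
    )
    uy = ndimage.map_coordinates(
        displacement.uy, [pos[:, 1], pos[:, 0]], order=1, mode="nearest"
    )
    shifted = pos + np.stack([ux, uy], axis=1) / h

    sigma_px = psf_sigma / h
    reference = _render_gaussians(pos, (ny, nx), sigma_px, amplitude)
    deformed = _render_gaussians(shifted, (ny, nx), sigma_px, amplitude)
    if noise_sd > 0:
        reference = reference + rng.normal(0.0, noise_sd, size=(ny, nx))
        deformed = deformed + rng.normal(0.0, noise_sd, size=(ny, nx))
    return np.clip(reference, 0.0, None), np.clip(deformed, 0.0, None)


def _render_gaussians(
    positions: np.ndarray, shape: tuple[int, int], sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    ny, nx = shape
    image = np.zeros(shape)
    half = max(int(np.ceil(4.0 * sigma_px)), 2)
    for cx, cy in positions:
        c0 = int(np.floor(cx))
        r0 = int(np.floor(cy))
        cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, nx))
        rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, ny))
        if cols.size == 0 or rows.size == 0:
            continue
        gx = np.exp(-((cols - cx) ** 2) / (2.0 * sigma_px**2))
        gy = np.exp(-((rows - cy) ** 2) / (2.0 * sigma_px**2))
        image[np.ix_(rows, cols)] += amplitude * np.outer(gy, gx)
    return image


def make_junction_series(
    length_um: float,
    waviness: float,
    drift_deg_per_frame: float,
    n_frames: int,
    seed: int,
    n_points: int = 65,
    n_waves: int = 3,
) -> list[np.ndarray]:
    """Fabricate a time series of junction midline polylines.

    Frame 0 spans ``length_um`` between its endpoints along +x, with a
    normal perturbation ``waviness · (sin + noise)`` vanishing at the
    endpoints; each subsequent frame is the previous one rigidly rotated
    by ``drift_deg_per_frame`` about the polyline centroid.  With
    ``waviness = 0`` every frame is exactly straight (straightness 1).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if length_um <= 0:
        raise ValueError("length_um must be > 0")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_points)
    base = np.stack([s * length_um, np.zeros(n_points)], axis=1)
    if waviness > 0:
        noise = rng.standard_normal(n_points)
        offsets = waviness * (np.sin(2.0 * np.pi * n_waves * s)
                              + 0.2 * noise * np.sin(np.pi * s))
        offsets[0] = offsets[-1] = 0.0
        base[:, 1] += offsets
    frames = [base]
    phi = np.deg2rad(drift_deg_per_frame)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    for _ in range(1, n_frames):
        prev = frames[-1]
        centroid = prev.mean(axis=0)
        frames.append((prev - centroid) @ rot.T + centroid)
    return frames


def make_coloc_pair(
    rho_target: float, shape: tuple[int, int], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two images whose empirical Pearson correlation equals ``rho_target``.

    A shared Gaussian field and an independent one are mixed after
    empirical orthogonalization (Gram–Schmidt on the realized samples),
    so the sample correlation hits the target to round-off, not merely
    in expectation.  Intensities are affinely shifted to a positive
    range, which leaves Pearson's r unchanged.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(shape)
    other = rng.standard_normal(shape)
    za = _standardize(shared)
    resid = other - np.mean(other * za) / np.mean(za * za) * za
    resid -= resid.mean()
    zb = resid / np.sqrt(np.mean(resid**2))
    mix = rho_target * za + np.sqrt(max(1.0 - rho_target**2, 0.0)) * zb
    image_a = 100.0 + 20.0 * za
    image_b = 100.0 + 20.0 * mix
    return image_a, image_b


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    return x / np.sqrt(np.mean(x**2))


def scene_params_to_dict(params: SceneParams) -> dict:
    """JSON-serializable view of scene parameters (seed included)."""
    d = asdict(params)
    d["grid_shape"] = list(d["grid_shape"])
    if d["cell_centers"] is not None:
        d["cell_centers"] = [list(c) for c in d["cell_centers"]]
    return d
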