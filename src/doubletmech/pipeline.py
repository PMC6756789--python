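"""End-to-end doublet analysis chain as a library function.

Chains the measurement pipeline on a ground-truth scene exactly as it
runs on experimental data — render bead images, PIV, FTTC (λ picked per
dataset at the L-curve corner), mask-restricted force summaries, BISM
stress and junction decomposition — so tests, the benchmark command and
scripts can share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bism import BismConfig, infer_stress, stress_domain
from .fields import DisplacementField, StressField, TractionField
from .fttc import (
    CellForceRecord,
    FttcConfig,
    compute_traction,
    select_lambda_lcurve,
    summarize_mask_force,
)
from .junction import (
    JunctionDomain,
    build_junction_domain,
    downsample_mask,
    expand_cell_masks,
)
from .piv import PivConfig, compute_piv
from .substrate import SubstrateModel
from .synthetic import GroundTruthScene, forward_displacement, render_bead_images

__all__ = ["ChainConfig", "ChainResult", "run_doublet_chain"]

#: Default bead-image parameters: a diffraction-limited PSF of a dry
#: 20–40× objective (σ ≈ 0.375 µm) and a bead density dense enough that
#: every interrogation window holds tens of bead images.
DEFAULT_BEAD_DENSITY = 0.4  # beads / µm²
DEFAULT_PSF_SIGMA = 0.375  # µm


@dataclass
class ChainConfig:
    bead_density: float = DEFAULT_BEAD_DENSITY
    psf_sigma: float = DEFAULT_PSF_SIGMA
    noise_sd: float = 20.0  # absolute; bead peak amplitude is 1000
    piv: PivConfig = field(default_factory=lambda: PivConfig(
        window_size=16, overlap_fraction=0.75))
    #: "lcurve" (per-dataset corner) or a number.
    fttc_lambda: float | str = "lcurve"
    mask_margin_um: float = 8.0
    bism: BismConfig = field(default_factory=BismConfig)
    with_stress: bool = True
    junction_dilation_px: int = 2


@dataclass
class ChainResult:
    displacement: DisplacementField
    traction: TractionField
    fttc_lambda: float
    cell_records: dict[str, CellForceRecord]
    node_masks: dict[str, np.ndarray]
    stress: StressField | None = None
    junction: JunctionDomain | None = None

    @property
    def newton_ratio(self) -> float:
        """|doublet resultant| / Σ|T|·a over the doublet mask."""
        doublet = self.node_masks["cell1"] | self.node_masks["cell2"]
        total = (self.traction.magnitude[doublet].sum()
                 * self.traction.pixel_area) / 1000.0
        return self.cell_records["doublet"].resultant_magnitude / total

    def antiparallel_angle(self) -> float:
        """Angle (deg) between the two per-cell resultants; 180 = opposite."""
        f1 = self.cell_records["cell1"].resultant_force
        f2 = self.cell_records["cell2"].resultant_force
        cos = np.dot(f1, f2) / (np.linalg.norm(f1) * np.linalg.norm(f2))
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def run_doublet_chain(
    scene: GroundTruthScene,
    substrate: SubstrateModel,
    config: ChainConfig = ChainConfig(),
    seed: int = 0,
) -> ChainResult:
    """Measure a ground-truth scene through the full analysis chain."""
    pixel = scene.traction.grid_spacing
    disp_true = forward_displacement(scene.traction, substrate)
    reference, deformed = render_bead_images(
        disp_true, bead_density=config.bead_density,
        psf_sigma=config.psf_sigma, noise_sd=config.noise_sd, seed=seed,
    )
    disp = compute_piv(reference, deformed, config.piv, pixel_size=pixel)

    fcfg = FttcConfig(substrate=substrate)
    if config.fttc_lambda == "lcurve":
        lam = select_lambda_lcurve(disp, fcfg)
    else:
        lam = float(config.fttc_lambda)
    traction = compute_traction(
        disp, FttcConfig(regularization_lambda=lam, substrate=substrate)
    )

    image_shape = scene.cell_masks[0].shape
    spacing_px = disp.grid_spacing / pixel
    origin_px = (disp.origin[0] / pixel, disp.origin[1] / pixel)
    gen1, gen2 = expand_cell_masks(
        scene.cell_masks[0], scene.cell_masks[1],
        margin_px=config.mask_margin_um / pixel,
    )
    node_masks = {
        "cell1": downsample_mask(gen1, traction.shape, image_shape,
                                 origin_px, spacing_px),
        "cell2": downsample_mask(gen2, traction.shape, image_shape,
                                 origin_px, spacing_px),
    }
    records = {
        label: summarize_mask_force(traction, mask, mask_id=label)
        for label, mask in node_masks.items()
    }
    records["doublet"] = summarize_mask_force(
        traction, node_masks["cell1"] | node_masks["cell2"],
        mask_id="doublet",
    )

    stress = None
    jd = None
    if config.with_stress:
        tight = {
            label: downsample_mask(scene.cell_masks[i], traction.shape,
                                   image_shape, origin_px, spacing_px)
            for i, label in enumerate(("cell1", "cell2"))
        }
        domain = stress_domain(np.array([tight["cell1"], tight["cell2"]]))
        stress = infer_stress(traction, config.bism, domain)
        jd = build_junction_domain(
            tight["cell1"], tight["cell2"],
            dilation_radius=config.junction_dilation_px,
            grid_spacing=traction.grid_spacing,
        )
    return ChainResult(
        displacement=disp, traction=traction, fttc_lambda=lam,
        cell_records=records, node_masks=node_masks, stress=stress,
        junction=jd,
    )
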