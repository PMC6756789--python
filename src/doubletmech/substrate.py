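"""Elastic substrate model and the Boussinesq surface Green's function.

The substrate is treated as a semi-infinite, homogeneous, isotropic
elastic half-space.  For in-plane surface tractions the displacement
response is given, in Fourier space, by the classical Boussinesq
solution

    û(k) = Ĝ(k) · T̂(k),

    Ĝ(k) = (2 (1+ν) / (E k³)) · [[(1−ν) k² + ν ky²,  −ν kx ky],
                                  [−ν kx ky,  (1−ν) k² + ν kx²]],

with E the Young's modulus (Pa), ν the Poisson ratio and k = |k| in
rad/µm, so that Ĝ carries µm/Pa.  Both the forward model (synthetic
scenes) and the traction reconstruction (FTTC) use this tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubstrateModel",
    "SUBSTRATE_PRESETS",
    "greens_tensor_fourier",
    "greens_tensor_real",
]

#: Named silicone-gel presets: stiffer gels for fibronectin coating,
#: softer for E-cadherin coating.
SUBSTRATE_PRESETS: dict[str, float] = {
    "fibronectin_30kPa": 30_000.0,
    "ecadherin_15kPa": 15_000.0,
}


@dataclass(frozen=True)
class SubstrateModel:
    """Elastic half-space parameters plus the camera sampling.

    ``poisson_ratio`` defaults to 0.5 (incompressible silicone gel).
    """

    youngs_modulus: float  # Pa
    poisson_ratio: float = 0.5
    pixel_size: float = 1.0  # µm / pixel

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @classmethod
    def from_preset(cls, name: str, pixel_size: float = 1.0,
                    poisson_ratio: float = 0.5) -> "SubstrateModel":
        try:
            E = SUBSTRATE_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown substrate preset {name!r}; "
                f"available: {sorted(SUBSTRATE_PRESETS)}"
            ) from None
        return cls(youngs_modulus=E, poisson_ratio=poisson_ratio,
                   pixel_size=pixel_size)


def greens_tensor_fourier(
    kx: np.ndarray, ky: np.ndarray, E: float, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq Green's tensor in Fourier space.

    Parameters
    ----------
    kx, ky:
        Wavevector component grids in rad/µm.
    E, nu:
        Young's modulus (Pa) and Poisson ratio.

    Returns
    -------
    (Gxx, Gxy, Gyy) grids in µm/Pa.  The k = 0 entry is set to 0 (the
    rigid-translation mode carries no elastic information).
    """
    if E <= 0:
        raise ValueError("Young's modulus must be > 0")
    k2 = kx**2 + ky**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k3 = k2**1.5
        pref = 2.0 * (1.0 + nu) / (E * k3)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        gxy = -pref * nu * kx * ky
    zero = k2 == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def greens_tensor_real(
    dx: np.ndarray, dy: np.ndarray, E: float, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real-space Boussinesq surface Green's function.

    u_i(r) = (1+ν)/(π E) [ (1−ν) δ_ij / r + ν r_i r_j / r³ ] F_j

    for a tangential point force F at the origin of the half-space
    surface.  Used as an independent quadrature oracle for the spectral
    forward model; singular at r = 0 (entries there are set to 0 and
    must be excluded by the caller).
    """
    r2 = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(r2)
        pref = (1.0 + nu) / (np.pi * E)
        gxx = pref * ((1.0 - nu) / r + nu * dx * dx / (r2 * r))
        gyy = pref * ((1.0 - nu) / r + nu * dy * dy / (r2 * r))
        gxy = pref * nu * dx * dy / (r2 * r)
    zero = r2 == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy
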