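"""Built-in property checks over the whole pipeline.

Runs quick self-verification on synthetic ground truth: forward/inverse
round trip, regularization benefit on noisy data, Tikhonov and ridge
shrinkage monotonicity, and the divergence residual of the stress
inversion.  Each check reports a measured value, its bound and a
pass/fail flag; the CLI ``benchmark`` command serializes the result.
"""

from __future__ import annotations

import numpy as np

from .bism import BismConfig, infer_stress
from .fields import DisplacementField, TractionField
from .fttc import FttcConfig, compute_traction
from .substrate import SubstrateModel
from .synthetic import forward_displacement, make_smooth_traction

__all__ = ["run_benchmark"]


def _check(value: float, bound: float, smaller_is_better: bool = True) -> dict:
    passed = value <= bound if smaller_is_better else value >= bound
    return {"value": float(value), "bound": float(bound),
            "passed": bool(passed)}


def run_benchmark(seed: int = 0) -> dict:
    sub = SubstrateModel(30_000.0, 0.5, 1.0)
    truth = make_smooth_traction((128, 128), 1.0, seed=seed)
    disp = forward_displacement(truth, sub)

    out: dict = {"seed": seed}

    # Forward/inverse round trip, unregularized, noise-free.
    rec = compute_traction(
        disp, FttcConfig(regularization_lambda=0.0, substrate=sub)
    )
    b = 2
    err = (np.linalg.norm((rec.vectors - truth.vectors)[b:-b, b:-b])
           / np.linalg.norm(truth.vectors[b:-b, b:-b]))
    out["fttc_roundtrip_rel_error"] = _check(err, 0.05)

    # Regularization benefit at 5% displacement noise.
    rng = np.random.default_rng(seed + 1)
    rms = float(np.sqrt((disp.vectors**2).mean()))
    noisy = DisplacementField(
        disp.vectors + rng.normal(0.0, 0.05 * rms, disp.vectors.shape),
        disp.grid_spacing,
    )
    err0 = _rel_error(noisy, truth, sub, 0.0)
    err_reg = _rel_error(noisy, truth, sub, None)
    out["fttc_noisy_rel_error"] = _check(err_reg, 0.20)
    out["fttc_regularization_benefit"] = _check(err_reg, err0)

    # Tikhonov shrinkage: traction energy non-increasing in λ.
    norms = [
        float(np.linalg.norm(compute_traction(
            noisy, FttcConfig(regularization_lambda=lam, substrate=sub)
        ).vectors))
        for lam in (0.0, 0.02, 0.1, 0.5)
    ]
    mono = all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))
    out["fttc_shrinkage_monotone"] = {"norms": norms, "passed": mono}

    # BISM: ridge shrinkage in Λ and divergence residual.
    strip = _strip_traction()
    snorms = []
    for Lam in (1e3, 1e5, 1e7):
        sf = infer_stress(strip, BismConfig(Lambda=Lam))
        snorms.append(float(np.sqrt(
            (sf.sigma_xx**2 + sf.sigma_yy**2 + 2 * sf.sigma_xy**2).sum()
        )))
    mono = all(a >= b - 1e-9 for a, b in zip(snorms, snorms[1:]))
    out["bism_shrinkage_monotone"] = {"norms": snorms, "passed": mono}
    sf = infer_stress(strip, BismConfig())
    out["bism_divergence_residual"] = _check(
        sf.meta["divergence_residual_relative"], 0.05
    )
    return out


def _rel_error(
    noisy: DisplacementField, truth: TractionField, sub: SubstrateModel,
    lam: float | None,
) -> float:
    cfg = (FttcConfig(substrate=sub) if lam is None
           else FttcConfig(regularization_lambda=lam, substrate=sub))
    rec = compute_traction(noisy, cfg)
    return float(np.linalg.norm(rec.vectors - truth.vectors)
                 / np.linalg.norm(truth.vectors))


def _strip_traction(nx: int = 41, ny: int = 9, t0: float = 1.0) -> TractionField:
    x = (np.arange(nx) - (nx - 1) / 2.0)
    tx = -t0 * np.sign(x)[None, :].repeat(ny, axis=0)
    return TractionField(np.stack([tx, np.zeros_like(tx)], axis=-1), 1.0)
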