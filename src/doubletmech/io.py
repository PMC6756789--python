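"""File round-trips for the pipeline's tabular and image artifacts.

Vector fields travel as CSV (one node per row, µm/Pa/Pa·µm units in the
headers), bead images as 16-bit grayscale TIFF, polylines as ordered
(x, y) CSV in µm, and configuration/scene metadata as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fields import DisplacementField, StressField, TractionField

__all__ = [
    "save_displacement_csv", "load_displacement_csv",
    "save_traction_csv", "load_traction_csv",
    "save_stress_csv", "load_stress_csv",
    "save_polyline_csv", "load_polyline_csv",
    "save_image_tiff", "load_image_tiff",
    "save_mask_tiff", "load_mask_tiff",
    "save_json", "load_json",
]


def _grid_frame(field, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    X, Y = field.node_coords()
    data = {"x_um": X.ravel(), "y_um": Y.ravel()}
    data.update({k: v.ravel() for k, v in columns.items()})
    return pd.DataFrame(data)


def _grid_from_frame(df: pd.DataFrame) -> tuple[int, int, float, tuple[float, float]]:
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    spacing = float(x[1] - x[0]) if x.size > 1 else float(y[1] - y[0])
    return y.size, x.size, spacing, (float(x[0]), float(y[0]))


def save_displacement_csv(path: str | Path, field: DisplacementField) -> None:
    df = _grid_frame(field, {
        "ux_um": field.ux, "uy_um": field.uy, "valid": field.valid,
    })
    df.to_csv(path, index=False)


def load_displacement_csv(path: str | Path) -> DisplacementField:
    df = pd.read_csv(path)
    ny, nx, spacing, origin = _grid_from_frame(df)
    vectors = np.stack(
        [df["ux_um"].to_numpy().reshape(ny, nx),
         df["uy_um"].to_numpy().reshape(ny, nx)], axis=-1)
    valid = df["valid"].to_numpy().astype(bool).reshape(ny, nx)
    return DisplacementField(vectors, grid_spacing=spacing, origin=origin,
                             valid=valid)


def save_traction_csv(path: str | Path, field: TractionField) -> None:
    df = _grid_frame(field, {"Tx_Pa": field.tx, "Ty_Pa": field.ty})
    df.to_csv(path, index=False)


def load_traction_csv(path: str | Path) -> TractionField:
    df = pd.read_csv(path)
    ny, nx, spacing, origin = _grid_from_frame(df)
    vectors = np.stack(
        [df["Tx_Pa"].to_numpy().reshape(ny, nx),
         df["Ty_Pa"].to_numpy().reshape(ny, nx)], axis=-1)
    return TractionField(vectors, grid_spacing=spacing, origin=origin)


def save_stress_csv(path: str | Path, field: StressField) -> None:
    X, Y = np.meshgrid(
        field.origin[0] + field.grid_spacing * np.arange(field.shape[1]),
        field.origin[1] + field.grid_spacing * np.arange(field.shape[0]),
    )
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "sxx_Pa_um": field.sigma_xx.ravel(),
        "syy_Pa_um": field.sigma_yy.ravel(),
        "sxy_Pa_um": field.sigma_xy.ravel(),
    }).to_csv(path, index=False)


def load_stress_csv(path: str | Path) -> StressField:
    df = pd.read_csv(path)
    ny, nx, spacing, origin = _grid_from_frame(df)
    return StressField(
        df["sxx_Pa_um"].to_numpy().reshape(ny, nx),
        df["syy_Pa_um"].to_numpy().reshape(ny, nx),
        df["sxy_Pa_um"].to_numpy().reshape(ny, nx),
        grid_spacing=spacing, origin=origin,
    )


def save_polyline_csv(path: str | Path, polyline: np.ndarray) -> None:
    pts = np.asarray(polyline, dtype=float)
    pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]}).to_csv(path, index=False)


def load_polyline_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.stack([df["x_um"].to_numpy(), df["y_um"].to_numpy()], axis=1)


def save_image_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write an intensity image as 16-bit grayscale TIFF (clipped)."""
    img = np.clip(np.asarray(image, dtype=float), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), img.astype(np.uint16))


def load_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def save_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
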