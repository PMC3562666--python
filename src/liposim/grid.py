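"""1D axisymmetric finite-volume grid for the disc-shaped tissue domain.

The domain is a central circular tumour of radius ``r_tumour`` surrounded by
an annular shell of normal tissue of thickness ``t_normal``.  Geometry,
boundary conditions and parameters are all radially symmetric, so the 2D
disc reduces exactly to a 1D radial problem.  Cells are concentric annuli:
scalar unknowns live at cell centres, fluxes at faces, and the
tumour/normal interface coincides with a face so that interface continuity
is the natural flux matching of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NORMAL, TUMOUR

__all__ = ["RadialGrid", "build_grid", "spatial_mean"]


@dataclass(frozen=True)
class RadialGrid:
    r_faces: np.ndarray   # face radii (m), r_faces[0] == 0
    r_centers: np.ndarray  # cell-centre radii (m)
    areas: np.ndarray     # annular areas per unit depth (m^2)
    region: np.ndarray    # per-cell region label ('tumour' | 'normal')

    @property
    def n_cells(self) -> int:
        return self.r_centers.size

    @property
    def r_outer(self) -> float:
        return float(self.r_faces[-1])

    def mask(self, region: str) -> np.ndarray:
        """Boolean cell mask for 'tumour', 'normal' or 'all'."""
        if region == "all":
            return np.ones(self.n_cells, dtype=bool)
        if region not in (TUMOUR, NORMAL):
            raise ValueError(f"unknown region {region!r}")
        return self.region == region

    @property
    def interface_index(self) -> int:
        """Face index of the tumour/normal interface."""
        return int(np.sum(self.region == TUMOUR))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_center": self.r_centers,
            "area": self.areas,
            "region": self.region,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_grid(n_tumour: int, n_normal: int,
               r_tumour: float = 0.025, t_normal: float = 0.010) -> RadialGrid:
    """Build a radial grid with uniform spacing within each region.

    Parameters
    ----------
    n_tumour, n_normal
        Number of control volumes in the tumour and the normal shell
        (each at least 2).
    r_tumour
        Tumour radius (m); the region boundary falls exactly on a face here.
    t_normal
        Thickness of the normal-tissue shell (m).
    """
    if n_tumour < 2 or n_normal < 2:
        raise ValueError("need at least 2 cells per region")
    if r_tumour <= 0 or t_normal <= 0:
        raise ValueError("radii must be positive")
    f_t = np.linspace(0.0, r_tumour, n_tumour + 1)
    f_n = np.linspace(r_tumour, r_tumour + t_normal, n_normal + 1)
    r_faces = np.concatenate([f_t, f_n[1:]])
    r_centers = 0.5 * (r_faces[:-1] + r_faces[1:])
    areas = np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)
    region = np.array([TUMOUR] * n_tumour + [NORMAL] * n_normal)
    return RadialGrid(r_faces=r_faces, r_centers=r_centers,
                      areas=areas, region=region)


def spatial_mean(field: np.ndarray, grid: RadialGrid,
                 region: str = "all") -> float:
    """Area-weighted mean of a per-cell field over a region."""
    field = np.asarray(field, dtype=float)
    if field.shape[-1] != grid.n_cells:
        raise ValueError(
            f"field has {field.shape[-1]} cells, grid has {grid.n_cells}")
    m = grid.mask(region)
    w = grid.areas[m]
    res = np.sum(field[..., m] * w, axis=-1) / np.sum(w)
    return float(res) if np.ndim(res) == 0 else res
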