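"""Steady interstitial fluid flow: Darcy pressure field with Starling sources.

The interstitium is treated as a rigid porous medium.  At steady state,
mass conservation of the (incompressible) interstitial fluid reads

    div(v) = Fv - Fly,      v = -(kappa/mu) grad(p_i),

where ``Fv`` is the transvascular filtration rate given by Starling's law
and ``Fly`` the lymphatic drainage rate, both linear in the interstitial
pressure ``p_i``.  The momentum balance reduces to Darcy's law because the
interstitial velocities are tiny (creeping flow; inertial and viscous-shear
contributions are negligible at these Darcy numbers).  The resulting
problem is linear in ``p_i`` and is solved in one pass as a tridiagonal
system on the radial grid; the frozen pressure/velocity field then drives
all drug-transport equations (one-way coupling).

Boundary conditions: symmetry (zero flux) at r = 0 and a fixed relative
pressure of 0 Pa at the outer surface of the normal shell.  The
tumour/normal conductivity jump is handled with harmonic-mean face
conductivities, which enforce flux continuity at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .config import TissueParams, TUMOUR
from .grid import RadialGrid

__all__ = ["FlowField", "starling_source", "lymph_sink", "solve_ifp"]


def starling_source(p_i, tissue: TissueParams):
    """Transvascular filtration rate Fv (1/s) at interstitial pressure p_i.

    Fv = Kv*(S/V)*[p_v - p_i - sigma_T*(pi_v - pi_i)].  Negative values mean
    fluid reabsorption into the vasculature.
    """
    return tissue.kv * tissue.sv_ratio * (tissue.effective_pressure - np.asarray(p_i))


def lymph_sink(p_i, tissue: TissueParams):
    """Lymphatic drainage rate Fly (1/s): (K_ly*S_ly/V)*(p_i - p_ly)."""
    return tissue.kly_sly_v * (np.asarray(p_i) - tissue.p_ly)


@dataclass(frozen=True)
class FlowField:
    """Steady interstitial flow solution on a radial grid."""

    grid: RadialGrid
    p_i: np.ndarray     # cell-centre interstitial fluid pressure (Pa)
    v_face: np.ndarray  # radial Darcy velocity at faces (m/s), outward > 0
    fv: np.ndarray      # filtration rate per cell (1/s)
    fly: np.ndarray     # lymphatic drainage rate per cell (1/s)

    def mass_balance_residual(self) -> float:
        """Relative defect of global fluid balance.

        Net volumetric source must equal the outward boundary flux:
        sum((Fv - Fly) * area) = 2*pi*r_outer*v_outer.
        """
        src = float(np.sum((self.fv - self.fly) * self.grid.areas))
        out = 2.0 * np.pi * self.grid.r_outer * float(self.v_face[-1])
        scale = max(abs(src), abs(out), 1e-300)
        return abs(src - out) / scale

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_center": self.grid.r_centers,
            "p_i": self.p_i,
            "v": 0.5 * (self.v_face[:-1] + self.v_face[1:]),
            "Fv": self.fv,
            "Fly": self.fly,
            "region": self.grid.region,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cellwise(grid: RadialGrid, tumour: TissueParams, normal: TissueParams):
    """Per-cell parameter arrays (kappa/mu, Kv*S/V, effective p, lymph)."""
    tum = grid.mask(TUMOUR)
    pick = lambda a, b: np.where(tum, a, b)
    km = pick(tumour.kappa / tumour.mu, normal.kappa / normal.mu)
    kvsv = pick(tumour.kv * tumour.sv_ratio, normal.kv * normal.sv_ratio)
    pe = pick(tumour.effective_pressure, normal.effective_pressure)
    kly = pick(tumour.kly_sly_v, normal.kly_sly_v)
    ply = pick(tumour.p_ly, normal.p_ly)
    return km, kvsv, pe, kly, ply


def solve_ifp(grid: RadialGrid, tumour: TissueParams,
              normal: TissueParams) -> FlowField:
    """Solve the steady interstitial pressure problem on ``grid``.

    Returns the converged :class:`FlowField` with pressure at cell centres,
    Darcy velocity at faces (harmonic-mean face conductivity), and the
    filtration/drainage rates evaluated from the converged pressure.
    """
    n = grid.n_cells
    km, kvsv, pe, kly, ply = _cellwise(grid, tumour, normal)
    if np.all(kvsv == 0) and np.all(kly == 0):
        raise ValueError("all source conductances are zero: singular problem")

    rc, rf, area = grid.r_centers, grid.r_faces, grid.areas

    # face conductances g (m^2/Pa/s per unit depth): internal faces 1..n-1
    dr = rc[1:] - rc[:-1]
    km_face = 2.0 * km[:-1] * km[1:] / (km[:-1] + km[1:])
    g_int = 2.0 * np.pi * rf[1:-1] * km_face / dr
    # outer Dirichlet face (p = 0): half-cell conductance
    g_out = 2.0 * np.pi * rf[-1] * km[-1] / (rf[-1] - rc[-1])

    diag = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    diag[:-1] += g_int
    diag[1:] += g_int
    upper -= g_int
    lower -= g_int
    diag[-1] += g_out
    diag += area * (kvsv + kly)
    rhs = area * (kvsv * pe + kly * ply)

    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    p = solve_banded((1, 1), ab, rhs)

    v_face = np.zeros(n + 1)
    v_face[1:-1] = -km_face * (p[1:] - p[:-1]) / dr
    v_face[-1] = -km[-1] * (0.0 - p[-1]) / (rf[-1] - rc[-1])

    fv = kvsv * (pe - p)
    fly = kly * (p - ply)
    return FlowField(grid=grid, p_i=p, v_face=v_face, fv=fv, fly=fly)
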