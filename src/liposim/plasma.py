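"""Plasma pharmacokinetic drivers.

Two delivery modes are supported:

* **Direct infusion** — the total plasma drug concentration follows the
  closed-form triexponential response of a three-compartment model to a
  constant-rate infusion of dose ``D`` over duration ``T``; free and bound
  plasma concentrations are the fixed split (1-s, s) of that total, with a
  bound fraction s = 0.75.

* **Liposomal delivery** — the encapsulated plasma concentration is a
  prescribed biexponential decay (the circulating liposome pool is not
  depleted by the heat-triggered release), while the free and bound drug
  concentrations in plasma obey a pair of ODEs driven by release from
  circulating liposomes, protein binding/dissociation, first-order plasma
  clearance, and transcapillary loss to the tumour interstitium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BindingUptakeParams, PlasmaPKParams

__all__ = ["PlasmaState", "infusion_plasma_conc", "split_bound",
           "liposome_plasma_conc", "plasma_free_bound_rhs"]


@dataclass
class PlasmaState:
    """Plasma concentrations (kg/m^3) at time t (s)."""

    t: float
    c_lp: float = 0.0  # liposome-encapsulated drug
    c_fp: float = 0.0  # free drug
    c_bp: float = 0.0  # protein-bound drug


def infusion_plasma_conc(t, pk: PlasmaPKParams):
    """Total plasma concentration Cv(t) (kg/m^3) for a constant-rate infusion.

    Piecewise triexponential: during the infusion (t < T) each compartment
    rises as (A_j/alpha_j)(1 - exp(-alpha_j t)); afterwards it decays as
    (A_j/alpha_j)(exp(alpha_j T) - 1) exp(-alpha_j t).  The two branches
    are algebraically continuous at t = T.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    rate = pk.dose / pk.t_inf
    out = np.zeros_like(t)
    during = t < pk.t_inf
    after = ~during
    for a_j, k_j in ((pk.A, pk.alpha), (pk.B, pk.beta), (pk.C, pk.gamma)):
        out = out + np.where(
            during,
            (a_j / k_j) * -np.expm1(-k_j * t),
            # exp(kT - kt) - exp(-kt), written to stay finite for large kT
            (a_j / k_j) * (np.exp(np.minimum(k_j * (pk.t_inf - t), 0.0))
                           - np.exp(-k_j * np.where(after, t, pk.t_inf))),
        )
    out = rate * out
    return float(out) if out.ndim == 0 else out


def split_bound(cv, s: float):
    """Split a total plasma concentration into (free, bound) = ((1-s)Cv, sCv)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("bound fraction must lie in [0, 1]")
    cv = np.asarray(cv, dtype=float)
    free, bound = (1.0 - s) * cv, s * cv
    if cv.ndim == 0:
        return float(free), float(bound)
    return free, bound


def liposome_plasma_conc(t, pk: PlasmaPKParams):
    """Encapsulated plasma concentration A1*exp(-k1 t) + A2*exp(-k2 t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = pk.A1 * np.exp(-pk.k1 * t) + pk.A2 * np.exp(-pk.k2 * t)
    return float(out) if out.ndim == 0 else out


def plasma_free_bound_rhs(state: PlasmaState, mean_ffp: float, mean_fbe: float,
                          krel_now: float, pk: PlasmaPKParams,
                          binding: BindingUptakeParams) -> tuple[float, float]:
    """Time derivatives (dC_fp/dt, dC_bp/dt) for liposome-mode plasma drug.

    ``mean_ffp`` and ``mean_fbe`` are the tumour-volume-averaged
    transcapillary fluxes of free and bound drug (kg/m^3/s) leaving plasma,
    supplied by the tissue-transport solver; ``krel_now`` is the current
    release rate acting on the circulating liposome pool.
    """
    exch = binding.ka * state.c_fp - binding.kd * state.c_bp
    d_fp = (krel_now * state.c_lp - pk.vt_over_vb * mean_ffp
            - pk.cl_fp * state.c_fp - exch)
    d_bp = exch - pk.vt_over_vb * mean_fbe - pk.cl_bp * state.c_bp
    return d_fp, d_bp
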