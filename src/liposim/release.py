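"""Heat-triggered liposome release kinetics and the step heating schedule.

Thermosensitive liposomes retain their payload at 37 C and release it by
first-order kinetics once heated to the membrane phase-transition
temperature (42 C).  Heating is modelled as a step change, localised to the
tumour region: during the heating window the tumour release rate switches
to ``krel_42`` and the vascular permeabilities to free drug and liposome
are scaled by their hyperthermia fold-factors; normal tissue stays at 37 C
throughout.

The module also provides the nonlinear least-squares fit of the
release-vs-time saturation curve ``R(t) = Rc*(1 - exp(-krel*t))`` used to
calibrate the release rate from in-vitro release-percentage measurements,
plus a synthetic-curve generator for producing such measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import HeatingSchedule, NORMAL, TUMOUR

__all__ = ["ThermalState", "thermal_state", "release_fraction",
           "fit_release_rate", "generate_release_curve"]

T37 = 37.0
T42 = 42.0


@dataclass(frozen=True)
class ThermalState:
    """Per-region temperature, release rate and permeability multipliers."""

    temperature: dict      # region -> temperature (C)
    krel: dict             # region -> current release rate (1/s)
    perm_scale_free: dict  # region -> free-drug permeability multiplier
    perm_scale_lip: dict   # region -> liposome permeability multiplier

    @property
    def tumour_heated(self) -> bool:
        return self.temperature[TUMOUR] == T42


def thermal_state(t: float, schedule: HeatingSchedule,
                  h_free: float = 2.56, h_lip: float = 71.0) -> ThermalState:
    """Thermal state at time ``t``; a pure function of ``t``.

    The tumour is at 42 C iff t_on <= t < t_on + t_dur; normal tissue is
    always at 37 C.  At 42 C the free-drug and liposome permeability
    multipliers take their hyperthermia values and the release rate is
    ``krel_42``; at 37 C both multipliers are 1 and the release rate is 0.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    hot = schedule.t_on <= t < schedule.t_on + schedule.t_dur
    return ThermalState(
        temperature={TUMOUR: T42 if hot else T37, NORMAL: T37},
        krel={TUMOUR: schedule.krel_42 if hot else schedule.krel_37,
              NORMAL: schedule.krel_37},
        perm_scale_free={TUMOUR: h_free if hot else 1.0, NORMAL: 1.0},
        perm_scale_lip={TUMOUR: h_lip if hot else 1.0, NORMAL: 1.0},
    )


def release_fraction(t, rc: float, krel: float):
    """Cumulative released fraction Rc*(1 - exp(-krel*t)) at exposure time t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("exposure time must be >= 0")
    if not 0.0 <= rc <= 1.0:
        raise ValueError("rc must lie in [0, 1]")
    out = rc * -np.expm1(-krel * t)
    return float(out) if out.ndim == 0 else out


def generate_release_curve(times, krel: float, rc: float = 1.0,
                           noise_sd: float = 0.0, rng=None):
    """Synthetic release-percentage measurements for fitting exercises.

    Evaluates the first-order saturation curve and optionally adds i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` (absolute fraction
    units), clipping the result to [0, 1].
    """
    f = release_fraction(np.asarray(times, dtype=float), rc, krel)
    if noise_sd > 0.0:
        rng = np.random.default_rng(rng)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=np.shape(f)), 0.0, 1.0)
    return f


def fit_release_rate(times, fractions,
                     x0: tuple[float, float] = (0.01, 0.9),
                     tol: float = 1e-10) -> tuple[float, float]:
    """Fit (krel, Rc) to release-percentage data by nonlinear least squares.

    Minimises sum_i (Rc*(1 - exp(-krel*t_i)) - f_i)^2 with the fixed initial
    guess ``x0`` = (krel, Rc) and tight tolerances, so the result is
    deterministic for given inputs.

    Raises
    ------
    ValueError
        For fewer than 3 points, fractions outside [0, 1], or degenerate
        (all-zero) data.
    RuntimeError
        If the optimiser fails to converge.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 3 or f.size != t.size:
        raise ValueError("need at least 3 matching (time, fraction) points")
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.all(f == 0.0):
        raise ValueError("degenerate data: all fractions are zero")

    def resid(p):
        krel, rc = p
        return rc * -np.expm1(-krel * t) - f

    sol = least_squares(resid, x0=np.asarray(x0), bounds=([0.0, 0.0], [np.inf, 1.0]),
                        xtol=tol, ftol=tol, gtol=tol)
    if not sol.success:
        raise RuntimeError(f"release-rate fit did not converge: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])
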