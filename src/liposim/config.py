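"""Parameter sets and configuration handling.

All quantities are in SI units (kg, m, s, Pa).  The dataclasses below are the
single source of truth for every physical constant used by the simulator:
tissue-level fluid-exchange parameters, species transport properties
(free drug, protein-bound drug, liposome-encapsulated drug), protein-binding
and cellular uptake kinetics, plasma pharmacokinetics, pharmacodynamics, and
the heating/release schedule.

Intracellular concentrations (and the efflux half-saturation ``ki`` and the
half-effect concentration ``ec50``) carry units of kg per 10^5 cells; cell
densities are in units of 10^5 cells per m^3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

TUMOUR = "tumour"
NORMAL = "normal"
MODES = ("infusion", "liposome")


class ConfigError(ValueError):
    """Raised when a configuration value violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class TissueParams:
    """Fluid-exchange and cellular parameters of one tissue region.

    ``kappa`` is the interstitial (Darcy) permeability in m^2; note that
    reference tables often quote its reciprocal 1/kappa, which must be
    inverted before being entered here.  ``kly_sly_v`` is the lumped
    lymphatic conductance K_ly*S_ly/V; it is zero in tumour tissue, which
    lacks functional lymphatics.
    """

    region: str
    sv_ratio: float          # vascular surface area per volume S/V (1/m)
    kv: float                # vascular hydraulic conductivity (m/Pa/s)
    kappa: float             # interstitial permeability (m^2)
    mu: float = 7.8e-4       # interstitial fluid viscosity (kg/m/s)
    rho: float = 1000.0      # interstitial fluid density (kg/m^3)
    pv: float = 2080.0       # vascular pressure (Pa)
    pi_v: float = 2666.0     # plasma osmotic pressure (Pa)
    pi_i: float = 2000.0     # interstitial osmotic pressure (Pa)
    sigma_T: float = 0.82    # osmotic reflection coefficient, plasma protein
    kly_sly_v: float = 0.0   # lumped lymphatic conductance (1/Pa/s)
    p_ly: float = 0.0        # intralymphatic pressure (Pa)
    dc0: float = 1.0e10      # baseline cell density (10^5 cells/m^3)
    phi: float = 0.4         # extracellular volume fraction

    def __post_init__(self) -> None:
        _require(self.region in (TUMOUR, NORMAL), f"unknown region {self.region!r}")
        for name in ("sv_ratio", "kv", "kappa", "mu", "rho", "kly_sly_v", "dc0"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 <= self.sigma_T <= 1.0, "sigma_T must lie in [0, 1]")
        _require(0.0 < self.phi <= 1.0, "phi must lie in (0, 1]")
        if self.region == TUMOUR:
            _require(self.kly_sly_v == 0.0, "tumour tissue has no lymphatics")

    @property
    def effective_pressure(self) -> float:
        """Starling effective pressure p_v - sigma_T*(pi_v - pi_i) (Pa)."""
        return self.pv - self.sigma_T * (self.pi_v - self.pi_i)


@dataclass(frozen=True)
class SpeciesTransportParams:
    """Vascular permeability, diffusivity and sieving of one drug species.

    ``h_fold`` is the fold-increase of vascular permeability at the mild
    hyperthermia temperature (42 C) relative to 37 C; it applies only while
    the tumour is heated.
    """

    species: str             # 'free' | 'bound' | 'liposome'
    p_tumour: float          # baseline vascular permeability in tumour (m/s)
    p_normal: float          # baseline vascular permeability in normal tissue
    h_fold: float            # permeability multiplier at 42 C
    d_tumour: float          # interstitial diffusion coefficient (m^2/s)
    d_normal: float
    sigma_tumour: float      # osmotic reflection coefficient
    sigma_normal: float

    def __post_init__(self) -> None:
        _require(self.species in ("free", "bound", "liposome"),
                 f"unknown species {self.species!r}")
        for name in ("p_tumour", "p_normal", "d_tumour", "d_normal"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.h_fold >= 1.0, "h_fold must be >= 1")
        for name in ("sigma_tumour", "sigma_normal"):
            _require(0.0 <= getattr(self, name) <= 1.0,
                     f"{name} must lie in [0, 1]")
        if self.species == "liposome":
            _require(self.sigma_normal == 1.0,
                     "liposomes are fully sieved by normal-tissue vasculature")

    def permeability(self, region: str) -> float:
        return self.p_tumour if region == TUMOUR else self.p_normal

    def diffusivity(self, region: str) -> float:
        return self.d_tumour if region == TUMOUR else self.d_normal

    def sigma(self, region: str) -> float:
        return self.sigma_tumour if region == TUMOUR else self.sigma_normal


@dataclass(frozen=True)
class BindingUptakeParams:
    """Protein-binding kinetics and saturable cellular uptake/efflux.

    The association/dissociation pair (``ka``, ``kd``) must be consistent
    with the plasma bound fraction ``s_bound``: at equilibrium the bound
    fraction of a closed free/bound pool is ka/(ka + kd).
    """

    ka: float = 0.833        # association rate (1/s)
    kd: float = 0.278        # dissociation rate (1/s)
    vmax: float = 4.67e-15   # max transmembrane transport rate (kg/(10^5 cells)/s)
    ke: float = 2.19e-4      # uptake half-saturation (kg/m^3)
    ki: float = 1.37e-12     # efflux half-saturation (kg/(10^5 cells))
    s_bound: float = 0.75    # bound fraction of drug in plasma

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "vmax", "ke", "ki"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 <= self.s_bound <= 1.0, "s_bound must lie in [0, 1]")
        if self.ka + self.kd > 0:
            eq = self.ka / (self.ka + self.kd)
            _require(abs(eq - self.s_bound) <= 0.01,
                     "ka/(ka+kd) inconsistent with s_bound "
                     f"({eq:.4f} vs {self.s_bound:.4f})")


@dataclass(frozen=True)
class PlasmaPKParams:
    """Plasma pharmacokinetic drivers.

    For direct infusion the plasma concentration is the closed-form
    triexponential response to a constant-rate infusion of total dose
    ``dose`` over ``t_inf`` seconds, with compartment parameters
    (``A``, ``B``, ``C``; units 1/m^3) and clearance rates (``alpha``,
    ``beta``, ``gamma``; 1/s).  For liposomal delivery the encapsulated
    plasma concentration is the biexponential ``A1*exp(-k1 t)+A2*exp(-k2 t)``.

    ``cl_fp`` and ``cl_bp`` are plasma clearances already divided by the
    volume of distribution, i.e. first-order elimination rates in 1/s, so
    ``vd`` never enters the equations and is retained for bookkeeping only.
    An alternative literature value for ``cl_fp`` is 1.48e-5 1/s.
    ``vt_over_vb`` (tumour-to-plasma volume ratio) scales the coupling of
    tissue transcapillary exchange back onto the plasma pool; it only
    affects liposome-mode plasma kinetics.
    """

    dose: float = 8.56e-5    # total dose (kg)
    t_inf: float = 7200.0    # infusion duration (s)
    A: float = 74.6          # (1/m^3)
    B: float = 2.49
    C: float = 0.552
    alpha: float = 2.43e-3   # (1/s)
    beta: float = 2.83e-4
    gamma: float = 1.18e-5
    A1: float = 6.90e-3      # (kg/m^3)
    A2: float = 8.37e-5
    k1: float = 1.22e-2      # (1/s)
    k2: float = 4.17e-6
    vt_over_vb: float = 0.02
    vd: float = 1.0          # volume of distribution (m^3); cancels, see above
    cl_fp: float = 2.43e-3   # free-drug plasma clearance rate CL/V_D (1/s)
    cl_bp: float = 0.0       # bound-drug plasma clearance rate (1/s)

    def __post_init__(self) -> None:
        for name in ("dose", "t_inf", "alpha", "beta", "gamma", "A1", "A2",
                     "k1", "k2", "vt_over_vb", "cl_fp", "cl_bp"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.t_inf > 0, "infusion duration must be positive")


@dataclass(frozen=True)
class PDParams:
    """Log-kill pharmacodynamics with logistic cell turnover.

    dDc/dt = -fmax*Ci/(ec50+Ci)*Dc + kp*Dc - kg*Dc^2.  The degradation
    coefficient ``kg`` carries units 1/s per (10^5 cells/m^3) so that the
    drug-free equilibrium density kp/kg matches the baseline cell density.
    """

    fmax: float = 1.67e-5    # cell-kill rate constant (1/s)
    ec50: float = 5.0e-13    # half-effect intracellular conc. (kg/(10^5 cells))
    kp: float = 3.0e-6       # proliferation rate (1/s)
    kg: float = 3.0e-16      # degradation rate (1/s/(10^5 cells/m^3))

    def __post_init__(self) -> None:
        for name in ("fmax", "ec50", "kp", "kg"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass(frozen=True)
class HeatingSchedule:
    """Step heating of the tumour region and triggered liposome release.

    The tumour is held at 42 C for ``t_dur`` seconds starting at ``t_on``;
    outside this window (and in normal tissue at all times) the temperature
    is 37 C, where the release rate is zero.  ``rc`` is the total releasable
    fraction of the encapsulated payload at the heating temperature.
    """

    t_on: float = 86400.0    # heating start (s)
    t_dur: float = 3600.0    # heating duration (s)
    krel_37: float = 0.0     # release rate at 37 C (1/s)
    krel_42: float = 0.0078  # release rate at 42 C (1/s)
    rc: float = 1.0          # releasable fraction at 42 C

    def __post_init__(self) -> None:
        _require(self.krel_37 == 0.0, "no release occurs at 37 C")
        _require(self.krel_42 >= 0.0, "krel_42 must be >= 0")
        _require(self.t_dur >= 0.0, "heating duration must be >= 0")
        _require(self.t_on >= 0.0, "heating start must be >= 0")
        _require(0.0 <= self.rc <= 1.0, "rc must lie in [0, 1]")


@dataclass(frozen=True)
class GeometryParams:
    r_tumour: float = 0.025  # tumour radius (m)
    t_normal: float = 0.010  # normal-shell thickness (m)

    def __post_init__(self) -> None:
        _require(self.r_tumour > 0 and self.t_normal > 0,
                 "geometry lengths must be positive")


@dataclass(frozen=True)
class NumericsParams:
    """Discretisation settings.

    The default resolution (250 tumour + 100 normal cells, i.e. 100 um
    spacing) resolves the pressure/concentration boundary layers at the
    tissue interface; dt = 10 s with implicit stepping handles the stiff
    binding kinetics.
    """

    n_tumour: int = 250
    n_normal: int = 100
    dt: float = 10.0            # time step (s)
    t_end: float = 172800.0     # simulated horizon (s)
    output_every: float = 60.0  # recording cadence (s)
    picard_tol: float = 1.0e-10
    picard_max: int = 100

    def __post_init__(self) -> None:
        _require(self.n_tumour >= 2 and self.n_normal >= 2,
                 "need at least 2 cells per region")
        _require(self.dt > 0 and self.t_end > 0, "dt and t_end must be positive")
        _require(self.output_every >= self.dt, "output_every must be >= dt")
        ratio = self.output_every / self.dt
        _require(abs(ratio - round(ratio)) < 1e-9,
                 "output_every must be an integer multiple of dt")
        _require(self.picard_tol > 0 and self.picard_max >= 1,
                 "invalid Picard settings")


@dataclass(frozen=True)
class SimulationConfig:
    """Aggregate, validated model configuration."""

    mode: str = "infusion"
    geometry: GeometryParams = field(default_factory=GeometryParams)
    tissue_tumour: TissueParams = field(default_factory=lambda: TissueParams(
        region=TUMOUR, sv_ratio=20000.0, kv=2.10e-11, kappa=1.0 / 4.56e16,
        pi_i=2000.0, sigma_T=0.82, kly_sly_v=0.0))
    tissue_normal: TissueParams = field(default_factory=lambda: TissueParams(
        region=NORMAL, sv_ratio=7000.0, kv=2.70e-12, kappa=1.0 / 2.21e17,
        pi_i=1333.0, sigma_T=0.91, kly_sly_v=4.17e-7))
    free: SpeciesTransportParams = field(default_factory=lambda: SpeciesTransportParams(
        species="free", p_tumour=3.00e-6, p_normal=3.75e-7, h_fold=2.56,
        d_tumour=3.40e-10, d_normal=1.58e-10,
        sigma_tumour=0.15, sigma_normal=0.15))
    bound: SpeciesTransportParams = field(default_factory=lambda: SpeciesTransportParams(
        species="bound", p_tumour=7.80e-9, p_normal=2.50e-9, h_fold=1.0,
        d_tumour=8.89e-12, d_normal=4.17e-12,
        sigma_tumour=0.82, sigma_normal=0.82))
    liposome: SpeciesTransportParams = field(default_factory=lambda: SpeciesTransportParams(
        species="liposome", p_tumour=3.42e-9, p_normal=8.50e-10, h_fold=71.0,
        d_tumour=9.00e-12, d_normal=5.80e-12,
        sigma_tumour=0.95, sigma_normal=1.0))
    binding: BindingUptakeParams = field(default_factory=BindingUptakeParams)
    pk: PlasmaPKParams = field(default_factory=PlasmaPKParams)
    pd: PDParams = field(default_factory=PDParams)
    heating: HeatingSchedule = field(default_factory=HeatingSchedule)
    numerics: NumericsParams = field(default_factory=NumericsParams)
    # Model options
    include_bound_lymph: bool = False       # lymphatic drainage of bound drug
    liposome_normal_extravasation: bool = False  # liposomes cross normal vessels
    pd_coupling: str = "oneway"             # 'oneway' | 'twoway' (Dc fed back)

    def __post_init__(self) -> None:
        _require(self.mode in MODES, f"unknown mode {self.mode!r}")
        _require(self.tissue_tumour.region == TUMOUR
                 and self.tissue_normal.region == NORMAL,
                 "tissue regions mislabelled")
        _require(self.pd_coupling in ("oneway", "twoway"),
                 f"unknown pd_coupling {self.pd_coupling!r}")
        # Drug-free tissue must be at proliferation/degradation equilibrium.
        if self.pd.kg > 0:
            eq = self.pd.kp / self.pd.kg
            _require(abs(eq - self.tissue_tumour.dc0) <= 1e-6 * self.tissue_tumour.dc0,
                     "kp/kg must equal the baseline cell density dc0")

    def tissue(self, region: str) -> TissueParams:
        return self.tissue_tumour if region == TUMOUR else self.tissue_normal

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tissue"] = {TUMOUR: d.pop("tissue_tumour"), NORMAL: d.pop("tissue_normal")}
        d["drug"] = {"free": d.pop("free"), "bound": d.pop("bound")}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config(mode: str = "infusion", **overrides: Any) -> SimulationConfig:
    """Baseline configuration for the given delivery mode.

    Infusion mode delivers the full dose as a 2-hour constant-rate infusion
    with no heating; liposome mode administers the dose as a thermosensitive
    liposome bolus with 1 hour of tumour hyperthermia starting at 24 h.
    Keyword overrides replace top-level config fields.
    """
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}")
    cfg = SimulationConfig(mode=mode)
    if mode == "infusion":
        cfg = dataclasses.replace(cfg, heating=HeatingSchedule(t_dur=0.0))
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


# ----------------------------------------------------------------------
# file loading: flat dotted keys or nested mappings, merged over defaults
# ----------------------------------------------------------------------

def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


_SECTION_MAP = {
    "geometry": ("geometry", GeometryParams),
    "tissue.tumour": ("tissue_tumour", TissueParams),
    "tissue.normal": ("tissue_normal", TissueParams),
    "drug.free": ("free", SpeciesTransportParams),
    "drug.bound": ("bound", SpeciesTransportParams),
    "liposome": ("liposome", SpeciesTransportParams),
    "binding": ("binding", BindingUptakeParams),
    "pk": ("pk", PlasmaPKParams),
    "pd": ("pd", PDParams),
    "heating": ("heating", HeatingSchedule),
    "numerics": ("numerics", NumericsParams),
}

_TOP_LEVEL = {"mode", "include_bound_lymph", "liposome_normal_extravasation",
              "pd_coupling"}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML configuration file, filling absent fields with defaults.

    Keys may be nested mappings or flat dotted names (``tissue.tumour.kv``).
    Unknown keys and values violating physical bounds raise
    :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    flat = _flatten(raw)

    mode = flat.pop("mode", "infusion")
    base = default_config(mode)

    fields: dict[str, Any] = {}
    for key in _TOP_LEVEL - {"mode"}:
        if key in flat:
            fields[key] = flat.pop(key)

    updates: dict[str, dict[str, Any]] = {}
    for key, value in flat.items():
        section, _, leaf = key.rpartition(".")
        if section not in _SECTION_MAP or not leaf:
            raise ConfigError(f"unknown configuration key {key!r}")
        updates.setdefault(section, {})[leaf] = value

    for section, leaves in updates.items():
        attr, _cls = _SECTION_MAP[section]
        current = getattr(base, attr)
        valid = {f.name for f in dataclasses.fields(current)}
        unknown = set(leaves) - valid
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in section {section!r}")
        try:
            fields[attr] = dataclasses.replace(current, **leaves)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:  # bad value type
            raise ConfigError(f"invalid value in section {section!r}: {exc}")

    return dataclasses.replace(base, **fields)
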