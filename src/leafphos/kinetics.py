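"""Forward FvCB photosynthesis model and temperature-response machinery.

The Farquhar-von Caemmerer-Berry (FvCB) model treats net CO2 assimilation of
a C3 leaf as the minimum of a Rubisco-carboxylation-limited rate and an
RuBP-regeneration (electron-transport) limited rate, minus day respiration:

    A_c   = Vcmax (Ci - GammaStar) / (Ci + Km),   Km = Kc (1 + O/Ko)
    A_j   = J (Ci - GammaStar) / (4 Ci + 8 GammaStar)
    A_net = min(A_c, A_j) - Rd

All biochemical rate parameters are stored at the 25 degC reference and scaled
to leaf temperature on evaluation: Arrhenius for the enzyme kinetic constants
(Kc, Ko, GammaStar) and for Rd, and a peaked (deactivating) Arrhenius function
for Vcmax and Jmax whose entropy term acclimates linearly to growth
temperature (Kattge & Knorr style).

Temperatures are degrees Celsius at every public interface and Kelvin
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_GAS",
    "T_REF_C",
    "KineticConstants",
    "LeafBiochem",
    "arrhenius_factor",
    "peaked_factor",
    "temperature_factor",
    "scale_to_leaf_temperature",
    "normalize_to_25",
    "rubisco_limited",
    "rubp_limited",
    "net_assimilation",
]

R_GAS = 8.314462618  # universal gas constant, J mol-1 K-1
T_REF_C = 25.0
_T_REF_K = T_REF_C + 273.15

# Parameter classes scaled by a simple Arrhenius response vs. the peaked form.
_ARRHENIUS_TAGS = frozenset({"Kc", "Ko", "GammaStar", "Rd"})
_PEAKED_TAGS = frozenset({"Vcmax", "Jmax"})


class ConfigurationError(ValueError):
    """Unknown parameter tag or inconsistent kinetic configuration."""


@dataclass(frozen=True)
class KineticConstants:
    """Enzyme kinetic constants and temperature-response parameters.

    Defaults are the Bernacchi (2001) in-vivo Rubisco constants with
    Kattge & Knorr (2007) acclimation of the Vcmax/Jmax entropy terms to
    growth temperature.  Every field can be overridden, e.g. from a YAML
    config (see :func:`leafphos.coefficients.load_kinetics`).

    Units: Kc25, GammaStar25 in umol mol-1; Ko25, O in mmol mol-1; all
    energies in J mol-1; Tgrowth in degC.
    """

    Kc25: float = 404.9
    Ko25: float = 278.4
    GammaStar25: float = 42.75
    O: float = 210.0
    Ea_Kc: float = 79_430.0
    Ea_Ko: float = 36_380.0
    Ea_GammaStar: float = 37_830.0
    # Day-respiration Arrhenius energy; an assumption, the temperature
    # treatment of Rd before normalization is not constrained by data here.
    Ea_Rd: float = 46_390.0
    Ha_V: float = 71_513.0
    Ha_J: float = 49_884.0
    Hd: float = 200_000.0
    Tgrowth: float = 25.0

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "GammaStar25", "O"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("Ea_Kc", "Ea_Ko", "Ea_GammaStar", "Ea_Rd", "Ha_V", "Ha_J", "Hd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        # Entropy terms must place the temperature optimum above 0 degC.
        for ds in (self.deltaS_V, self.deltaS_J):
            if not (0.0 < ds < self.Hd / 273.0):
                raise ConfigurationError(
                    f"entropy term {ds:.2f} J mol-1 K-1 outside (0, Hd/273)"
                )

    @property
    def deltaS_V(self) -> float:
        """Vcmax entropy term (J mol-1 K-1), acclimated to Tgrowth."""
        return 668.39 - 1.07 * self.Tgrowth

    @property
    def deltaS_J(self) -> float:
        """Jmax entropy term (J mol-1 K-1), acclimated to Tgrowth."""
        return 659.70 - 0.75 * self.Tgrowth

    def Km(self, tleaf: float = T_REF_C) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko) at leaf temperature."""
        kc = scale_to_leaf_temperature(self.Kc25, "Kc", self, tleaf)
        ko = scale_to_leaf_temperature(self.Ko25, "Ko", self, tleaf)
        return kc * (1.0 + self.O / ko)

    def gamma_star(self, tleaf: float = T_REF_C) -> float:
        """CO2 compensation point without day respiration at leaf temperature."""
        return scale_to_leaf_temperature(self.GammaStar25, "GammaStar", self, tleaf)

    def to_dict(self) -> dict:
        d = {
            name: getattr(self, name)
            for name in (
                "Kc25", "Ko25", "GammaStar25", "O", "Ea_Kc", "Ea_Ko",
                "Ea_GammaStar", "Ea_Rd", "Ha_V", "Ha_J", "Hd", "Tgrowth",
            )
        }
        d["deltaS_V"] = self.deltaS_V
        d["deltaS_J"] = self.deltaS_J
        return d


@dataclass(frozen=True)
class LeafBiochem:
    """Leaf photosynthetic capacities at the 25 degC reference.

    Vcmax25, Jmax25, Rd25 in umol m-2 s-1 (area basis).
    """

    Vcmax25: float
    Jmax25: float
    Rd25: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Vcmax25 > 0 and self.Jmax25 > 0):
            raise ValueError("Vcmax25 and Jmax25 must be > 0")
        if self.Rd25 < 0:
            raise ValueError("Rd25 must be >= 0")


def _tleaf_kelvin(tleaf: float) -> float:
    if not np.isfinite(tleaf):
        raise ValueError("Tleaf must be finite")
    if not (0.0 <= tleaf <= 50.0):
        raise ValueError(f"Tleaf {tleaf} degC outside supported range [0, 50]")
    return tleaf + 273.15


def arrhenius_factor(Ea: float, tleaf: float) -> float:
    """Arrhenius scaling factor relative to 25 degC: exp((Ea/R)(1/298.15 - 1/Tk))."""
    tk = _tleaf_kelvin(tleaf)
    return math.exp(Ea / R_GAS * (1.0 / _T_REF_K - 1.0 / tk))


def peaked_factor(Ha: float, Hd: float, deltaS: float, tleaf: float) -> float:
    """Peaked (deactivating) Arrhenius factor relative to 25 degC.

    f(T) = Arrh(Ha, T) * [1 + exp((Tref dS - Hd)/(Tref R))]
                       / [1 + exp((Tk dS - Hd)/(Tk R))]

    Equals 1 at 25 degC exactly and has a single interior maximum.
    """
    tk = _tleaf_kelvin(tleaf)
    num = 1.0 + math.exp((_T_REF_K * deltaS - Hd) / (_T_REF_K * R_GAS))
    den = 1.0 + math.exp((tk * deltaS - Hd) / (tk * R_GAS))
    return arrhenius_factor(Ha, tleaf) * num / den


def temperature_factor(which: str, kin: KineticConstants, tleaf: float) -> float:
    """Multiplicative factor taking a 25 degC value to leaf temperature."""
    if which in _ARRHENIUS_TAGS:
        ea = {
            "Kc": kin.Ea_Kc,
            "Ko": kin.Ea_Ko,
            "GammaStar": kin.Ea_GammaStar,
            "Rd": kin.Ea_Rd,
        }[which]
        return arrhenius_factor(ea, tleaf)
    if which == "Vcmax":
        return peaked_factor(kin.Ha_V, kin.Hd, kin.deltaS_V, tleaf)
    if which == "Jmax":
        return peaked_factor(kin.Ha_J, kin.Hd, kin.deltaS_J, tleaf)
    raise ConfigurationError(
        f"unknown parameter tag {which!r}; expected one of "
        f"{sorted(_ARRHENIUS_TAGS | _PEAKED_TAGS)}"
    )


def scale_to_leaf_temperature(
    value25: float, which: str, kin: KineticConstants, tleaf: float
) -> float:
    """Scale a rate from the 25 degC reference to leaf temperature."""
    if value25 < 0:
        raise ValueError("value25 must be >= 0")
    return value25 * temperature_factor(which, kin, tleaf)


def normalize_to_25(
    value_at_t: float, which: str, kin: KineticConstants, tleaf: float
) -> float:
    """Exact inverse of :func:`scale_to_leaf_temperature`."""
    if value_at_t < 0:
        raise ValueError("value_at_T must be >= 0")
    factor = temperature_factor(which, kin, tleaf)
    if factor < 1e-300:
        raise FloatingPointError("temperature scaling factor underflow")
    return value_at_t / factor


def rubisco_limited(
    ci: np.ndarray | float, vcmax: float, gamma_star: float, km: float
) -> np.ndarray | float:
    """Rubisco-carboxylation-limited gross rate A_c (umol m-2 s-1)."""
    ci = np.asarray(ci, dtype=float)
    return vcmax * (ci - gamma_star) / (ci + km)


def rubp_limited(
    ci: np.ndarray | float, j: float, gamma_star: float
) -> np.ndarray | float:
    """RuBP-regeneration-limited gross rate A_j for electron transport J."""
    ci = np.asarray(ci, dtype=float)
    return j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)


def net_assimilation(
    ci: np.ndarray | float,
    biochem: LeafBiochem,
    kin: KineticConstants | None = None,
    tleaf: float = T_REF_C,
    gm: float | None = None,
) -> np.ndarray | float:
    """Net CO2 assimilation A_net at intercellular CO2 `ci` (umol mol-1).

    Light-saturated form: electron transport J = Jmax.  All parameters are
    scaled from the 25 degC reference to `tleaf` before evaluation.  With the
    default infinite mesophyll conductance the chloroplast CO2 equals `ci`;
    pass a finite `gm` (mol m-2 s-1) to solve A with Cc = Ci - A/gm instead.

    Returns a scalar for scalar input, an ndarray otherwise.
    """
    kin = kin or KineticConstants()
    ci_arr = np.asarray(ci, dtype=float)
    if not np.all(np.isfinite(ci_arr)):
        raise ValueError("Ci contains non-finite values")
    if np.any(ci_arr < 0):
        raise ValueError("Ci must be >= 0")

    vcmax = scale_to_leaf_temperature(biochem.Vcmax25, "Vcmax", kin, tleaf)
    jmax = scale_to_leaf_temperature(biochem.Jmax25, "Jmax", kin, tleaf)
    rd = scale_to_leaf_temperature(biochem.Rd25, "Rd", kin, tleaf)
    gs = kin.gamma_star(tleaf)
    km = kin.Km(tleaf)

    if gm is None:
        a_c = rubisco_limited(ci_arr, vcmax, gs, km)
        a_j = rubp_limited(ci_arr, jmax, gs)
        a_net = np.minimum(a_c, a_j) - rd
    else:
        # Finite mesophyll conductance: each limitation becomes a quadratic
        # in the gross rate A; take the smaller (physical) root.
        a_c = _quadratic_limited(ci_arr, vcmax, gs, km, gm)
        a_j = _quadratic_limited(ci_arr, jmax / 4.0, gs, 2.0 * gs, gm)
        a_net = np.minimum(a_c, a_j) - rd
    return float(a_net) if np.isscalar(ci) else a_net


def _quadratic_limited(ci, vmax, gamma_star, k, gm):
    # gross A solves A = vmax (Cc - G*)/(Cc + k) with Cc = Ci - A/gm
    b = -(vmax + (ci + k) * gm)
    c = vmax * gm * (ci - gamma_star)
    disc = np.sqrt(b * b - 4.0 * c)
    return (-b - disc) / 2.0
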