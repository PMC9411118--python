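"""Forward predictors of photosynthetic biochemistry from leaf N and P.

Power-law predictor equations for Vcmax and Jmax from leaf nutrient
concentrations, on mass basis (nmol g-1 s-1, nutrients in mg g-1) and area
basis (umol m-2 s-1, nutrients in g m-2); mass <-> area conversion through
leaf dry mass per area Ma; linear Jmax-Vcmax lines by leaf-P class; and the
sigmoidal P-acquisition scalar of the leaf N:P mass ratio used to throttle
plant P-acquisition processes between N- and P-limited regimes.

Two published coefficient sets are shipped (see ``data/coefficients.yaml``):
``methods`` (main effects of ln P and ln N only, mass and area bases fitted
independently — the set used in the canopy experiment) and ``table2`` (the
full-dataset mass-basis multiple regression including the N x P interaction).
The mass- and area-basis equations are independent fits; they are never
chained silently — conversion through Ma is an explicit call.
"""

from __future__ import annotations

import math

import numpy as np

from .coefficients import load_coefficients

__all__ = [
    "predict_biochem_mass",
    "predict_biochem_area",
    "predict_ma",
    "mass_area_convert",
    "jv_line",
    "p_acquisition_scalar",
    "unlimited_p_leaf",
]


def _eval_loglinear(coefs: dict, lnN: np.ndarray, lnP: np.ndarray) -> np.ndarray:
    out = (coefs["intercept"]
           + coefs.get("coef_lnN", 0.0) * lnN
           + coefs.get("coef_lnP", 0.0) * lnP
           + coefs.get("coef_lnN_lnP", 0.0) * lnN * lnP)
    return np.exp(out)


def _check_pos(name, v):
    if np.any(~(np.asarray(v, dtype=float) > 0)):
        raise ValueError(f"{name} must be strictly positive")


def predict_biochem_mass(Nmass, Pmass, coeff_set: str = "methods"):
    """Predict (Vcmax_mass, Jmax_mass) in nmol g-1 s-1 from leaf N and P
    concentrations in mg g-1.

    ``coeff_set`` selects ``"methods"`` (main effects only, default) or
    ``"table2"`` (includes the N x P interaction).
    """
    _check_pos("Nmass", Nmass)
    _check_pos("Pmass", Pmass)
    sets = load_coefficients()["predictor_sets"]
    if coeff_set not in sets:
        raise KeyError(f"unknown coefficient set {coeff_set!r}")
    cset = sets[coeff_set]["mass"]
    lnN = np.log(np.asarray(Nmass, dtype=float))
    lnP = np.log(np.asarray(Pmass, dtype=float))
    vc = _eval_loglinear(cset["Vcmax"], lnN, lnP)
    jm = _eval_loglinear(cset["Jmax"], lnN, lnP)
    if np.isscalar(Nmass) and np.isscalar(Pmass):
        return float(vc), float(jm)
    return vc, jm


def predict_biochem_area(Narea, Parea):
    """Predict (Vcmax, Jmax) in umol m-2 s-1 from leaf N and P per area
    in g m-2 (independent area-basis fit; ``methods`` set only)."""
    _check_pos("Narea", Narea)
    _check_pos("Parea", Parea)
    cset = load_coefficients()["predictor_sets"]["methods"]["area"]
    lnN = np.log(np.asarray(Narea, dtype=float))
    lnP = np.log(np.asarray(Parea, dtype=float))
    vc = _eval_loglinear(cset["Vcmax"], lnN, lnP)
    jm = _eval_loglinear(cset["Jmax"], lnN, lnP)
    if np.isscalar(Narea) and np.isscalar(Parea):
        return float(vc), float(jm)
    return vc, jm


def predict_ma(Nmass, Pmass):
    """Predict leaf dry mass per area Ma (g m-2) from N_mass and P_mass
    (mg g-1) with the published ln-scale N x P model."""
    _check_pos("Nmass", Nmass)
    _check_pos("Pmass", Pmass)
    coefs = load_coefficients()["ma_model"]
    lnN = np.log(np.asarray(Nmass, dtype=float))
    lnP = np.log(np.asarray(Pmass, dtype=float))
    ma = _eval_loglinear(coefs, lnN, lnP)
    return float(ma) if np.isscalar(Nmass) and np.isscalar(Pmass) else ma


def mass_area_convert(value, Ma, direction: str = "mass_to_area"):
    """Convert a rate between mass (nmol g-1 s-1) and area (umol m-2 s-1)
    bases through leaf dry mass per area Ma (g m-2).

    area = mass * Ma / 1000; the two directions are exact inverses.
    """
    if np.any(~(np.asarray(Ma, dtype=float) > 0)):
        raise ValueError("Ma must be > 0")
    value = np.asarray(value, dtype=float)
    if direction == "mass_to_area":
        out = value * np.asarray(Ma, dtype=float) / 1000.0
    elif direction == "area_to_mass":
        out = value * 1000.0 / np.asarray(Ma, dtype=float)
    else:
        raise ValueError("direction must be 'mass_to_area' or 'area_to_mass'")
    return float(out) if out.ndim == 0 else out


def jv_line(Vcmax, p_class: str):
    """Jmax from Vcmax (umol m-2 s-1, 25 degC) on the published linear line
    for the ``'low'`` or ``'high'`` end-member leaf P_mass class."""
    lines = load_coefficients()["jv_lines"]
    if p_class not in lines:
        raise KeyError(f"unknown P class {p_class!r}; expected {sorted(lines)}")
    if np.any(np.asarray(Vcmax, dtype=float) < 0):
        raise ValueError("Vcmax must be >= 0")
    ln = lines[p_class]
    out = ln["intercept"] + ln["slope"] * np.asarray(Vcmax, dtype=float)
    return float(out) if out.ndim == 0 else out


def p_acquisition_scalar(NtoP):
    """Sigmoidal P-acquisition scalar f(N:P) = 1/(1 + exp(-(N:P)/2 + 10)).

    N:P is the leaf mass ratio (g N per g P).  Strictly increasing, 0.5 at
    N:P = 20, rising sharply between N:P of 15 and 25 — the transition from
    N- toward P-limited plant communities.
    """
    ratio = np.asarray(NtoP, dtype=float)
    if np.any(~(ratio > 0)):
        raise ValueError("N:P ratio must be > 0")
    pa = load_coefficients()["p_acquisition"]
    out = 1.0 / (1.0 + np.exp(-ratio / pa["divisor"] + pa["offset"]))
    return float(out) if out.ndim == 0 else out


def unlimited_p_leaf(Nmass):
    """Leaf P_mass (mg g-1) under unlimited P supply: the ceiling set by the
    minimum leaf N:P mass ratio of 5, i.e. P_mass = N_mass / 5."""
    _check_pos("Nmass", Nmass)
    ratio = load_coefficients()["min_n_to_p"]
    out = np.asarray(Nmass, dtype=float) / ratio
    return float(out) if out.ndim == 0 else out
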