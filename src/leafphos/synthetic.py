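"""Synthetic-data generators emulating the statistical structure the
analysis assumes, so every pipeline stage is testable without the deposited
field dataset.

What is emulated: log-normal leaf N_mass and P_mass with a target squared
correlation between their logs (default 0.39); power-law trait-nutrient
responses generated from the published coefficient sets with Gaussian
log-scale residuals calibrated to the printed r2 values; Ma from its
published N x P model; linear Jmax-Vcmax class lines with r2-calibrated
linear-scale noise; and forward-model A-Ci curves with additive
instrument-like noise.  Every generator is a pure function of its
parameters and seed.

Residual calibration uses sd_resid^2 = var(fitted) * (1 - r2) / r2, the
closed form that makes the *expected* coefficient of determination equal
the target.  The field data's residual spreads are not published; this
calibration is a reconstruction, and generated tables carry no claim of
matching the real data's family composition or site structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aci import ACiCurve
from .coefficients import load_coefficients
from .kinetics import KineticConstants, LeafBiochem, net_assimilation

__all__ = [
    "TraitGeneratorSpec",
    "gen_leaf_traits",
    "gen_classed_traits",
    "gen_aci_curve",
    "gen_jv_dataset",
    "residual_sd_for_r2",
]

_CONTINENTS = ("South America", "Africa", "Asia", "Australia")


def residual_sd_for_r2(fitted: np.ndarray, target_r2: float) -> float:
    """Residual sd making the expected r2 of fitted+noise equal target_r2."""
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError("target r2 must be in (0, 1]")
    var_fit = float(np.var(fitted))
    return float(np.sqrt(var_fit * (1.0 - target_r2) / target_r2))


@dataclass(frozen=True)
class TraitGeneratorSpec:
    """Parameters of the species-site trait-table generator.

    Defaults mirror the analysed dataset: n = 446 species-site records, leaf
    N_mass centred near 20 mg g-1, leaf P_mass centred at the 0.92 mg g-1
    class threshold with a ~50-fold range, squared log-log N-P correlation
    0.39, responses from the full-dataset ("table2") interaction models with
    noise calibrated to the printed r2 values.
    """

    n: int = 446
    mean_lnN: float = float(np.log(20.0))   # mg g-1
    sd_lnN: float = 0.30
    mean_lnP: float = float(np.log(0.92))   # mg g-1
    sd_lnP: float = 0.65
    r2_lnN_lnP: float = 0.39
    coeff_set: str = "table2"
    residual_scale: float = 1.0             # 0 => exact generating surface
    continents: tuple = _CONTINENTS
    n_sites: int = 50

    def __post_init__(self):
        if self.sd_lnN <= 0 or self.sd_lnP <= 0:
            raise ValueError("log-scale sds must be > 0")
        if not (0.0 <= self.r2_lnN_lnP < 1.0):
            raise ValueError("target r2 between logs must be in [0, 1)")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def _eval_surface(coefs: dict, lnN: np.ndarray, lnP: np.ndarray) -> np.ndarray:
    return (coefs["intercept"]
            + coefs.get("coef_lnN", 0.0) * lnN
            + coefs.get("coef_lnP", 0.0) * lnP
            + coefs.get("coef_lnN_lnP", 0.0) * lnN * lnP)


def gen_leaf_traits(spec: TraitGeneratorSpec, seed: int) -> pd.DataFrame:
    """Generate a species-site trait table.

    (ln N, ln P) are bivariate normal with correlation sqrt(r2_lnN_lnP);
    mass-based responses (Vcmax_mass, Jmax_mass, Amass; nmol g-1 s-1) come
    from the selected generating models plus Gaussian log residuals; Ma from
    its published model; area-based rates and nutrient columns follow by
    unit algebra.  Bit-reproducible given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    rho = float(np.sqrt(spec.r2_lnN_lnP))
    cov = [[spec.sd_lnN ** 2, rho * spec.sd_lnN * spec.sd_lnP],
           [rho * spec.sd_lnN * spec.sd_lnP, spec.sd_lnP ** 2]]
    lnN, lnP = rng.multivariate_normal(
        [spec.mean_lnN, spec.mean_lnP], cov, size=spec.n).T

    table = load_coefficients()
    sets = table["predictor_sets"]
    if spec.coeff_set not in sets:
        raise ValueError(f"unknown generating coefficient set {spec.coeff_set!r}")
    models = dict(sets[spec.coeff_set]["mass"])

    df = pd.DataFrame({
        "species": [f"sp{i:04d}" for i in range(spec.n)],
        "site": [f"site{i % spec.n_sites:02d}" for i in range(spec.n)],
        "continent": rng.choice(spec.continents, size=spec.n),
        "Nmass": np.exp(lnN),
        "Pmass": np.exp(lnP),
    })

    colname = {"Vcmax": "Vcmax_mass", "Jmax": "Jmax_mass", "Amass": "Amass"}
    for target, coefs in models.items():
        fitted = _eval_surface(coefs, lnN, lnP)
        sd = residual_sd_for_r2(fitted, coefs.get("r2", 0.5)) * spec.residual_scale
        df[colname.get(target, target)] = np.exp(fitted + rng.normal(0.0, sd, spec.n))

    ma_coefs = table["ma_model"]
    ma_fit = _eval_surface(ma_coefs, lnN, lnP)
    ma_sd = residual_sd_for_r2(ma_fit, ma_coefs.get("r2", 0.5)) * spec.residual_scale
    df["Ma"] = np.exp(ma_fit + rng.normal(0.0, ma_sd, spec.n))

    df["Narea"] = df["Nmass"] * df["Ma"] / 1000.0
    df["Parea"] = df["Pmass"] * df["Ma"] / 1000.0
    if "Vcmax_mass" in df:
        df["Vcmax25"] = df["Vcmax_mass"] * df["Ma"] / 1000.0
    if "Jmax_mass" in df:
        df["Jmax25"] = df["Jmax_mass"] * df["Ma"] / 1000.0
    if "Amass" in df:
        df["Anet"] = df["Amass"] * df["Ma"] / 1000.0
    return df


def gen_classed_traits(n_low: int, n_mod: int, seed: int,
                       response: str = "Vcmax_vs_N",
                       threshold: float | None = None) -> pd.DataFrame:
    """Generate a two-class dataset from the published single-factor class
    lines (low vs moderate leaf P), noise calibrated to each printed r2.

    Returns columns Nmass, Pmass, y, p_class; P_mass is placed on the
    correct side of the class threshold so downstream classing reproduces
    the generating membership exactly.
    """
    rng = np.random.default_rng(seed)
    table = load_coefficients()["single_factor"]
    thr = threshold if threshold is not None else table["p_threshold"]
    rows = table[response]
    frames = []
    for label, n in (("low", n_low), ("moderate", n_mod)):
        coefs = rows[label]
        lnN = rng.normal(np.log(20.0), 0.30, n)
        fitted = coefs["intercept"] + coefs["slope"] * lnN
        sd = residual_sd_for_r2(fitted, coefs["r2"])
        y = np.exp(fitted + rng.normal(0.0, sd, n))
        pmass = (rng.uniform(0.3 * thr, 0.98 * thr, n) if label == "low"
                 else rng.uniform(1.02 * thr, 3.0 * thr, n))
        frames.append(pd.DataFrame({
            "Nmass": np.exp(lnN), "Pmass": pmass, "y": y, "p_class": label,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_aci_curve(biochem: LeafBiochem, seed: int,
                  tleaf: float = 25.0,
                  ci_grid: np.ndarray | None = None,
                  noise_sd: float = 0.5,
                  kin: KineticConstants | None = None,
                  gsw: float = 200.0, ppfd: float = 1800.0,
                  leaf_id: str = "synthetic", species: str = "synthetic",
                  site: str = "synthetic", continent: str = "") -> ACiCurve:
    """Forward-model A-Ci curve with additive Gaussian instrument noise.

    The default 11-point Ci grid spans 50-1500 umol mol-1, covering both
    the Rubisco-limited low-Ci and RuBP-limited high-Ci regions.
    """
    kin = kin or KineticConstants()
    if ci_grid is None:
        ci_grid = np.array([50., 100., 150., 200., 275., 400., 600.,
                            800., 1000., 1250., 1500.])
    ci_grid = np.asarray(ci_grid, dtype=float)
    if len(ci_grid) < 5:
        raise ValueError("Ci grid needs at least 5 points")
    rng = np.random.default_rng(seed)
    anet = np.array([net_assimilation(c, biochem, kin, tleaf) for c in ci_grid])
    if noise_sd > 0:
        anet = anet + rng.normal(0.0, noise_sd, len(ci_grid))
    n = len(ci_grid)
    return ACiCurve(
        ci=ci_grid, anet=anet, tleaf=np.full(n, float(tleaf)),
        ppfd=np.full(n, float(ppfd)), gsw=np.full(n, float(gsw)),
        leaf_id=leaf_id, species=species, site=site, continent=continent,
    )


def gen_jv_dataset(n: int, slope: float, intercept: float, target_r2: float,
                   vcmax_range: tuple[float, float], seed: int) -> pd.DataFrame:
    """(Vcmax, Jmax) pairs on a linear line with r2-calibrated noise.

    Vcmax is uniform on ``vcmax_range``; the noise sd is solved analytically
    from the uniform variance so the expected r2 equals ``target_r2``:
    sd^2 = slope^2 (b - a)^2 / 12 * (1 - r2) / r2.
    """
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError("target_r2 must be in (0, 1]")
    if n < 3:
        raise ValueError("n must be >= 3")
    a, b = vcmax_range
    rng = np.random.default_rng(seed)
    vcmax = rng.uniform(a, b, n)
    var_fit = slope ** 2 * (b - a) ** 2 / 12.0
    sd = np.sqrt(var_fit * (1.0 - target_r2) / target_r2)
    jmax = intercept + slope * vcmax + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
    return pd.DataFrame({"Vcmax": vcmax, "Jmax": jmax})
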