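"""Desk-scale big-leaf canopy GPP engine for P-limitation scenario contrasts.

This module reproduces the *structure* of a nutrient-limitation model
experiment — gross primary productivity with leaf-P-constrained biochemistry
versus GPP with unlimited P (leaf N:P ratio at the minimum of 5) — on a
synthetic grid, aggregated into 2-degree latitude bands.  The leaf
biochemistry (Vcmax/Jmax from N and P) is the published predictor; everything
around it (big-leaf scaling, Beer-law light absorption, sinusoidal
photoperiod, fixed Ci/Ca) is deliberately simple plumbing whose constants
are config keys, not published values.  Absolute GPP magnitudes from a full
land-surface model are out of scope; direction and structure are what this
module delivers and what its tests verify.

GPP is gross: day respiration is not subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (KineticConstants, rubisco_limited, rubp_limited,
                       scale_to_leaf_temperature)
from .predictors import (mass_area_convert, p_acquisition_scalar,
                         predict_biochem_mass, unlimited_p_leaf)

__all__ = [
    "CanopyCell",
    "CanopyConfig",
    "ScenarioResult",
    "big_leaf_gpp",
    "scenario_compare",
    "zonal_aggregate",
]

_SECONDS = 3600.0
_GC_PER_UMOL = 12.011e-6  # g C per umol CO2


@dataclass(frozen=True)
class CanopyCell:
    """One grid cell's leaf traits and forcing summary."""

    lat: float                 # degrees, |lat| <= 35
    lon: float
    Nmass: float               # mg g-1
    Pmass: float               # mg g-1
    Ma: float = 100.0          # g m-2
    LAI: float = 5.0           # m2 m-2
    Tgrowth: float = 25.0      # degC, also the leaf temperature used
    ppfd_peak: float = 2000.0  # umol m-2 s-1 at solar noon
    Ca: float = 400.0          # umol mol-1
    CiCa: float = 0.7

    def __post_init__(self):
        if abs(self.lat) > 35.0:
            raise ValueError("cell latitude outside the tropical/subtropical "
                             "domain (|lat| <= 35)")
        if self.LAI < 0:
            raise ValueError("LAI must be >= 0")
        if not (0.0 < self.CiCa < 1.0):
            raise ValueError("CiCa must be in (0, 1)")
        if self.Nmass <= 0 or self.Pmass <= 0 or self.Ma <= 0:
            raise ValueError("Nmass, Pmass and Ma must be > 0")


@dataclass(frozen=True)
class CanopyConfig:
    """Invented plumbing constants (none of them published values)."""

    k_beer: float = 0.5        # canopy light extinction coefficient
    theta: float = 0.7         # NRH light-response curvature
    quantum_yield: float = 0.3 # e- per absorbed photon
    photoperiod_h: float = 12.0
    n_steps: int = 48          # diurnal integration steps
    days_per_year: int = 365


@dataclass
class ScenarioResult:
    """Paired P-limited / P-unlimited GPP with zonal means."""

    per_cell: pd.DataFrame
    zonal: pd.DataFrame
    gpp_limited: float        # area-weighted mean, g C m-2 y-1
    gpp_unlimited: float
    fractional_reduction: float


def _nrh_j(q_abs: float, jmax: float, alpha: float, theta: float) -> float:
    """Non-rectangular-hyperbola electron transport J(Q)."""
    if q_abs <= 0.0 or jmax <= 0.0:
        return 0.0
    b = alpha * q_abs + jmax
    disc = b * b - 4.0 * theta * alpha * q_abs * jmax
    return (b - math.sqrt(disc)) / (2.0 * theta)


def big_leaf_gpp(cell: CanopyCell,
                 coeff_set: str = "methods",
                 kin: KineticConstants | None = None,
                 config: CanopyConfig | None = None,
                 pmass: float | None = None) -> float:
    """Annual gross primary productivity of one cell, g C m-2 y-1.

    Leaf Vcmax/Jmax come from the published mass-basis N/P predictor
    (``coeff_set``), converted to area basis with the cell's Ma.  The canopy
    is a single big leaf: photosynthetic capacities are scaled by
    (1 - exp(-k LAI))/k and incident light by (1 - exp(-k LAI)) (Beer law);
    electron transport follows a non-rectangular hyperbola of absorbed PPFD;
    Ci is fixed at CiCa * Ca; PPFD follows a half-sine photoperiod.
    Deterministic; ``pmass`` overrides the cell's leaf P (used by the
    unlimited-P scenario).
    """
    config = config or CanopyConfig()
    kin = kin or KineticConstants(Tgrowth=cell.Tgrowth)
    p = cell.Pmass if pmass is None else pmass

    vc_mass, jm_mass = predict_biochem_mass(cell.Nmass, p, coeff_set)
    vc25 = mass_area_convert(vc_mass, cell.Ma)
    jm25 = mass_area_convert(jm_mass, cell.Ma)

    tleaf = cell.Tgrowth
    vcmax = scale_to_leaf_temperature(vc25, "Vcmax", kin, tleaf)
    jmax = scale_to_leaf_temperature(jm25, "Jmax", kin, tleaf)

    k = config.k_beer
    if cell.LAI == 0:
        return 0.0
    fabs = 1.0 - math.exp(-k * cell.LAI)  # absorbed light fraction
    fcap = fabs / k                        # big-leaf capacity scaling
    vcmax_c = vcmax * fcap
    jmax_c = jmax * fcap

    ci = cell.CiCa * cell.Ca
    gs = kin.gamma_star(tleaf)
    km = kin.Km(tleaf)
    a_c = float(rubisco_limited(ci, vcmax_c, gs, km))

    # integrate the diurnal cycle (half-sine PPFD over the photoperiod)
    dt_h = config.photoperiod_h / config.n_steps
    daily_umol = 0.0
    for i in range(config.n_steps):
        t = (i + 0.5) * dt_h
        q0 = cell.ppfd_peak * math.sin(math.pi * t / config.photoperiod_h)
        q_abs = q0 * fabs
        j = _nrh_j(q_abs, jmax_c, config.quantum_yield, config.theta)
        a_j = float(rubp_limited(ci, j, gs))
        a_gross = max(min(a_c, a_j), 0.0)
        daily_umol += a_gross * dt_h * _SECONDS
    return daily_umol * config.days_per_year * _GC_PER_UMOL


def scenario_compare(cells: list[CanopyCell],
                     coeff_set: str = "methods",
                     kin: KineticConstants | None = None,
                     config: CanopyConfig | None = None) -> ScenarioResult:
    """Run the P-limited vs unlimited-P GPP contrast over a set of cells.

    The unlimited-P run raises each cell's leaf P to N_mass/5 (never lowered
    below the observed value).  The sigmoidal P-acquisition scalar of the
    cell's N:P ratio is reported as a per-cell diagnostic only — it feeds no
    state back into the GPP calculation.
    """
    if not cells:
        raise ValueError("scenario_compare needs at least one cell")
    rows = []
    for cell in cells:
        p_unltd = max(unlimited_p_leaf(cell.Nmass), cell.Pmass)
        g_lim = big_leaf_gpp(cell, coeff_set, kin, config)
        g_unl = big_leaf_gpp(cell, coeff_set, kin, config, pmass=p_unltd)
        rows.append({
            "lat": cell.lat, "lon": cell.lon,
            "Nmass": cell.Nmass, "Pmass": cell.Pmass,
            "NtoP": cell.Nmass / cell.Pmass,
            "p_acquisition": p_acquisition_scalar(cell.Nmass / cell.Pmass),
            "gpp_limited": g_lim, "gpp_unlimited": g_unl,
            "reduction": 1.0 - g_lim / g_unl if g_unl > 0 else 0.0,
        })
    per_cell = pd.DataFrame(rows)
    zonal = zonal_aggregate(per_cell)
    w = np.cos(np.radians(per_cell["lat"].to_numpy()))
    g_lim = float(np.average(per_cell["gpp_limited"], weights=w))
    g_unl = float(np.average(per_cell["gpp_unlimited"], weights=w))
    frac = 1.0 - g_lim / g_unl if g_unl > 0 else 0.0
    return ScenarioResult(per_cell=per_cell, zonal=zonal,
                          gpp_limited=g_lim, gpp_unlimited=g_unl,
                          fractional_reduction=frac)


def zonal_aggregate(per_cell: pd.DataFrame, band_width: float = 2.0) -> pd.DataFrame:
    """Cos-latitude-weighted means of both scenarios per latitude band.

    Bands are ``band_width`` degrees wide, labelled by their centre.
    """
    df = per_cell.copy()
    df["band"] = (np.floor(df["lat"] / band_width) * band_width
                  + band_width / 2.0)
    rows = []
    for band, grp in df.groupby("band"):
        w = np.cos(np.radians(grp["lat"].to_numpy()))
        row = {"band": float(band), "n_cells": len(grp)}
        for col in ("gpp_limited", "gpp_unlimited"):
            row[col] = float(np.average(grp[col], weights=w))
        row["difference"] = row["gpp_unlimited"] - row["gpp_limited"]
        row["reduction"] = (1.0 - row["gpp_limited"] / row["gpp_unlimited"]
                            if row["gpp_unlimited"] > 0 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("band").reset_index(drop=True)
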