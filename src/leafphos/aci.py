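"""A-Ci curve inversion, quality filtering and species-at-site aggregation.

Each measured CO2-response curve (net assimilation A_net vs intercellular
CO2 Ci, with per-point leaf temperature) is inverted against the forward
FvCB model to estimate the leaf's Vcmax25, Jmax25 and Rd25 by bounded
nonlinear least squares.  Because the forward model scales parameters to the
measured leaf temperature point-by-point, the estimates come out already
normalised to 25 degC.

Quality control applies three inclusion rules to per-leaf records: mean
stomatal conductance gsw >= 30 mmol H2O m-2 s-1, mass-based assimilation
A_mass > 20 nmol g-1 s-1 and curve-fit CV of the initial slope < 30%.
Leaves passing QC are then averaged to one record per species-at-site, the
analysis unit of all downstream regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticConstants, LeafBiochem, net_assimilation

__all__ = [
    "ACiCurve",
    "FvcbFit",
    "fit_aci",
    "curves_from_frame",
    "fit_frame",
    "qc_filter",
    "species_site_means",
    "QC_GSW_MIN",
    "QC_AMASS_MIN",
    "QC_CV_MAX",
]

QC_GSW_MIN = 30.0    # mmol H2O m-2 s-1
QC_AMASS_MIN = 20.0  # nmol g-1 s-1 (rule is strict: A_mass must exceed it)
QC_CV_MAX = 30.0     # % CV of the fitted initial-slope parameter

# Parameter bounds for (Vcmax25, Jmax25, Rd25); deterministic multi-starts.
_BOUNDS = ([1.0, 2.0, 0.0], [500.0, 1000.0, 50.0])
_STARTS = [(30.0, 60.0, 0.5), (75.0, 150.0, 1.5), (150.0, 280.0, 1.0)]


@dataclass
class ACiCurve:
    """One leaf's CO2-response series."""

    ci: np.ndarray        # umol mol-1
    anet: np.ndarray      # umol m-2 s-1
    tleaf: np.ndarray     # degC
    ppfd: np.ndarray      # umol m-2 s-1
    gsw: np.ndarray       # mmol H2O m-2 s-1
    leaf_id: str = ""
    species: str = ""
    site: str = ""
    continent: str = ""

    def __post_init__(self):
        for name in ("ci", "anet", "tleaf", "ppfd", "gsw"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.ci)
        if n < 5:
            raise ValueError("an A-Ci curve needs at least 5 points")
        if any(len(getattr(self, name)) != n for name in ("anet", "tleaf", "ppfd", "gsw")):
            raise ValueError("curve columns must have equal length")
        if np.any(self.ci < 0):
            raise ValueError("Ci must be non-negative")
        if np.ptp(self.ci) == 0:
            raise ValueError("Ci values are all equal; curve not invertible")

    def __len__(self) -> int:
        return len(self.ci)


@dataclass
class FvcbFit:
    """Inversion result for one curve, parameters at 25 degC."""

    biochem: LeafBiochem | None
    rmse: float
    cv_initial_slope: float
    n_points: int
    converged: bool
    qc_flags: set = field(default_factory=set)
    leaf_id: str = ""
    species: str = ""
    site: str = ""
    continent: str = ""
    mean_gsw: float = np.nan


def fit_aci(curve: ACiCurve, kin: KineticConstants | None = None) -> FvcbFit:
    """Estimate (Vcmax25, Jmax25, Rd25) by least-squares inversion.

    Bounded trust-region least squares from three deterministic starts; the
    best optimum is kept.  The CV of the initial slope is the relative
    standard error of the fitted Vcmax25, from the Jacobian-based covariance
    at the optimum.  Non-convergence is flagged, never silent.
    """
    kin = kin or KineticConstants()
    lo, hi = curve.ci.min(), curve.ci.max()
    if not (lo < 250.0 and hi > 400.0):
        warnings.warn(
            f"curve {curve.leaf_id!r}: Ci range [{lo:.0f}, {hi:.0f}] does not span "
            "both a low (<250) and high (>400 umol mol-1) region; "
            "Vcmax/Jmax may be poorly identified", stacklevel=2)

    tleafs = curve.tleaf
    unique_t = np.unique(tleafs)
    n_pts = len(curve)

    def residuals(theta):
        biochem = LeafBiochem(*theta)
        pred = np.empty(n_pts)
        for t in unique_t:  # vectorized per measurement temperature
            m = tleafs == t
            pred[m] = net_assimilation(curve.ci[m], biochem, kin, float(t))
        return pred - curve.anet

    best = None          # best properly converged solution
    best_any = None      # best solution regardless of termination status
    for start in _STARTS:
        try:
            res = least_squares(residuals, start, bounds=_BOUNDS,
                                method="trf", x_scale=[50.0, 100.0, 1.0],
                                xtol=1e-10, ftol=1e-8, gtol=1e-8,
                                max_nfev=2000)
        except Exception:
            continue
        if best_any is None or res.cost < best_any.cost:
            best_any = res
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    converged = best is not None
    if best is None:  # flagged, never silent; parameters still reported
        best = best_any

    n = len(curve)
    if best is None or not np.all(np.isfinite(best.x)):
        return FvcbFit(None, np.nan, np.nan, n, False,
                       leaf_id=curve.leaf_id, species=curve.species,
                       site=curve.site, continent=curve.continent,
                       mean_gsw=float(curve.gsw.mean()))

    vc, jm, rd = best.x
    ssr = 2.0 * best.cost
    dof = max(n - 3, 1)
    s2 = ssr / dof
    jac = best.jac
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se_vc = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_vc = np.inf
    cv = 100.0 * se_vc / vc
    return FvcbFit(
        biochem=LeafBiochem(vc, jm, rd),
        rmse=float(np.sqrt(ssr / n)),
        cv_initial_slope=float(cv),
        n_points=n,
        converged=converged,
        leaf_id=curve.leaf_id, species=curve.species,
        site=curve.site, continent=curve.continent,
        mean_gsw=float(curve.gsw.mean()),
    )


def curves_from_frame(df: pd.DataFrame) -> list[ACiCurve]:
    """Split a long-format gas-exchange table into per-leaf curves.

    Expected columns: leaf_id, species, site, continent, ci, anet, tleaf,
    ppfd, gsw (one row per measurement point).
    """
    required = {"leaf_id", "ci", "anet", "tleaf", "ppfd", "gsw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gas-exchange table missing columns: {sorted(missing)}")
    curves = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        curves.append(ACiCurve(
            ci=grp["ci"].to_numpy(), anet=grp["anet"].to_numpy(),
            tleaf=grp["tleaf"].to_numpy(), ppfd=grp["ppfd"].to_numpy(),
            gsw=grp["gsw"].to_numpy(), leaf_id=str(leaf_id),
            species=str(grp["species"].iloc[0]) if "species" in grp else "",
            site=str(grp["site"].iloc[0]) if "site" in grp else "",
            continent=str(grp["continent"].iloc[0]) if "continent" in grp else "",
        ))
    return curves


def fit_frame(df: pd.DataFrame, kin: KineticConstants | None = None,
              traits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit every leaf in a long-format table; one output row per leaf.

    If a trait table keyed by ``leaf_id`` (columns Nmass, Pmass, Ma) is
    given, mass-based rates and nutrient columns are merged in so the result
    can feed :func:`qc_filter` directly.
    """
    rows = []
    for curve in curves_from_frame(df):
        fit = fit_aci(curve, kin)
        row = {
            "leaf_id": fit.leaf_id, "species": fit.species, "site": fit.site,
            "continent": fit.continent, "n_points": fit.n_points,
            "converged": fit.converged, "rmse": fit.rmse,
            "cv_initial_slope": fit.cv_initial_slope, "gsw": fit.mean_gsw,
        }
        if fit.biochem is not None:
            row.update(Vcmax25=fit.biochem.Vcmax25, Jmax25=fit.biochem.Jmax25,
                       Rd25=fit.biochem.Rd25)
            # light-saturated Anet at a common operating point (Ci=275, 25C)
            row["Anet"] = net_assimilation(275.0, fit.biochem, kin or KineticConstants())
        rows.append(row)
    out = pd.DataFrame(rows)
    if traits is not None:
        out = out.merge(traits, on="leaf_id", how="left")
        if "Ma" in out.columns:
            for area_col, mass_col in (("Anet", "Amass"), ("Vcmax25", "Vcmax_mass"),
                                       ("Jmax25", "Jmax_mass")):
                if area_col in out.columns:
                    out[mass_col] = out[area_col] * 1000.0 / out["Ma"]
            if "Nmass" in out.columns:
                out["Narea"] = out["Nmass"] * out["Ma"] / 1000.0
            if "Pmass" in out.columns:
                out["Parea"] = out["Pmass"] * out["Ma"] / 1000.0
    return out


def qc_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three inclusion rules; return (kept, removed-with-reasons).

    Removal tags: LOW_GSW (gsw < 30), LOW_AMASS (A_mass <= 20), HIGH_CV
    (CV >= 30%), plus MISSING_FIELD when a rule's input is absent — a record
    with missing QC fields is removed, never silently kept.  Every removal
    lists every rule it failed.
    """
    records = records.copy()
    reasons: list[list[str]] = []
    for _, row in records.iterrows():
        tags = []
        for col, bad, tag in (
            ("gsw", lambda v: v < QC_GSW_MIN, "LOW_GSW"),
            ("Amass", lambda v: v <= QC_AMASS_MIN, "LOW_AMASS"),
            ("cv_initial_slope", lambda v: v >= QC_CV_MAX, "HIGH_CV"),
        ):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                tags.append("MISSING_FIELD")
            elif bad(v):
                tags.append(tag)
        reasons.append(tags)
    removed_mask = np.array([len(t) > 0 for t in reasons])
    kept = records.loc[~removed_mask].reset_index(drop=True)
    removed = records.loc[removed_mask].reset_index(drop=True)
    removed["qc_reasons"] = [";".join(t) for t, m in zip(reasons, removed_mask) if m]
    return kept, removed


def species_site_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average QC-passed leaves to one record per species x site.

    Arithmetic means of every numeric column (mass- and area-based fields
    averaged directly, not as ratios of means); group size reported as
    ``n_leaves``.  Conflicting continent labels within a group raise.
    """
    for col in ("species", "site"):
        if col not in records.columns:
            raise ValueError(f"records lack a {col!r} column")
    num_cols = [c for c in records.columns
                if pd.api.types.is_numeric_dtype(records[c]) and c != "n_points"]
    rows = []
    for (sp, site), grp in records.groupby(["species", "site"], sort=False):
        row = {"species": sp, "site": site, "n_leaves": len(grp)}
        if "continent" in grp.columns:
            conts = grp["continent"].dropna().unique()
            if len(conts) > 1:
                raise ValueError(
                    f"conflicting continent labels for {sp}@{site}: {sorted(conts)}")
            row["continent"] = conts[0] if len(conts) else ""
        for c in num_cols:
            row[c] = float(grp[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)
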