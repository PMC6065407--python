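"""Dose-response curve fitting, IC50/AUC, plate QC and screen summaries.

Organoid viability screens use a 7-point half-log dilution series per
compound (successive doses differ by 10^0.5, spanning a 1000-fold range).
Viability is modelled as a two-parameter logistic on log10 concentration
with fixed asymptotes 1 and 0:

    v(x) = 1 / (1 + exp((x - x0) / s)),   IC50 = 10^x0.

AUC is the mean fitted viability over the seven tested doses, so a fully
viable curve has AUC 1 and ``sensitivity = 1 - AUC`` lies in [0, 1]. When
the fitted midpoint lies outside the tested range the IC50 is censored at
the range edge and flagged. Plate quality uses the Z-factor,
``Z = 1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit

HALF_LOG = 10 ** 0.5


def half_log_doses(max_conc: float, n_points: int = 7) -> np.ndarray:
    """Descending half-log dilution ladder starting at ``max_conc``."""
    if max_conc <= 0:
        raise ValueError("max_conc must be positive")
    return max_conc * 10.0 ** (-0.5 * np.arange(n_points))


def _logistic(x, x0, s):
    return 1.0 / (1.0 + np.exp((x - x0) / s))


@dataclass
class DoseResponseFit:
    """Sigmoid fit for one (organoid, compound) pair."""

    organoid: str
    compound: str
    concentrations: np.ndarray  # molar, descending half-log ladder
    viabilities: np.ndarray
    log_ic50: float
    slope: float
    ic50: float
    censored: str | None  # None, "above", or "below"
    auc: float
    converged: bool = True

    @property
    def sensitivity(self) -> float:
        return 1.0 - self.auc


def fit_curve(concentrations, viabilities, organoid: str = "",
              compound: str = "") -> DoseResponseFit:
    """Least-squares logistic fit on log10 concentration.

    Initialization is deterministic (midpoint from the dose whose viability
    is closest to 0.5, slope from the tested range), so identical data give
    identical fits. Non-convergence falls back to a normalized trapezoid AUC
    on the raw points and is flagged.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if conc.shape != viab.shape or conc.ndim != 1:
        raise ValueError("concentrations and viabilities must be matching 1-D arrays")
    if len(conc) < 5:
        raise ValueError("dose-response fitting requires at least 5 points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(viab < 0):
        raise ValueError("viabilities must be non-negative")

    x = np.log10(conc)
    x_min, x_max = float(x.min()), float(x.max())
    x0_init = float(x[np.argmin(np.abs(viab - 0.5))])
    s_init = 0.25 * (x_max - x_min) if x_max > x_min else 0.5
    lo = (x_min - 4.0, 1e-3)
    hi = (x_max + 4.0, 10.0)
    converged = True
    try:
        popt, _ = curve_fit(
            _logistic, x, viab,
            p0=(x0_init, s_init), bounds=(lo, hi), maxfev=20000,
        )
        x0, s = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        x0, s = x0_init, s_init

    if converged:
        auc = float(np.mean(_logistic(x, x0, s)))
    else:
        order = np.argsort(x)
        auc = float(np.trapezoid(viab[order], x[order]) / (x_max - x_min))

    censored = None
    ic50 = 10.0 ** x0
    if x0 > x_max:
        censored = "above"
        ic50 = 10.0 ** x_max
    elif x0 < x_min:
        censored = "below"
        ic50 = 10.0 ** x_min

    return DoseResponseFit(
        organoid=organoid, compound=compound,
        concentrations=conc, viabilities=viab,
        log_ic50=x0, slope=s, ic50=ic50, censored=censored,
        auc=auc, converged=converged,
    )


@dataclass
class PlateQC:
    """Control-well separation summary for one plate."""

    z_factor: float
    n_negative: int
    n_positive: int
    mean_negative: float
    sd_negative: float
    mean_positive: float
    sd_positive: float
    defined: bool = True


def z_factor(negative_controls, positive_controls) -> PlateQC:
    """Z-factor from negative (untreated) and positive (killed) control wells.

    Z = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|; Z <= 1 always, and
    Z > 0 indicates well-separated controls. Undefined (flagged) when the
    control means coincide.
    """
    neg = np.asarray(negative_controls, dtype=float)
    pos = np.asarray(positive_controls, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("z_factor requires >= 2 wells per control group")
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    sd_n = float(neg.std(ddof=1))
    sd_p = float(pos.std(ddof=1))
    if mu_n == mu_p:
        return PlateQC(np.nan, len(neg), len(pos), mu_n, sd_n, mu_p, sd_p,
                       defined=False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return PlateQC(z, len(neg), len(pos), mu_n, sd_n, mu_p, sd_p)


def _metric_value(fit: DoseResponseFit, metric: str) -> float:
    if metric == "AUC":
        return fit.auc
    if metric == "IC50":
        # Censored IC50s sit at the range edge by construction.
        return fit.ic50
    raise ValueError("metric must be 'AUC' or 'IC50'")


def replicate_correlation(fits_rep1, fits_rep2, metric: str = "AUC") -> float:
    """Spearman rank correlation of a fit metric across shared
    (organoid, compound) pairs of two replicate screens."""
    by_key1 = {(f.organoid, f.compound): f for f in fits_rep1}
    by_key2 = {(f.organoid, f.compound): f for f in fits_rep2}
    shared = sorted(set(by_key1) & set(by_key2))
    if len(shared) < 5:
        raise ValueError("replicate correlation requires >= 5 shared pairs")
    a = [_metric_value(by_key1[k], metric) for k in shared]
    b = [_metric_value(by_key2[k], metric) for k in shared]
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class SensitivityMatrix:
    """1-AUC matrix with IC50 threshold counts and clustering orders."""

    matrix: pd.DataFrame  # organoids x compounds of 1-AUC
    ic50_counts: pd.DataFrame  # per organoid: n below 1 uM / 0.1 uM
    row_order: list
    col_order: list


def sensitivity_matrix(fits, thresholds=(1e-6, 1e-7)) -> SensitivityMatrix:
    """Organoids x compounds sensitivity (1-AUC) summary of a screen.

    IC50 threshold counts use uncensored fits only; both axes are ordered by
    complete-linkage hierarchical clustering on Euclidean distance (axes
    with < 2 entries keep their input order).
    """
    fits = list(fits)
    records = [(f.organoid, f.compound, f.sensitivity) for f in fits]
    matrix = (pd.DataFrame(records, columns=["organoid", "compound", "sensitivity"])
              .pivot(index="organoid", columns="compound", values="sensitivity"))
    counts = {}
    for org in matrix.index:
        own = [f for f in fits if f.organoid == org and f.censored is None]
        counts[org] = {
            f"ic50_below_{t:g}M": sum(f.ic50 < t for f in own) for t in thresholds
        }
    counts = pd.DataFrame(counts).T.loc[matrix.index]

    def _order(frame: pd.DataFrame) -> list:
        if len(frame) < 2 or frame.isna().any().any():
            return list(frame.index)
        link = hierarchy.linkage(frame.to_numpy(), method="complete",
                                 metric="euclidean")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    return SensitivityMatrix(
        matrix=matrix,
        ic50_counts=counts,
        row_order=_order(matrix),
        col_order=_order(matrix.T),
    )


def anchored_combination_layout(
    anchor_a: tuple[str, float] = ("cisplatin", 4e-6),
    anchor_b: tuple[str, float] = ("5-fluorouracil", 1e-5),
    titrated: tuple[str, float] = ("epirubicin", 1e-5),
    n_points: int = 7,
) -> pd.DataFrame:
    """Anchored chemotherapy-combination design: two compounds at fixed
    concentrations, the third titrated down a half-log ladder.

    Defaults follow the standard triplet regimen: cisplatin held at 4 uM,
    5-fluorouracil at 10 uM, epirubicin titrated from 10 uM.
    """
    for name, conc in (anchor_a, anchor_b, titrated):
        if conc <= 0:
            raise ValueError(f"concentration for {name} must be positive")
    doses = half_log_doses(titrated[1], n_points)
    return pd.DataFrame({
        "well": np.arange(1, n_points + 1),
        f"{titrated[0]}_conc_M": doses,
        f"{anchor_a[0]}_conc_M": anchor_a[1],
        f"{anchor_b[0]}_conc_M": anchor_b[1],
    })


def fits_table(fits) -> pd.DataFrame:
    """Flat CSV-ready table of dose-response fits."""
    return pd.DataFrame([
        {"organoid": f.organoid, "compound": f.compound,
         "ic50_M": f.ic50, "censored": f.censored or "",
         "log10_ic50": f.log_ic50, "slope": f.slope,
         "auc": f.auc, "sensitivity": f.sensitivity,
         "converged": f.converged}
        for f in fits
    ])
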