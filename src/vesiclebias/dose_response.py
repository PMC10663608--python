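"""Constitutive-signal correction and fixed-slope Hill fitting.

The per-vesicle response is the antibody/receptor fluorescence ratio. The
zero-ligand group estimates the constitutive (ligand-independent) offset,
which is subtracted before fitting ``E(L) = E_top * L / (L + EC50)`` — the
Hill equation with slope fixed at 1 — to all single-vesicle points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "compute_ratios",
    "estimate_constitutive",
    "fit_hill",
    "aggregate",
    "etop_ec50_from_tau",
    "fret_unmix",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """Per-concentration summary: mean ratio, SEM, and vesicle count."""

    ligand_conc: float
    mean_ratio: float
    sem_ratio: float
    n_vesicles: int

    def __post_init__(self) -> None:
        if self.sem_ratio < 0:
            raise ValueError("sem_ratio must be >= 0")
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")


@dataclass(frozen=True)
class HillFit:
    """Result of the slope-1 Hill fit.

    ``cov`` is the 2x2 covariance of (EC50, E_top). When every corrected
    response is zero, ``E_top`` is 0 and EC50 is unidentifiable
    (``ec50_identifiable`` False, EC50 = NaN).
    """

    e_top: float
    e_top_se: float
    ec50: float
    ec50_se: float
    e0: float = 0.0
    e0_se: float = 0.0
    hill_slope: float = 1.0
    cov: tuple = field(default=((0.0, 0.0), (0.0, 0.0)))
    n_points: int = 0
    converged: bool = True
    ec50_identifiable: bool = True

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Corrected model response at concentration(s) ``conc``."""
        conc = np.asarray(conc, dtype=float)
        if not self.ec50_identifiable:
            return np.zeros_like(conc)
        return self.e_top * conc / (conc + self.ec50)

    def to_dict(self) -> dict:
        return {
            "E_top": self.e_top,
            "E_top_se": self.e_top_se,
            "EC50": self.ec50,
            "EC50_se": self.ec50_se,
            "E0": self.e0,
            "E0_se": self.e0_se,
            "hill_slope": self.hill_slope,
            "cov_EC50_Etop": [list(row) for row in self.cov],
            "n_points": self.n_points,
            "converged": self.converged,
            "ec50_identifiable": self.ec50_identifiable,
        }


class RatioError(ValueError):
    """A vesicle record cannot yield a valid response ratio."""


def compute_ratios(records: pd.DataFrame) -> pd.Series:
    """Per-vesicle response ratio antibody_fluor / receptor_fluor.

    Order-preserving. Raises :class:`RatioError` naming the offending
    vesicle if any receptor_fluor is not strictly positive.
    """
    receptor = pd.to_numeric(records["receptor_fluor"])
    bad = receptor <= 0
    if bad.any():
        ids = records.loc[bad, "vesicle_id"].tolist() if "vesicle_id" in records else records.index[bad].tolist()
        raise RatioError(f"nonpositive receptor_fluor for vesicle(s): {ids[:10]}")
    return pd.to_numeric(records["antibody_fluor"]) / receptor


def estimate_constitutive(records_or_ratios) -> tuple[float, float]:
    """Estimate the constitutive offset E0 from the zero-ligand group.

    Accepts either a vesicle table (the ``ligand_conc_nM == 0`` subset is
    used) or an array of zero-ligand response ratios. Returns (mean, SEM).
    """
    if isinstance(records_or_ratios, pd.DataFrame):
        zero = records_or_ratios[records_or_ratios["ligand_conc_nM"] == 0]
        ratios = np.asarray(compute_ratios(zero), dtype=float) if len(zero) else np.array([])
    else:
        ratios = np.asarray(records_or_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError(
            "no zero-ligand vesicles: supply an explicit E0 or fit with a free E0 "
            "(e0_mode='fit')"
        )
    if ratios.size < 2:
        raise ValueError("need >= 2 zero-ligand vesicles to estimate E0 and its SE")
    mean = float(np.mean(ratios))
    sem = float(np.std(ratios, ddof=1) / math.sqrt(ratios.size))
    return mean, sem


def aggregate(records: pd.DataFrame) -> list[DoseResponsePoint]:
    """Per-concentration mean, SEM (sd/sqrt(n)) and count of response ratios.

    Single-vesicle groups get SEM = 0 by convention.
    """
    if len(records) == 0:
        raise ValueError("empty input")
    ratios = compute_ratios(records)
    out = []
    for conc, grp in ratios.groupby(pd.to_numeric(records["ligand_conc_nM"])):
        n = len(grp)
        sem = float(np.std(grp, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(DoseResponsePoint(float(conc), float(np.mean(grp)), sem, n))
    out.sort(key=lambda p: p.ligand_conc)
    return out


def _hill(conc: np.ndarray, ec50: float, e_top: float) -> np.ndarray:
    return e_top * conc / (conc + ec50)


def _hill_free_e0(conc: np.ndarray, ec50: float, e_top: float, e0: float) -> np.ndarray:
    return e0 + e_top * conc / (conc + ec50)


def fit_hill(
    records: pd.DataFrame | None = None,
    *,
    conc: np.ndarray | None = None,
    response: np.ndarray | None = None,
    e0_mode: str | float = "subtract",
) -> HillFit:
    """Fit the slope-1 Hill model to single-vesicle dose-response data.

    Parameters
    ----------
    records : DataFrame, optional
        Vesicle table; ratios are computed internally. Alternatively pass
        raw ``conc`` and ``response`` arrays.
    e0_mode : {'subtract', 'fit'} or float
        'subtract' (default): estimate E0 as the zero-ligand mean ratio and
        subtract it before fitting; requires zero-ligand records. 'fit':
        co-fit E0 as a third parameter. A float fixes E0 to that value.

    Zero-ligand points participate with model value 0 after correction.
    Unweighted least squares over all points; SEs from the covariance.
    """
    if records is not None:
        conc = pd.to_numeric(records["ligand_conc_nM"]).to_numpy(dtype=float)
        response = np.asarray(compute_ratios(records), dtype=float)
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have the same shape")

    if len(np.unique(conc[conc > 0])) < 3:
        raise ValueError("need >= 3 distinct positive concentrations to fit the Hill model")

    e0 = 0.0
    e0_se = 0.0
    fit_e0 = False
    if e0_mode == "subtract":
        e0, e0_se = estimate_constitutive(response[conc == 0])
        corrected = response - e0
    elif e0_mode == "fit":
        fit_e0 = True
        corrected = response
    else:
        e0 = float(e0_mode)
        corrected = response - e0

    # initialization: E_top from the max per-conc mean; EC50 from the
    # concentration nearest half-max (tie-break: lowest concentration)
    concs_sorted = np.array(sorted(np.unique(conc)))
    means = np.array([np.mean(corrected[conc == c]) for c in concs_sorted])
    e_top0 = float(np.max(means))
    if e_top0 <= 0 or np.all(corrected == 0):
        if np.all(corrected == 0):
            return HillFit(
                e_top=0.0, e_top_se=0.0, ec50=float("nan"), ec50_se=float("nan"),
                e0=e0, e0_se=e0_se, n_points=conc.size, converged=True,
                ec50_identifiable=False,
            )
        e_top0 = max(e_top0, float(np.max(np.abs(corrected))), 1e-12)
    positive = concs_sorted[concs_sorted > 0]
    half = e_top0 / 2.0
    resid_half = np.abs(means[np.isin(concs_sorted, positive)] - half)
    ec50_0 = float(positive[np.argmin(resid_half)])  # argmin ties break to lowest conc

    try:
        if fit_e0:
            popt, pcov = curve_fit(
                _hill_free_e0, conc, corrected, p0=[ec50_0, e_top0, float(np.mean(corrected[conc == 0])) if np.any(conc == 0) else 0.0],
                bounds=([1e-12, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
            )
            ec50, e_top, e0 = (float(v) for v in popt)
            ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            ec50_se, e_top_se, e0_se = (float(s) for s in ses)
            cov = tuple(tuple(float(x) for x in row) for row in pcov[:2, :2])
        else:
            popt, pcov = curve_fit(
                _hill, conc, corrected, p0=[ec50_0, e_top0],
                bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000,
            )
            ec50, e_top = (float(v) for v in popt)
            ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            ec50_se, e_top_se = (float(s) for s in ses)
            cov = tuple(tuple(float(x) for x in row) for row in pcov)
        converged = True
    except RuntimeError:
        return HillFit(
            e_top=float("nan"), e_top_se=float("nan"), ec50=float("nan"),
            ec50_se=float("nan"), e0=e0, e0_se=e0_se, n_points=conc.size,
            converged=False,
        )

    return HillFit(
        e_top=e_top, e_top_se=e_top_se, ec50=ec50, ec50_se=ec50_se,
        e0=e0, e0_se=e0_se, cov=cov, n_points=conc.size, converged=converged,
    )


def etop_ec50_from_tau(tau: float, K_L: float, R_max: float) -> tuple[float, float]:
    """Hill parameters implied by the operational model.

    ``E_top = tau*R_max/(tau+1)`` and ``EC50 = K_L/(tau+1)``.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if not K_L > 0:
        raise ValueError("K_L must be > 0")
    if R_max < 0:
        raise ValueError("R_max must be >= 0")
    return tau * R_max / (tau + 1.0), K_L / (tau + 1.0)


def fret_unmix(
    fret_channel,
    donor_channel,
    acceptor_channel,
    donor_bleed: float = 0.33,
    acceptor_bleed: float = 0.07,
):
    """Sensitized FRET emission after bleed-through subtraction.

    ``sensitized = fret - donor_bleed*donor - acceptor_bleed*acceptor``.
    May be negative; reported as-is.
    """
    if donor_bleed < 0 or acceptor_bleed < 0:
        raise ValueError("bleed coefficients must be >= 0")
    fret = np.asarray(fret_channel, dtype=float)
    donor = np.asarray(donor_channel, dtype=float)
    acceptor = np.asarray(acceptor_channel, dtype=float)
    if np.any(fret < 0) or np.any(donor < 0) or np.any(acceptor < 0):
        raise ValueError("channel intensities must be >= 0")
    out = fret - donor_bleed * donor - acceptor_bleed * acceptor
    return float(out) if out.ndim == 0 else out
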