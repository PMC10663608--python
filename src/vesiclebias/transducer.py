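"""Transducer-function fitting and phosphorylation efficiency.

Three-channel data give a per-vesicle stimulus (ligand/receptor fluorescence
ratio, rescaled so the largest per-concentration mean bound fraction is 1)
and a response (constitutive-corrected antibody/receptor ratio). The
transducer function is the hyperbola

    R = f_bound * R_max / (f_bound + K_resp)

fitted by unweighted least squares over all single vesicles. The efficiency
``1/(1+K_resp)`` is the maximal per-receptor response at full occupancy; a
value of 1 marks a full agonist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from vesiclebias.stats import MCSettings, monte_carlo_se

__all__ = [
    "TransducerFit",
    "BinnedTransducer",
    "scale_bound_fraction",
    "fit_transducer",
    "efficiency",
    "bin_transducer",
]


@dataclass(frozen=True)
class TransducerFit:
    """Hyperbolic stimulus-response fit: K_resp, R_max, efficiency + SEs."""

    k_resp: float
    k_resp_se: float
    r_max: float
    r_max_se: float
    efficiency: float
    efficiency_se: float
    n_vesicles: int
    converged: bool = True
    cov: tuple = field(default=((0.0, 0.0), (0.0, 0.0)))

    def predict(self, f_bound: np.ndarray | float) -> np.ndarray | float:
        f = np.asarray(f_bound, dtype=float)
        return f * self.r_max / (f + self.k_resp)

    def to_dict(self) -> dict:
        return {
            "K_resp": self.k_resp,
            "K_resp_se": self.k_resp_se,
            "R_max": self.r_max,
            "R_max_se": self.r_max_se,
            "efficiency": self.efficiency,
            "efficiency_se": self.efficiency_se,
            "n_vesicles": self.n_vesicles,
            "converged": self.converged,
            "cov_Kresp_Rmax": [list(row) for row in self.cov],
        }


@dataclass(frozen=True)
class BinnedTransducer:
    """Binned stimulus-response curve for visualization."""

    centers: tuple
    means: tuple
    sems: tuple
    counts: tuple
    width: float = 0.1
    min_n: int = 50


def scale_bound_fraction(records: pd.DataFrame) -> np.ndarray:
    """Per-vesicle bound fraction from the ligand channel.

    ``raw_i = ligand_fluor_i / receptor_fluor_i``; the scale factor is the
    maximum over ligand-concentration groups of the group mean of raw, so
    the maximum per-concentration mean of the result is exactly 1.
    Individual vesicles may exceed 1.
    """
    if "ligand_fluor" not in records or records["ligand_fluor"].isna().all():
        raise ValueError("ligand_fluor channel is required to compute bound fractions")
    receptor = pd.to_numeric(records["receptor_fluor"]).to_numpy(dtype=float)
    if np.any(receptor <= 0):
        raise ValueError("receptor_fluor must be > 0")
    conc = pd.to_numeric(records["ligand_conc_nM"]).to_numpy(dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 ligand concentrations to scale the bound fraction")
    raw = pd.to_numeric(records["ligand_fluor"]).to_numpy(dtype=float) / receptor
    group_means = pd.Series(raw).groupby(pd.Series(conc)).mean()
    scale = float(group_means.max())
    if scale <= 0:
        raise ValueError("no binding signal in any concentration group (scale factor is 0)")
    return raw / scale


def _hyperbola(f: np.ndarray, k_resp: float, r_max: float) -> np.ndarray:
    return f * r_max / (f + k_resp)


def fit_transducer(
    f_bound: np.ndarray,
    responses: np.ndarray,
    *,
    mc: MCSettings | None = None,
) -> TransducerFit:
    """Fit the hyperbolic transducer to all single-vesicle points.

    ``responses`` must already be corrected for the constitutive signal.
    Negative corrected responses and bound fractions > 1 are retained.
    Efficiency SE is propagated from the K_resp SE by Monte Carlo.
    """
    f = np.asarray(f_bound, dtype=float)
    r = np.asarray(responses, dtype=float)
    if f.shape != r.shape:
        raise ValueError("f_bound and responses must have the same shape")
    if np.unique(f).size < 2:
        raise ValueError("need >= 2 distinct f_bound levels")

    r_max0 = max(float(np.max(r)), 1e-12)
    try:
        popt, pcov = curve_fit(
            _hyperbola, f, r, p0=[0.5, r_max0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return TransducerFit(
            k_resp=float("nan"), k_resp_se=float("nan"), r_max=float("nan"),
            r_max_se=float("nan"), efficiency=float("nan"),
            efficiency_se=float("nan"), n_vesicles=f.size, converged=False,
        )
    k_resp, r_max = (float(v) for v in popt)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    k_resp_se, r_max_se = (float(s) for s in ses)
    eff = efficiency(k_resp)
    eff_se = 0.0
    if k_resp_se > 0:
        eff_se = monte_carlo_se(
            lambda k: np.where(k > -1.0, 1.0 / (1.0 + k), np.nan),
            [k_resp], [k_resp_se], mc or MCSettings(n_draws=100_000),
        )
    return TransducerFit(
        k_resp=k_resp, k_resp_se=k_resp_se, r_max=r_max, r_max_se=r_max_se,
        efficiency=eff, efficiency_se=eff_se, n_vesicles=f.size,
        converged=converged,
        cov=tuple(tuple(float(x) for x in row) for row in pcov),
    )


def efficiency(k_resp: float, *, se: float | None = None, mc: MCSettings | None = None):
    """Phosphorylation efficiency 1/(1+K_resp), in (0, 1].

    With ``se`` given, returns ``(value, se)`` with the SE propagated by
    Monte Carlo from the K_resp uncertainty.
    """
    if k_resp < 0:
        raise ValueError("K_resp must be >= 0")
    value = 1.0 / (1.0 + k_resp)
    if se is None:
        return value
    eff_se = 0.0
    if se > 0:
        eff_se = monte_carlo_se(
            lambda k: np.where(k > -1.0, 1.0 / (1.0 + k), np.nan),
            [k_resp], [se], mc or MCSettings(),
        )
    return value, eff_se


def bin_transducer(
    f_bound: np.ndarray,
    responses: np.ndarray,
    width: float = 0.1,
    min_n: int = 50,
) -> BinnedTransducer:
    """Bin the stimulus axis into half-open intervals [k*w, (k+1)*w).

    Bins with fewer than ``min_n`` vesicles are omitted. Returns per-bin
    center, mean response, SEM, and count.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    f = np.asarray(f_bound, dtype=float)
    r = np.asarray(responses, dtype=float)
    if f.size == 0:
        raise ValueError("empty input")
    idx = np.floor(f / width).astype(int)
    centers, means, sems, counts = [], [], [], []
    for k in sorted(np.unique(idx)):
        sel = idx == k
        n = int(sel.sum())
        if n < min_n:
            continue
        vals = r[sel]
        centers.append((k + 0.5) * width)
        means.append(float(np.mean(vals)))
        sems.append(float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
        counts.append(n)
    return BinnedTransducer(
        centers=tuple(centers), means=tuple(means), sems=tuple(sems),
        counts=tuple(counts), width=width, min_n=min_n,
    )
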