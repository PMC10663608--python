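"""Monte-Carlo uncertainty propagation and hypothesis tests.

SEs of derived quantities (bias coefficients, efficiencies) are obtained by
resampling each input parameter from a Gaussian with the parameter's mean
and standard error and taking the sample SD of the recomputed quantity.
Group comparisons use one-way ANOVA with Tukey's HSD, or pairwise two-tailed
t-tests with the Holm-Šidák step-down correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "MCSettings",
    "TestResult",
    "AnovaTukeyResult",
    "monte_carlo_se",
    "anova_tukey",
    "ttests_holm_sidak",
    "coefficient_groups_from_mc",
]


@dataclass(frozen=True)
class MCSettings:
    """Monte-Carlo propagation settings: number of draws and seed."""

    n_draws: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1_000:
            raise ValueError("n_draws must be >= 1000")


@dataclass(frozen=True)
class TestResult:
    """One pairwise comparison: statistic, raw and adjusted p-values."""

    comparison: tuple
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if not (math.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError("p-values must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "method": self.method,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class AnovaTukeyResult:
    """One-way ANOVA F and p, plus Tukey-HSD-adjusted pairwise results."""

    f_stat: float
    p_value: float
    pairwise: tuple
    degenerate: bool = False


class DomainError(ValueError):
    """Too many Monte-Carlo draws fell outside the function's domain."""


def monte_carlo_se(fn, means, ses, settings: MCSettings | None = None) -> float:
    """SE of ``fn(params)`` under independent Gaussian parameter draws.

    ``fn`` must accept one array per parameter and evaluate elementwise.
    Draws on which ``fn`` is not finite (e.g. a negative EC50 inside a log)
    are rejected and counted; if they exceed 1% of draws a
    :class:`DomainError` is raised with the rejection fraction.
    Deterministic given the seed. Returns 0 when every SE is 0.
    """
    settings = settings or MCSettings()
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if means.shape != ses.shape:
        raise ValueError("means and ses must have the same length")
    if np.any(ses < 0):
        raise ValueError("ses must be >= 0")
    if np.all(ses == 0):
        return 0.0
    rng = np.random.default_rng(settings.seed)
    draws = rng.normal(means, ses, size=(settings.n_draws, means.size))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.asarray(fn(*(draws[:, j] for j in range(means.size))), dtype=float)
    finite = np.isfinite(values)
    bad_frac = 1.0 - finite.mean()
    if bad_frac > 0.01:
        raise DomainError(
            f"{bad_frac:.1%} of {settings.n_draws} draws fell outside the function's domain "
            "(e.g. nonpositive arguments to log); parameter SEs may be too large"
        )
    return float(np.std(values[finite], ddof=1))


def _is_degenerate(groups: list[np.ndarray]) -> bool:
    return all(np.ptp(g) == 0 for g in groups)


def _pairwise_t(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, bool]:
    """Two-tailed two-sample t; degenerate (zero-variance) cases flagged."""
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        if np.mean(g1) == np.mean(g2):
            return 0.0, 1.0, True
        return float("inf"), 0.0, True
    t, p = sps.ttest_ind(g1, g2)
    return float(t), float(p), False


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD on all pairs.

    ``groups`` maps group name to replicate values (each n >= 2). Raw
    pairwise p-values come from unadjusted two-sample t-tests; adjusted
    p-values from the studentized-range (Tukey) distribution.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    degenerate = _is_degenerate(arrays)
    if degenerate:
        # zero within-group variance: F undefined; report flagged nulls
        same = len({float(np.mean(a)) for a in arrays}) == 1
        f_stat, p_value = (0.0, 1.0) if same else (float("inf"), 0.0)
        pairwise = []
        for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
            t, p, _ = _pairwise_t(a, b)
            pairwise.append(TestResult((names[i], names[j]), t, p, p, "tukey_hsd", degenerate=True))
        return AnovaTukeyResult(f_stat, p_value, tuple(pairwise), degenerate=True)

    f_stat, p_value = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = []
    for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
        t, p_raw, deg = _pairwise_t(a, b)
        p_adj = float(hsd.pvalue[i, j])
        p_adj = min(1.0, max(p_adj, p_raw))  # guard numerical inversion of monotonicity
        pairwise.append(TestResult((names[i], names[j]), t, p_raw, p_adj, "tukey_hsd", degenerate=deg))
    return AnovaTukeyResult(float(f_stat), float(p_value), tuple(pairwise))


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Šidák step-down adjustment.

    Sort raw p ascending; ``adj_(i) = 1 - (1 - p_(i))**(m - i + 1)`` with
    1-based rank i; enforce monotone nondecreasing along the sorted order;
    cap at 1. Returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def ttests_holm_sidak(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    labels: list[tuple[str, str]] | None = None,
) -> list[TestResult]:
    """Two-tailed t-tests on each pair, Holm-Šidák-adjusted p-values."""
    if labels is None:
        labels = [(f"group{2*i+1}", f"group{2*i+2}") for i in range(len(pairs))]
    stats_p = []
    for g1, g2 in pairs:
        g1 = np.asarray(g1, dtype=float)
        g2 = np.asarray(g2, dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise ValueError("each group needs n >= 2")
        stats_p.append(_pairwise_t(g1, g2))
    raw = np.array([p for _, p, _ in stats_p])
    adjusted = holm_sidak_adjust(raw)
    adjusted = np.minimum(1.0, np.maximum(adjusted, raw))
    return [
        TestResult(tuple(lab), t, float(p), float(p_adj), "holm_sidak", degenerate=deg)
        for lab, (t, p, deg), p_adj in zip(labels, stats_p, adjusted)
    ]


def coefficient_groups_from_mc(
    coefficients: dict[str, tuple[float, float]],
    n_per_group: int = 3,
    settings: MCSettings | None = None,
) -> dict[str, np.ndarray]:
    """Gaussian pseudo-replicates for group-based tests of coefficients.

    Maps each name to ``n_per_group`` draws from N(mean, se). A
    reconstruction: actual replicate structure behind published group tests
    is generally unavailable, so this bridges MC SEs to ANOVA/t-test inputs.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    settings = settings or MCSettings()
    rng = np.random.default_rng(settings.seed)
    out = {}
    for name, (mean, se) in coefficients.items():
        if se < 0:
            raise ValueError(f"{name}: se must be >= 0")
        out[name] = rng.normal(mean, se, size=n_per_group)
    return out
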