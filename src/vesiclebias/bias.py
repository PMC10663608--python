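"""Bias plots and relative/absolute bias coefficients.

A relative coefficient compares two responses (phosphosites A and B) for a
test entity against a reference entity — another ligand (ligand bias) or the
wild-type receptor (mutation-induced bias):

    beta = log10( (E_top,A * EC50,B / (EC50,A * E_top,B))_test
                * (E_top,B * EC50,A / (EC50,B * E_top,A))_ref )

Positive values mean response A is preferred, negative response B. Because
detection gain enters E_top,A identically in test and reference, the
coefficient is free of measurement bias. Absolute coefficients are defined
from the transducer constants, ``beta_star = log10(K_resp,B / K_resp,A)``,
and chain additively: ``beta_star_test = beta_rel + beta_star_ref``.

Standard errors are propagated by Monte Carlo (see
:func:`vesiclebias.stats.monte_carlo_se`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from vesiclebias.dose_response import HillFit, etop_ec50_from_tau
from vesiclebias.stats import MCSettings, monte_carlo_se

__all__ = [
    "BiasCoefficient",
    "BiasPlotSeries",
    "bias_plot",
    "beta_lig",
    "beta_mut",
    "beta_star_from_kresp",
    "beta_star_transfer",
    "beta_from_tau",
]


@dataclass(frozen=True)
class BiasCoefficient:
    """A log10 bias value with SE and comparison metadata."""

    value: float
    se: float
    kind: str  # {'ligand', 'mutation', 'absolute'}
    response_a: str = "Y1068"
    response_b: str = "Y1173"
    test_entity: str = ""
    reference_entity: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.response_a == self.response_b:
            raise ValueError("response_a and response_b must differ")

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "se": self.se,
            "kind": self.kind,
            "response_A": self.response_a,
            "response_B": self.response_b,
            "test_entity": self.test_entity,
            "reference_entity": self.reference_entity,
            "meta": dict(self.meta),
        }


@dataclass(frozen=True)
class BiasPlotSeries:
    """Paired per-concentration means/SEMs of two responses."""

    ligand_conc: tuple
    mean_a: tuple
    sem_a: tuple
    mean_b: tuple
    sem_b: tuple
    n_a: tuple
    n_b: tuple


def bias_plot(points_a, points_b) -> BiasPlotSeries:
    """Pair two dose-response summaries at their shared concentrations.

    Response A means go on one axis, response B means on the other, at the
    same ligand concentrations, sorted ascending. Raises if the series share
    fewer than two concentrations.
    """
    by_conc_a = {p.ligand_conc: p for p in points_a}
    by_conc_b = {p.ligand_conc: p for p in points_b}
    shared = sorted(set(by_conc_a) & set(by_conc_b))
    if len(shared) < 2:
        raise ValueError(
            "need >= 2 shared concentrations; "
            f"A has {sorted(by_conc_a)}, B has {sorted(by_conc_b)}"
        )
    return BiasPlotSeries(
        ligand_conc=tuple(shared),
        mean_a=tuple(by_conc_a[c].mean_ratio for c in shared),
        sem_a=tuple(by_conc_a[c].sem_ratio for c in shared),
        mean_b=tuple(by_conc_b[c].mean_ratio for c in shared),
        sem_b=tuple(by_conc_b[c].sem_ratio for c in shared),
        n_a=tuple(by_conc_a[c].n_vesicles for c in shared),
        n_b=tuple(by_conc_b[c].n_vesicles for c in shared),
    )


def _check_fit(fit: HillFit, label: str) -> None:
    if not fit.converged:
        raise ValueError(f"{label}: Hill fit did not converge")
    if not fit.ec50_identifiable or not fit.ec50 > 0 or not fit.e_top > 0:
        raise ValueError(f"{label}: bias undefined for nonpositive E_top or EC50")


def _log_ratio(etop_a, ec50_a, etop_b, ec50_b):
    return np.log10(etop_a * ec50_b / (ec50_a * etop_b))


def _relative_beta(
    fit_a_test: HillFit,
    fit_b_test: HillFit,
    fit_a_ref: HillFit,
    fit_b_ref: HillFit,
    kind: str,
    test_entity: str,
    reference_entity: str,
    response_a: str,
    response_b: str,
    mc: MCSettings | None,
) -> BiasCoefficient:
    for fit, label in [
        (fit_a_test, "test/A"), (fit_b_test, "test/B"),
        (fit_a_ref, "ref/A"), (fit_b_ref, "ref/B"),
    ]:
        _check_fit(fit, label)

    def fn(ea_t, ca_t, eb_t, cb_t, ea_r, ca_r, eb_r, cb_r):
        with np.errstate(invalid="ignore", divide="ignore"):
            return _log_ratio(ea_t, ca_t, eb_t, cb_t) - _log_ratio(ea_r, ca_r, eb_r, cb_r)

    means = [
        fit_a_test.e_top, fit_a_test.ec50, fit_b_test.e_top, fit_b_test.ec50,
        fit_a_ref.e_top, fit_a_ref.ec50, fit_b_ref.e_top, fit_b_ref.ec50,
    ]
    ses = [
        fit_a_test.e_top_se, fit_a_test.ec50_se, fit_b_test.e_top_se, fit_b_test.ec50_se,
        fit_a_ref.e_top_se, fit_a_ref.ec50_se, fit_b_ref.e_top_se, fit_b_ref.ec50_se,
    ]
    value = float(fn(*means))
    mc = mc or MCSettings()
    se = monte_carlo_se(fn, means, ses, mc)
    return BiasCoefficient(
        value=value, se=se, kind=kind,
        response_a=response_a, response_b=response_b,
        test_entity=test_entity, reference_entity=reference_entity,
        meta={"log_base": 10, "mc_n_draws": mc.n_draws, "mc_seed": mc.seed},
    )


def beta_lig(
    fit_a_lig: HillFit,
    fit_b_lig: HillFit,
    fit_a_ref: HillFit,
    fit_b_ref: HillFit,
    *,
    ligand: str = "ligand",
    reference: str = "reference",
    response_a: str = "Y1068",
    response_b: str = "Y1173",
    mc: MCSettings | None = None,
) -> BiasCoefficient:
    """Ligand-induced bias coefficient from four Hill fits.

    ``fit_a_lig``/``fit_b_lig`` are the test ligand's fits for responses A
    and B; ``fit_a_ref``/``fit_b_ref`` the reference ligand's.
    """
    return _relative_beta(
        fit_a_lig, fit_b_lig, fit_a_ref, fit_b_ref,
        kind="ligand", test_entity=ligand, reference_entity=reference,
        response_a=response_a, response_b=response_b, mc=mc,
    )


def beta_mut(
    fits_mutant: tuple[HillFit, HillFit],
    fits_wt: tuple[HillFit, HillFit],
    *,
    mutant: str = "L834R",
    wildtype: str = "WT",
    response_a: str = "Y1068",
    response_b: str = "Y1173",
    mc: MCSettings | None = None,
) -> BiasCoefficient:
    """Mutation-induced bias coefficient: mutant vs wild-type, same ligand.

    Each argument is an (A-response fit, B-response fit) pair.
    """
    return _relative_beta(
        fits_mutant[0], fits_mutant[1], fits_wt[0], fits_wt[1],
        kind="mutation", test_entity=mutant, reference_entity=wildtype,
        response_a=response_a, response_b=response_b, mc=mc,
    )


def beta_star_from_kresp(
    k_resp_a: float,
    k_resp_b: float,
    *,
    se_a: float = 0.0,
    se_b: float = 0.0,
    entity: str = "",
    response_a: str = "Y1068",
    response_b: str = "Y1173",
    mc: MCSettings | None = None,
) -> BiasCoefficient:
    """Absolute bias coefficient log10(K_resp,B / K_resp,A).

    Positive values mean response A is preferred. SE by Monte Carlo from the
    supplied K_resp standard errors.
    """
    if not (k_resp_a > 0 and k_resp_b > 0):
        raise ValueError("K_resp values must be > 0")
    value = math.log10(k_resp_b / k_resp_a)
    se = 0.0
    if se_a > 0 or se_b > 0:
        mc = mc or MCSettings()

        def fn(ka, kb):
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.log10(kb / ka)

        se = monte_carlo_se(fn, [k_resp_a, k_resp_b], [se_a, se_b], mc)
    return BiasCoefficient(
        value=value, se=se, kind="absolute",
        response_a=response_a, response_b=response_b,
        test_entity=entity, reference_entity="absolute-scale",
        meta={"log_base": 10},
    )


def beta_star_transfer(
    beta_rel: BiasCoefficient,
    beta_star_ref: BiasCoefficient,
    *,
    mc: MCSettings | None = None,
) -> BiasCoefficient:
    """Absolute coefficient for the test entity of a relative comparison.

    ``beta_star_test = beta_rel + beta_star_ref``; the relative coefficient
    must have been computed against the entity whose absolute coefficient is
    supplied. SE by Monte Carlo on the sum.
    """
    if beta_star_ref.kind != "absolute":
        raise ValueError("beta_star_ref must be an absolute coefficient")
    if beta_rel.reference_entity != beta_star_ref.test_entity:
        raise ValueError(
            f"reference mismatch: relative coefficient is vs {beta_rel.reference_entity!r} "
            f"but absolute coefficient is for {beta_star_ref.test_entity!r}"
        )
    if (beta_rel.response_a, beta_rel.response_b) != (beta_star_ref.response_a, beta_star_ref.response_b):
        raise ValueError("response A/B assignment differs between the two coefficients")
    mc = mc or MCSettings()
    se = monte_carlo_se(
        lambda x, y: x + y, [beta_rel.value, beta_star_ref.value],
        [beta_rel.se, beta_star_ref.se], mc,
    )
    return BiasCoefficient(
        value=beta_rel.value + beta_star_ref.value, se=se, kind="absolute",
        response_a=beta_rel.response_a, response_b=beta_rel.response_b,
        test_entity=beta_rel.test_entity, reference_entity="absolute-scale",
        meta={"log_base": 10, "sign_convention": "beta_star_test = beta_rel + beta_star_ref",
              "chained_from": beta_star_ref.test_entity},
    )


def beta_from_tau(
    tau_a_test: float,
    tau_b_test: float,
    tau_a_ref: float,
    tau_b_ref: float,
    *,
    kind: str = "ligand",
    test_entity: str = "",
    reference_entity: str = "",
    response_a: str = "Y1068",
    response_b: str = "Y1173",
) -> BiasCoefficient:
    """Bias coefficient on the transducer-coefficient route.

    ``beta = log10((tau_A/tau_B)_test * (tau_B/tau_A)_ref)``. With a shared
    ligand dissociation constant this equals the Hill-parameter route
    exactly.
    """
    taus = [tau_a_test, tau_b_test, tau_a_ref, tau_b_ref]
    if not all(t > 0 for t in taus):
        raise ValueError("all tau must be > 0")
    value = math.log10((tau_a_test / tau_b_test) * (tau_b_ref / tau_a_ref))
    return BiasCoefficient(
        value=value, se=0.0, kind=kind,
        response_a=response_a, response_b=response_b,
        test_entity=test_entity, reference_entity=reference_entity,
        meta={"log_base": 10, "route": "tau"},
    )
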