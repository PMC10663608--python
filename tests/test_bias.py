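import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesiclebias import (
    BiasCoefficient,
    beta_from_tau,
    beta_lig,
    beta_mut,
    beta_star_from_kresp,
    beta_star_transfer,
    bias_plot,
    etop_ec50_from_tau,
)
from vesiclebias.dose_response import DoseResponsePoint, HillFit


def exact_fit(e_top, ec50):
    """A HillFit with zero SEs (bias SEs then collapse to 0)."""
    return HillFit(e_top=e_top, e_top_se=0.0, ec50=ec50, ec50_se=0.0)


def points(pairs):
    return [DoseResponsePoint(c, m, 0.01, 100) for c, m in pairs]


class TestBiasPlot:
    def test_identity_line(self):
        a = points([(1.0, 0.2), (10.0, 0.5)])
        series = bias_plot(a, a)
        assert series.mean_a == series.mean_b

    def test_direct_pairing(self):
        a = points([(1.0, 0.2), (10.0, 0.5)])
        b = points([(1.0, 0.1), (10.0, 0.4)])
        series = bias_plot(a, b)
        assert series.ligand_conc == (1.0, 10.0)
        assert series.mean_a == (0.2, 0.5)
        assert series.mean_b == (0.1, 0.4)

    def test_intersection_only_and_sorted(self):
        a = points([(10.0, 0.5), (1.0, 0.2), (3.0, 0.3)])
        b = points([(1.0, 0.1), (10.0, 0.4)])
        series = bias_plot(a, b)
        assert series.ligand_conc == (1.0, 10.0)

    def test_empty_intersection_lists_available(self):
        a = points([(1.0, 0.2), (2.0, 0.3)])
        b = points([(5.0, 0.1), (7.0, 0.4)])
        with pytest.raises(ValueError, match=r"A has.*B has"):
            bias_plot(a, b)

    def test_unbiased_synthetic_ligands_overlap(self):
        # two ligands sharing the transducer pair trace the same bias curve
        from vesiclebias import GenerativeConfig, aggregate, simulate_dose_response

        def series_for(seed):
            pts = {}
            for site, k_resp, r_max in [("Y1068", 0.4, 0.95), ("Y1173", 0.86, 0.39)]:
                config = GenerativeConfig(
                    ligand_concentrations=(0.0, 1.0, 3.0, 10.0, 30.0, 100.0),
                    vesicles_per_concentration=400,
                    K_resp=k_resp,
                    R_max=r_max,
                    E0=0.1,
                    cv_antibody=0.2,
                    seed=seed,
                )
                pts[site] = aggregate(simulate_dose_response(config, {"py_site": site}))
            return bias_plot(pts["Y1068"], pts["Y1173"])

        s1 = series_for(seed=1)
        s2 = series_for(seed=2)
        for m1, m2, e1, e2 in zip(s1.mean_a, s2.mean_a, s1.sem_a, s2.sem_a):
            assert abs(m1 - m2) < 4 * math.hypot(e1, e2)
        for m1, m2, e1, e2 in zip(s1.mean_b, s2.mean_b, s1.sem_b, s2.sem_b):
            assert abs(m1 - m2) < 4 * math.hypot(e1, e2)


class TestBetaLig:
    def test_self_comparison_is_zero(self):
        fa, fb = exact_fit(1.0, 3.0), exact_fit(0.5, 8.0)
        coeff = beta_lig(fa, fb, fa, fb)
        assert coeff.value == pytest.approx(0.0, abs=1e-12)
        assert coeff.se == 0.0

    def test_direct_substitution_log10(self):
        lig_a, lig_b = exact_fit(1.0, 1.0), exact_fit(1.0, 10.0)
        ref = exact_fit(1.0, 1.0)
        coeff = beta_lig(lig_a, lig_b, ref, ref)
        assert coeff.value == pytest.approx(1.0, abs=1e-12)

    def test_detection_gain_cancels(self):
        lig_a, lig_b = exact_fit(1.0, 2.0), exact_fit(0.7, 9.0)
        ref_a, ref_b = exact_fit(0.8, 4.0), exact_fit(0.6, 6.0)
        base = beta_lig(lig_a, lig_b, ref_a, ref_b).value
        scaled = beta_lig(
            exact_fit(3.5 * 1.0, 2.0), lig_b, exact_fit(3.5 * 0.8, 4.0), ref_b
        ).value
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_unit_rescaling_invariance(self):
        # uniform concentration unit change leaves beta unchanged
        fits = [exact_fit(1.0, 2.0), exact_fit(0.7, 9.0), exact_fit(0.8, 4.0), exact_fit(0.6, 6.0)]
        base = beta_lig(*fits).value
        scaled = beta_lig(*[exact_fit(f.e_top, 1000.0 * f.ec50) for f in fits]).value
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_rejects_unconverged_fit(self):
        bad = HillFit(e_top=1.0, e_top_se=0.0, ec50=1.0, ec50_se=0.0, converged=False)
        with pytest.raises(ValueError, match="converge"):
            beta_lig(bad, exact_fit(1, 1), exact_fit(1, 1), exact_fit(1, 1))

    def test_rejects_nonpositive_parameters(self):
        zero = HillFit(e_top=0.0, e_top_se=0.0, ec50=1.0, ec50_se=0.0)
        with pytest.raises(ValueError, match="undefined"):
            beta_lig(zero, exact_fit(1, 1), exact_fit(1, 1), exact_fit(1, 1))

    def test_metadata(self):
        coeff = beta_lig(
            exact_fit(1, 1), exact_fit(1, 1), exact_fit(1, 1), exact_fit(1, 1),
            ligand="epiregulin", reference="EGF",
        )
        assert coeff.kind == "ligand"
        assert coeff.test_entity == "epiregulin"
        assert coeff.reference_entity == "EGF"
        assert coeff.meta["log_base"] == 10


class TestBetaMut:
    def test_identical_fits_zero(self):
        pair = (exact_fit(1.0, 2.0), exact_fit(0.5, 7.0))
        assert beta_mut(pair, pair).value == pytest.approx(0.0, abs=1e-12)

    def test_doubled_ec50_a(self):
        wt = (exact_fit(1.0, 2.0), exact_fit(0.5, 7.0))
        mut = (exact_fit(1.0, 4.0), exact_fit(0.5, 7.0))
        assert beta_mut(mut, wt).value == pytest.approx(-math.log10(2.0), abs=1e-12)

    def test_antisymmetry_on_response_swap(self):
        mut = (exact_fit(1.0, 2.0), exact_fit(0.5, 7.0))
        wt = (exact_fit(0.8, 3.0), exact_fit(0.6, 5.0))
        forward = beta_mut(mut, wt).value
        swapped = beta_mut((mut[1], mut[0]), (wt[1], wt[0])).value
        assert swapped == pytest.approx(-forward, abs=1e-12)


class TestBetaStar:
    def test_paper_worked_value(self):
        coeff = beta_star_from_kresp(0.40, 0.86)
        assert round(coeff.value, 2) == 0.33

    def test_equal_kresp_zero(self):
        assert beta_star_from_kresp(0.5, 0.5).value == 0.0

    def test_swap_flips_sign(self):
        fwd = beta_star_from_kresp(0.40, 0.86).value
        rev = beta_star_from_kresp(0.86, 0.40).value
        assert rev == pytest.approx(-fwd, abs=1e-12)

    def test_positive_means_response_a_preferred(self):
        # K_resp,B > K_resp,A: A more efficient, coefficient positive
        assert beta_star_from_kresp(0.40, 0.86).value > 0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            beta_star_from_kresp(0.0, 1.0)

    def test_mc_se_attached(self):
        from vesiclebias.stats import MCSettings

        coeff = beta_star_from_kresp(
            0.40, 0.86, se_a=0.03, se_b=0.08, mc=MCSettings(n_draws=200_000, seed=3)
        )
        assert coeff.se > 0


class TestBetaStarTransfer:
    def _star(self, value, entity="rho-mEGF"):
        return BiasCoefficient(
            value=value, se=0.0, kind="absolute",
            test_entity=entity, reference_entity="absolute-scale",
        )

    def _rel(self, value, test="EGF", ref="rho-mEGF"):
        return BiasCoefficient(
            value=value, se=0.0, kind="ligand", test_entity=test, reference_entity=ref
        )

    def test_unbiased_ligand_inherits_reference_value(self):
        out = beta_star_transfer(self._rel(0.0), self._star(0.33))
        assert out.value == pytest.approx(0.33)

    def test_zero_reference(self):
        out = beta_star_transfer(self._rel(0.5), self._star(0.0))
        assert out.value == pytest.approx(0.5)

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            beta_star_transfer(self._rel(0.1, ref="TGFa"), self._star(0.33))

    def test_consistency_with_kresp_route(self):
        # beta_rel from Hill parameters + reference beta_star equals the
        # direct K_resp route when all fits share K_L
        k_l = 10.0
        test_k = {"A": 0.3, "B": 0.9}
        ref_k = {"A": 0.4, "B": 0.86}
        fits = {}
        for name, ks in [("test", test_k), ("ref", ref_k)]:
            for site in "AB":
                e_top, ec50 = etop_ec50_from_tau(1.0 / ks[site], k_l, 1.0)
                fits[(name, site)] = exact_fit(e_top, ec50)
        rel = beta_lig(
            fits[("test", "A")], fits[("test", "B")],
            fits[("ref", "A")], fits[("ref", "B")],
            ligand="test", reference="ref",
        )
        star_ref = beta_star_from_kresp(ref_k["A"], ref_k["B"], entity="ref")
        chained = beta_star_transfer(rel, star_ref)
        direct = beta_star_from_kresp(test_k["A"], test_k["B"], entity="test")
        assert chained.value == pytest.approx(direct.value, abs=1e-10)


class TestBetaFromTau:
    def test_all_equal_zero(self):
        assert beta_from_tau(2.0, 2.0, 2.0, 2.0).value == 0.0

    def test_direct_substitution(self):
        assert beta_from_tau(10.0, 1.0, 3.0, 3.0).value == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            beta_from_tau(0.0, 1.0, 1.0, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        tau_a=st.floats(1e-3, 1e3),
        tau_b=st.floats(1e-3, 1e3),
        tau_ar=st.floats(1e-3, 1e3),
        tau_br=st.floats(1e-3, 1e3),
        k_l=st.floats(1e-2, 1e4),
        r_max=st.floats(1e-3, 1e2),
    )
    def test_equals_hill_parameter_route(self, tau_a, tau_b, tau_ar, tau_br, k_l, r_max):
        fits = {}
        for key, tau in [("a", tau_a), ("b", tau_b), ("ar", tau_ar), ("br", tau_br)]:
            e_top, ec50 = etop_ec50_from_tau(tau, k_l, r_max)
            fits[key] = exact_fit(e_top, ec50)
        via_hill = beta_lig(fits["a"], fits["b"], fits["ar"], fits["br"]).value
        via_tau = beta_from_tau(tau_a, tau_b, tau_ar, tau_br).value
        assert abs(via_hill - via_tau) < 1e-10


class TestCoefficientProperties:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.05, 20.0), min_size=8, max_size=8))
    def test_antisymmetry(self, params):
        ea, ca, eb, cb, ear, car, ebr, cbr = params
        fwd = beta_lig(exact_fit(ea, ca), exact_fit(eb, cb), exact_fit(ear, car), exact_fit(ebr, cbr)).value
        rev = beta_lig(exact_fit(eb, cb), exact_fit(ea, ca), exact_fit(ebr, cbr), exact_fit(ear, car)).value
        assert rev == pytest.approx(-fwd, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.05, 20.0), min_size=12, max_size=12))
    def test_reference_chaining(self, params):
        f = [exact_fit(params[2 * i], params[2 * i + 1]) for i in range(6)]
        lig1, lig2, lig3 = (f[0], f[1]), (f[2], f[3]), (f[4], f[5])
        b13 = beta_lig(lig1[0], lig1[1], lig3[0], lig3[1]).value
        b12 = beta_lig(lig1[0], lig1[1], lig2[0], lig2[1]).value
        b23 = beta_lig(lig2[0], lig2[1], lig3[0], lig3[1]).value
        assert b13 == pytest.approx(b12 + b23, abs=1e-9)

    def test_response_labels_must_differ(self):
        with pytest.raises(ValueError):
            BiasCoefficient(value=0.0, se=0.0, kind="ligand", response_a="Y1068", response_b="Y1068")
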