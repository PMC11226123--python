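"""ACE/ADE liability-threshold fits: Weinberg rule, closed-form
method-of-moments oracle, and joint ML self-consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liabtwin import (
    BiometricModel,
    ConcordanceTable,
    GenerativeConfig,
    WeinbergAdjustment,
    aggregate,
    expected_pair_correlation,
    fit_biometric,
    mom_oracle,
    simulate_pairs,
    weinberg,
)
from liabtwin.biometric import group_coefficients

from .conftest import TAU_017, exact_table


class TestWeinberg:
    def test_published_pair_counts_give_074(self):
        adj = weinberg(22_331, 11_619)
        assert round(adj.gamma, 2) == 0.74
        assert adj.p_mz == pytest.approx((22_331 - 11_619) / 22_331)

    def test_all_dz(self):
        adj = weinberg(5_000, 5_000)
        assert adj.p_mz == 0.0
        assert adj.gamma == 0.5
        assert adj.delta_same_sex == 0.25

    def test_all_mz(self):
        adj = weinberg(5_000, 0)
        assert adj.p_mz == 1.0
        assert adj.gamma == 1.0

    def test_excess_opposite_sex_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            adj = weinberg(100, 150)
        assert adj.p_mz == 0.0
        assert adj.gamma == 0.5

    def test_requires_same_sex_pairs(self):
        with pytest.raises(ValueError):
            weinberg(0, 10)


class TestExpectedPairCorrelation:
    def setup_method(self):
        self.coeffs = group_coefficients(weinberg(22_331, 11_619))

    def test_same_sex_ace(self):
        r = expected_pair_correlation("ACE", 0.57, 0.0, self.coeffs["same_sex"])
        assert r == pytest.approx(0.74 * 0.57, abs=2e-4)

    def test_opposite_sex_ace(self):
        r = expected_pair_correlation("ACE", 0.57, 0.0, self.coeffs["opposite_sex"])
        assert r == pytest.approx(0.285, abs=1e-12)

    def test_opposite_sex_ade_dominance(self):
        r = expected_pair_correlation("ADE", 0.0, 1.0, self.coeffs["opposite_sex"])
        assert r == pytest.approx(0.25, abs=1e-12)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            expected_pair_correlation("ACDE", 0.5, 0.1, self.coeffs["same_sex"])


class TestMomOracle:
    def setup_method(self):
        self.adj = weinberg(22_331, 11_619)

    def test_forward_generated_correlations(self):
        g = self.adj.gamma
        a2, c2, e2 = mom_oracle(g * 0.57, 0.5 * 0.57, self.adj, "ACE")
        assert a2 == pytest.approx(0.57, abs=1e-12)
        assert c2 == pytest.approx(0.0, abs=1e-12)
        assert e2 == pytest.approx(0.43, abs=1e-12)

    def test_equal_correlations_no_genetic_signal(self):
        a2, c2, _ = mom_oracle(0.3, 0.3, self.adj, "ACE")
        assert a2 == pytest.approx(0.0, abs=1e-12)
        assert c2 == pytest.approx(0.3, abs=1e-12)

    def test_maximal_heritability(self):
        a2, c2, _ = mom_oracle(self.adj.gamma, 0.5, self.adj, "ACE")
        assert a2 == pytest.approx(1.0, abs=1e-12)
        assert c2 == pytest.approx(0.0, abs=1e-12)

    def test_ade_linear_system(self):
        g, d_ss = self.adj.gamma, self.adj.delta_same_sex
        r_ss = g * 0.5 + d_ss * 0.2
        r_os = 0.5 * 0.5 + 0.25 * 0.2
        a2, d2, e2 = mom_oracle(r_ss, r_os, self.adj, "ADE")
        assert a2 == pytest.approx(0.5, abs=1e-10)
        assert d2 == pytest.approx(0.2, abs=1e-10)
        assert e2 == pytest.approx(0.3, abs=1e-10)

    def test_gamma_half_not_identified(self):
        adj = weinberg(5_000, 5_000)
        with pytest.raises(ValueError, match="not identified"):
            mom_oracle(0.4, 0.3, adj, "ACE")

    @given(st.floats(0.3, 0.6), st.floats(0.05, 0.25))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_same_sex_correlation(self, r_ss, r_os):
        a2_lo, _, _ = mom_oracle(r_ss, r_os, self.adj, "ACE")
        a2_hi, _, _ = mom_oracle(r_ss + 0.05, r_os, self.adj, "ACE")
        assert a2_hi > a2_lo


class TestBiometricFit:
    def test_recovers_exact_paper_design(self, paper_design_tables):
        adj = weinberg(22_331, 11_619)
        res = fit_biometric(paper_design_tables, model="ACE", adjustment=adj)
        assert res.converged
        assert res.a2 == pytest.approx(0.57, abs=5e-3)
        assert res.c2_or_d2 == pytest.approx(0.0, abs=5e-3)
        assert res.tau == pytest.approx(TAU_017, abs=5e-3)

    def test_standardization_identity_machine_precision(self, paper_design_tables):
        res = fit_biometric(paper_design_tables, adjustment=weinberg(22_331, 11_619))
        assert res.a2 + res.c2_or_d2 + res.e2 == pytest.approx(1.0, abs=1e-15)
        for comp in (res.a2, res.c2_or_d2, res.e2):
            assert 0.0 <= comp <= 1.0

    def test_equal_group_correlations_give_pure_shared_environment(self):
        tables = [
            exact_table(0.3, 0.9542, 5e4, group="same_sex"),
            exact_table(0.3, 0.9542, 5e4, group="opposite_sex"),
        ]
        res = fit_biometric(tables, adjustment=weinberg(22_331, 11_619))
        assert res.a2 == pytest.approx(0.0, abs=5e-3)
        assert res.c2_or_d2 == pytest.approx(0.3, abs=5e-3)

    def test_ml_matches_mom_oracle_on_exact_tables(self):
        adj = weinberg(22_331, 11_619)
        for a2_true, c2_true in [(0.4, 0.2), (0.6, 0.05), (0.2, 0.4)]:
            r_ss = adj.gamma * a2_true + c2_true
            r_os = 0.5 * a2_true + c2_true
            tables = [
                exact_table(r_ss, TAU_017, 1e5, group="same_sex"),
                exact_table(r_os, TAU_017, 1e5, group="opposite_sex"),
            ]
            ml = fit_biometric(tables, adjustment=adj)
            mom = mom_oracle(r_ss, r_os, adj, "ACE")
            assert ml.a2 == pytest.approx(mom[0], abs=5e-3)
            assert ml.c2_or_d2 == pytest.approx(mom[1], abs=5e-3)

    def test_ade_fit_recovers_dominance(self):
        adj = weinberg(22_331, 11_619)
        r_ss = adj.gamma * 0.45 + adj.delta_same_sex * 0.15
        r_os = 0.5 * 0.45 + 0.25 * 0.15
        tables = [
            exact_table(r_ss, TAU_017, 2e5, group="same_sex"),
            exact_table(r_os, TAU_017, 2e5, group="opposite_sex"),
        ]
        res = fit_biometric(tables, model="ADE", adjustment=adj)
        assert res.a2 == pytest.approx(0.45, abs=0.01)
        assert res.c2_or_d2 == pytest.approx(0.15, abs=0.01)
        assert res.component_label == "d2"

    def test_twin_sibling_design(self):
        adj = weinberg(22_331, 11_619)
        r_ss = adj.gamma * 0.5 + 0.2
        r_sib = 0.5 * 0.5 + 0.2
        tables = [
            exact_table(r_ss, TAU_017, 1e5, group="same_sex"),
            exact_table(r_sib, TAU_017, 1e5, group="sibling"),
        ]
        res = fit_biometric(tables, design="twin_sibling", adjustment=adj)
        assert res.a2 == pytest.approx(0.5, abs=5e-3)
        assert res.c2_or_d2 == pytest.approx(0.2, abs=5e-3)

    def test_twin_sibling_needs_explicit_adjustment(self):
        tables = [
            exact_table(0.5, TAU_017, 1e4, group="same_sex"),
            exact_table(0.3, TAU_017, 1e4, group="sibling"),
        ]
        with pytest.raises(ValueError, match="adjustment"):
            fit_biometric(tables, design="twin_sibling")

    def test_identical_kappa_not_identified(self):
        adj = weinberg(5_000, 5_000)  # gamma = 0.5 == DZ
        tables = [
            exact_table(0.3, TAU_017, 1e4, group="same_sex"),
            exact_table(0.3, TAU_017, 1e4, group="opposite_sex"),
        ]
        with pytest.raises(ValueError, match="not identified"):
            fit_biometric(tables, adjustment=adj)

    def test_missing_group_errors(self):
        tables = [exact_table(0.4, TAU_017, 1e4, group="same_sex")]
        with pytest.raises(ValueError, match="missing"):
            fit_biometric(tables)

    def test_ace_loglik_at_least_nested_ae(self, paper_design_tables):
        adj = weinberg(22_331, 11_619)
        model = BiometricModel(paper_design_tables, adjustment=adj)
        res = model.fit()
        llf_ae = model._max_loglike_fixed("c2_or_d2", 0.0)
        assert res.llf >= llf_ae - 1e-6

    def test_simulated_recovery_within_ci(self):
        cfg = GenerativeConfig(
            n_mz_pairs=8_000, n_dz_pairs=16_000, a2=0.6, c2=0.1,
            prevalence=0.17, seed=77,
        )
        res = fit_biometric(aggregate(simulate_pairs(cfg)))
        lo, hi = res.conf_int()["a2"]
        assert lo <= 0.6 <= hi
        assert res.a2 == pytest.approx(0.6, abs=0.1)

    def test_profile_ci_brackets_estimate(self, paper_design_tables):
        scaled = [t.scaled(0.02) for t in paper_design_tables]  # N = 2000/group
        res = fit_biometric(scaled, adjustment=weinberg(22_331, 11_619))
        ci = res.conf_int(method="profile")
        lo, hi = ci["a2"]
        assert lo <= res.a2 <= hi
        assert (hi - lo) < 1.0

    def test_group_specific_thresholds_option(self):
        tables = [
            exact_table(0.42, 0.8, 5e4, group="same_sex"),
            exact_table(0.28, 1.1, 5e4, group="opposite_sex"),
        ]
        res = fit_biometric(
            tables, adjustment=weinberg(22_331, 11_619), shared_tau=False
        )
        assert res.converged

    def test_summary_contains_components(self, paper_design_tables):
        s = fit_biometric(
            paper_design_tables, adjustment=weinberg(22_331, 11_619)
        ).summary()
        assert "a2" in s and "e2" in s and "gamma" in s
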