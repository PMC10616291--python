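"""qPCR arithmetic: enrichment, ddCt, SELECT calibration, ANOVA + Dunnett."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from m6adose import qpcr
from m6adose import synthetic as syn


class TestRelativeAmount:
    def test_doubling_per_cycle(self):
        assert qpcr.relative_amount(20.0) / qpcr.relative_amount(21.0) == pytest.approx(2.0)

    def test_identity_at_zero_ct(self):
        assert qpcr.relative_amount(0.0) == 1.0

    def test_partial_efficiency(self):
        r = qpcr.relative_amount(20.0, efficiency=1.9) / qpcr.relative_amount(23.0, efficiency=1.9)
        assert r == pytest.approx(1.9**3)

    def test_efficiency_range_enforced(self):
        for bad in (1.0, 2.5, 0.9):
            with pytest.raises(ValueError):
                qpcr.relative_amount(20.0, efficiency=bad)


class TestMeripEnrichment:
    def test_identity_and_stated_formula(self):
        assert qpcr.merip_enrichment(25.0, 25.0, 500.0, 500.0) == pytest.approx(1.0)
        # 2^3 * (500 / 2000) = 2.0
        assert qpcr.merip_enrichment(24.0, 27.0, 2000.0, 500.0) == pytest.approx(2.0)

    def test_two_step_recomputation_oracle(self, rng):
        """Matches amounts-then-mass-normalized-ratio recomputation to 1e-12."""
        ct_ip = rng.uniform(18, 30, 50)
        ct_in = rng.uniform(18, 30, 50)
        m_ip = rng.uniform(100, 4000, 50)
        m_in = rng.uniform(100, 4000, 50)
        got = qpcr.merip_enrichment(ct_ip, ct_in, m_ip, m_in)
        amount_ip = 2.0**-ct_ip / m_ip  # amount per ng
        amount_in = 2.0**-ct_in / m_in
        np.testing.assert_allclose(got, amount_ip / amount_in, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ct_ip=st.floats(15, 35), delta=st.floats(0.01, 5), scale=st.floats(0.1, 10)
    )
    def test_monotonicity_and_mass_scale_invariance(self, ct_ip, delta, scale):
        base = qpcr.merip_enrichment(ct_ip, 27.0)
        lower_ct = qpcr.merip_enrichment(ct_ip - delta, 27.0)
        assert lower_ct > base  # enrichment strictly increases as ct_ip drops
        scaled = qpcr.merip_enrichment(ct_ip, 27.0, 2000.0 * scale, 500.0 * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unpaired_record_rejected(self):
        ct = syn.simulate_merip_ct({"a": 2.0}, n_replicates=2, seed=0)
        broken = ct[~((ct["fraction"] == "input") & (ct["replicate"] == 2))]
        with pytest.raises(ValueError, match="unpaired"):
            qpcr.merip_enrichment_table(broken)


class TestRelativeM6aLevel:
    def test_self_normalization_and_direct_ratio(self):
        fold, se = qpcr.relative_m6a_level([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert fold == 1.0 and se == 0.0
        fold, _ = qpcr.relative_m6a_level([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert fold == 2.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            qpcr.relative_m6a_level([1.0], [0.0, 0.0])

    def test_monte_carlo_threefold_recovery(self):
        """Simulated 3-fold enrichment, Ct sd 0.1, n=5: mean fold in [2.8, 3.2]."""
        folds = []
        for s in range(1000):
            ct = syn.simulate_merip_ct({"ctl": 1.5, "ir": 4.5}, ct_sd=0.1, seed=s)
            enr = qpcr.merip_enrichment_table(ct)
            g = enr.loc[enr["group_id"] == "ir", "enrichment"].to_numpy()
            c = enr.loc[enr["group_id"] == "ctl", "enrichment"].to_numpy()
            folds.append(qpcr.relative_m6a_level(g, c)[0])
        assert 2.8 <= np.mean(folds) <= 3.2


class TestPrimerFeasibility:
    def test_boundary_inclusive_and_fail(self):
        ok, ratio = qpcr.primer_feasibility(4.0, 1.0)
        assert ok and ratio == 4.0
        bad, _ = qpcr.primer_feasibility(1.0, 1.0)
        assert not bad

    def test_randomized_agreement_with_direct_ratio(self, rng):
        ip = rng.lognormal(1, 1, 50)
        igg = rng.lognormal(-1, 1, 50)
        for a, b in zip(ip, igg):
            ok, ratio = qpcr.primer_feasibility(a, b)
            assert ok == (a / b >= 4.0)
            assert ratio == pytest.approx(a / b)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            qpcr.primer_feasibility(0.0, 1.0)


class TestDdct:
    def test_identity_and_direct_evaluation(self):
        assert qpcr.relative_expression_ddct(24, 18, 24, 18) == 1.0
        # ddCt = -1 -> fold 2
        assert qpcr.relative_expression_ddct(23, 18, 24, 18) == pytest.approx(2.0)

    def test_amount_ratio_equivalence_oracle(self, rng):
        """ddCt equals relative_amount(target)/relative_amount(ref), control-normalized."""
        cts = rng.uniform(15, 30, (20, 4))
        for t_s, r_s, t_c, r_c in cts:
            got = qpcr.relative_expression_ddct(t_s, r_s, t_c, r_c)
            sample = qpcr.relative_amount(t_s) / qpcr.relative_amount(r_s)
            control = qpcr.relative_amount(t_c) / qpcr.relative_amount(r_c)
            assert got == pytest.approx(sample / control, rel=1e-9)


class TestSelectCurve:
    def test_exact_interpolation_and_anchor(self):
        fr = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        ct_100 = 20.0
        r_true = 0.1 + 0.9 * fr
        cts = ct_100 + np.log2(r_true)
        curve = qpcr.fit_select_curve(fr, cts)
        assert curve.slope_ == pytest.approx(0.9, abs=1e-9)
        assert curve.intercept_ == pytest.approx(0.1, abs=1e-9)
        assert curve.r2_ == pytest.approx(1.0)
        # the 100% standard's own relative product is 1 by construction
        assert curve._relative_product(ct_100, curve.ct_ref_100_) == pytest.approx(1.0)

    def test_normal_equation_oracle_on_noisy_data(self, rng):
        fr = np.tile([0.0, 0.25, 0.5, 0.75, 1.0], 3)
        cts = 20.0 + np.log2(0.15 + 0.85 * fr) + rng.normal(0, 0.05, fr.size)
        curve = qpcr.fit_select_curve(fr, cts)
        r = 2.0 ** (cts - cts[np.isclose(fr, 1.0)].mean())
        slope = np.cov(fr, r, ddof=1)[0, 1] / np.var(fr, ddof=1)
        intercept = r.mean() - slope * fr.mean()
        assert curve.slope_ == pytest.approx(slope, rel=1e-9)
        assert curve.intercept_ == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            qpcr.fit_select_curve([1.0, 1.0, 1.0], [20.0, 20.1, 19.9])
        with pytest.raises(ValueError, match="100%"):
            qpcr.fit_select_curve([0.0, 0.3, 0.6], [21.0, 20.5, 20.0])

    def test_abundance_mode_flips_slope_sign(self):
        fr = np.array([0.0, 0.5, 1.0])
        cts = 20.0 + np.log2(0.1 + 0.9 * fr)
        lit = qpcr.fit_select_curve(fr, cts, normalization="literal")
        ab = qpcr.fit_select_curve(fr, cts, normalization="abundance")
        assert lit.slope_ > 0 > ab.slope_

    def test_fraction_estimation_fixed_points_and_clamp(self):
        fr = np.array([0.0, 0.5, 1.0])
        cts = 20.0 + np.log2(0.1 + 0.9 * fr)
        curve = qpcr.fit_select_curve(fr, cts)
        est, flag = qpcr.estimate_select_fraction(20.0, curve)
        assert est == pytest.approx(1.0) and not flag
        # r = intercept -> fraction 0
        est0, _ = qpcr.estimate_select_fraction(20.0 + np.log2(0.1), curve)
        assert est0 == pytest.approx(0.0, abs=1e-9)
        # beyond the 100% anchor: clamped with the out-of-range flag
        est_hi, flag_hi = qpcr.estimate_select_fraction(25.0, curve)
        assert est_hi == 1.0 and flag_hi

    def test_inverse_property_on_grid(self):
        """Zero-noise curve generation followed by estimation is the identity."""
        grid = {chr(97 + i): f for i, f in enumerate(np.linspace(0, 1, 11))}
        std, samples = syn.simulate_select_ct(grid, ct_sd=0.0, n_replicates=1, seed=0)
        curve = qpcr.fit_select_curve(std["m6a_fraction"].to_numpy(), std["ct"].to_numpy())
        est, _ = qpcr.estimate_select_fraction(samples["ct"].to_numpy(), curve)
        np.testing.assert_allclose(est, np.linspace(0, 1, 11), atol=1e-9)


class TestAnovaDunnett:
    def test_two_group_case_matches_ttest(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        comp = qpcr.anova_dunnett([a, b], n_mc=200_000, seed=0)
        _, p = stats.ttest_ind(b, a)
        assert comp.adjusted_pvalues[1] == pytest.approx(p, abs=0.01)

    def test_overwhelming_effect(self, rng):
        groups = [rng.normal(0, 1, 5) for _ in range(3)] + [rng.normal(10, 1, 5)]
        comp = qpcr.anova_dunnett(groups, n_mc=50_000, seed=0)
        assert comp.adjusted_pvalues[3] < 0.001

    def test_dominance_over_raw_p(self, rng):
        for s in range(20):
            groups = [rng.normal(0, 1, 4) for _ in range(5)]
            comp = qpcr.anova_dunnett(groups, n_mc=2000, seed=s)
            assert np.all(comp.adjusted_pvalues[1:] >= comp.raw_pvalues[1:])

    def test_agrees_with_scipy_dunnett(self, rng):
        """Independent cross-check against the multivariate-t implementation."""
        groups = [rng.normal(0, 1, 8), rng.normal(0.8, 1, 8), rng.normal(0.3, 1, 8)]
        comp = qpcr.anova_dunnett(groups, control_index=0, n_mc=200_000, seed=1)
        ref = stats.dunnett(groups[1], groups[2], control=groups[0])
        np.testing.assert_allclose(comp.adjusted_pvalues[1:], ref.pvalue, atol=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            qpcr.anova_dunnett([[1.0, 2.0]])
        with pytest.raises(ValueError):
            qpcr.anova_dunnett([[1.0], [2.0]])
        with pytest.raises(ValueError):
            qpcr.anova_dunnett([[1.0, 2.0], [3.0, 4.0]], control_index=5)
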