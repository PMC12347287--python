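"""Micellar-diagram fitting, stoichiometry selection and bootstrap."""

import numpy as np
import pytest

import lipocd as L
from lipocd.errors import ValidationError


def _diag(binding, cd_grid, seed=0, cv=0.0, reps=1):
    return L.make_diagram(
        L.SyntheticDiagramSpec(
            binding=binding, cd_grid_m=cd_grid, seed=seed,
            noise_cv=cv, n_replicates=reps,
        )
    )


class TestBuildDiagram:
    def _fits(self, cds_mm, cmcs):
        return [
            (cd, L.BreakpointFit(cmc, 0, 5, 8, -43, 6, 0.0, 6, 6))
            for cd, cmc in zip(cds_mm, cmcs)
        ]

    def test_mM_levels_converted_and_sorted(self):
        fits = self._fits([0, 1, 2.5, 5, 10], [6, 10, 17, 28, 49])
        d = L.build_diagram(fits)
        assert np.allclose(d.cd_conc_m, [0, 0.001, 0.0025, 0.005, 0.01])

    def test_shuffled_input_gives_identical_diagram(self):
        fits = self._fits([0, 1, 2.5, 5, 10], [6, 10, 17, 28, 49])
        d1 = L.build_diagram(fits)
        d2 = L.build_diagram(fits[::-1])
        assert np.array_equal(d1.cd_conc_m, d2.cd_conc_m)
        assert np.array_equal(d1.cmc_um, d2.cmc_um)

    def test_duplicate_level_rejected(self):
        fits = self._fits([0, 1, 1], [6, 10, 10])
        with pytest.raises(ValidationError):
            L.build_diagram(fits)

    def test_missing_zero_anchor_rejected(self):
        fits = self._fits([1, 2.5, 5], [10, 17, 28])
        with pytest.raises(ValidationError):
            L.build_diagram(fits)


class TestFit1to1:
    def test_recovers_reference_kc(self, clean_diagram_1to1):
        fit = L.fit_1to1(clean_diagram_1to1)
        assert fit.params.kc == pytest.approx(720.0, rel=1e-6)
        assert fit.params.cmc0 == 6.0
        assert fit.cmc0_source == "measured_at_zero"

    def test_recovers_fatty_acid_regime_kc(self):
        d = _diag(L.BindingParams.one_to_one(43.0, 7432.0), [0, 0.001, 0.0025, 0.005, 0.01])
        assert L.fit_1to1(d).params.kc == pytest.approx(7432.0, rel=1e-6)

    def test_flat_diagram_gives_zero_kc(self):
        d = L.MicellarDiagram(np.array([0, 0.001, 0.01]), np.array([6.0, 6.0, 6.0]))
        fit = L.fit_1to1(d)
        assert fit.params.kc == 0.0
        assert np.isnan(fit.r_squared)
        assert any("r_squared" in w for w in fit.warnings)

    def test_decreasing_diagram_clamped_with_warning(self):
        d = L.MicellarDiagram(np.array([0, 0.001, 0.01]), np.array([6.0, 5.0, 3.0]))
        fit = L.fit_1to1(d)
        assert fit.params.kc == 0.0
        assert any("clamped" in w for w in fit.warnings)

    def test_fitted_cmc0_mode(self, clean_diagram_1to1):
        fit = L.fit_1to1(clean_diagram_1to1, cmc0="fitted")
        assert fit.cmc0_source == "fitted"
        assert fit.params.cmc0 == pytest.approx(6.0, rel=1e-9)
        assert fit.params.kc == pytest.approx(720.0, rel=1e-6)


class TestFit1to2:
    def test_recovers_reference_constants(self, clean_diagram_1to2):
        fit = L.fit_1to2(clean_diagram_1to2)
        assert fit.params.k1 == pytest.approx(17.0, rel=1e-4)
        assert fit.params.k2 == pytest.approx(0.18, rel=1e-4)

    def test_nested_reduction_when_truth_is_linear(self, clean_diagram_1to1):
        fit2 = L.fit_1to2(clean_diagram_1to1)
        fit1 = L.fit_1to1(clean_diagram_1to1)
        assert fit2.params.k2 < 1e-8
        assert fit2.params.k1 == pytest.approx(fit1.params.kc, rel=1e-6)

    def test_three_levels_rejected(self):
        d = L.MicellarDiagram(np.array([0, 0.001, 0.01]), np.array([6.0, 7.0, 12.0]))
        with pytest.raises(ValidationError):
            L.fit_1to2(d)

    def test_sse_never_worse_than_1to1(self, resv4la_params):
        grid = [0, 0.002, 0.004, 0.006, 0.008, 0.01]
        for seed in range(10):
            d = _diag(resv4la_params, grid, seed=seed, cv=0.05)
            s1 = L.fit_1to1(d).sse
            s2 = L.fit_1to2(d).sse
            assert s2 <= s1 * (1 + 1e-9) + 1e-12


class TestSelectStoichiometry:
    def test_linear_truth_selects_1to1(self, clean_diagram_1to1):
        sel = L.select_stoichiometry(clean_diagram_1to1)
        assert sel.model is L.BindingModelKind.ONE_TO_ONE
        assert sel.rival is not None
        assert sel.rival.model is L.BindingModelKind.ONE_TO_TWO

    def test_curved_truth_selects_1to2(self):
        d = _diag(L.BindingParams.one_to_two(6.0, 17.0, 5.0), [0, 0.02, 0.04, 0.06, 0.08, 0.1])
        sel = L.select_stoichiometry(d)
        assert sel.model is L.BindingModelKind.ONE_TO_TWO
        assert sel.f_pvalue < 0.05

    def test_selection_consistency_as_noise_vanishes(self):
        """The generating model wins almost always at low CV, both kinds."""
        lin = L.BindingParams.one_to_one(6.0, 720.0)
        quad = L.BindingParams.one_to_two(6.0, 17.0, 5.0)
        grid_lin = [0, 0.002, 0.004, 0.006, 0.008, 0.01]
        grid_quad = [0, 0.02, 0.04, 0.06, 0.08, 0.1]
        for cv in (0.02, 0.01, 0.005):
            hits = 0
            for i in range(40):
                d = _diag(lin, grid_lin, seed=1000 * int(cv * 1000) + i, cv=cv)
                if L.select_stoichiometry(d).model is L.BindingModelKind.ONE_TO_ONE:
                    hits += 1
                d = _diag(quad, grid_quad, seed=7000 * int(cv * 1000) + i, cv=cv)
                if L.select_stoichiometry(d).model is L.BindingModelKind.ONE_TO_TWO:
                    hits += 1
            assert hits >= 72  # >= 90% of 80 decisions

    def test_bad_alpha_rejected(self, clean_diagram_1to1):
        with pytest.raises(ValidationError):
            L.select_stoichiometry(clean_diagram_1to1, alpha=0.9)


class TestBootstrap:
    def test_zero_residuals_collapse_to_point(self, clean_diagram_1to1):
        fit = L.fit_1to1(clean_diagram_1to1)
        b = L.bootstrap_binding(fit, clean_diagram_1to1, n_boot=200, seed=1)
        assert b.ci_lower["kc"] == b.ci_upper["kc"] == fit.params.kc
        assert any("zero residuals" in w for w in b.warnings)

    def test_deterministic_for_fixed_seed(self, resv4la_params):
        d = _diag(resv4la_params, [0, 0.002, 0.004, 0.006, 0.008, 0.01], seed=5, cv=0.05)
        fit = L.fit_1to1(d)
        b1 = L.bootstrap_binding(fit, d, n_boot=300, seed=11)
        b2 = L.bootstrap_binding(fit, d, n_boot=300, seed=11)
        assert b1.ci_lower == b2.ci_lower and b1.ci_upper == b2.ci_upper

    def test_interval_brackets_point_estimate(self, resv4la_params):
        d = _diag(resv4la_params, [0, 0.002, 0.004, 0.006, 0.008, 0.01], seed=6, cv=0.05)
        fit = L.fit_1to1(d)
        b = L.bootstrap_binding(fit, d, n_boot=300, seed=12)
        assert b.ci_lower["kc"] <= fit.params.kc <= b.ci_upper["kc"]

    def test_small_n_boot_rejected(self, clean_diagram_1to1):
        fit = L.fit_1to1(clean_diagram_1to1)
        with pytest.raises(ValidationError):
            L.bootstrap_binding(fit, clean_diagram_1to1, n_boot=50, seed=1)

    def test_interval_covers_truth_at_roughly_nominal_rate(self, resv4la_params):
        """Residual-bootstrap CIs on this 6-point design are mildly conservative."""
        grid = [0, 0.002, 0.004, 0.006, 0.008, 0.01]
        cover = 0
        n_outer = 60
        for i in range(n_outer):
            d = _diag(resv4la_params, grid, seed=40000 + i, cv=0.05)
            fit = L.fit_1to1(d)
            b = L.bootstrap_binding(fit, d, n_boot=300, seed=i)
            if b.ci_lower["kc"] <= 720.0 <= b.ci_upper["kc"]:
                cover += 1
        assert cover / n_outer >= 0.90
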