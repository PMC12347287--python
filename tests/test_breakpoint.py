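"""CMC estimation by two-line intersection."""

import numpy as np
import pytest

import lipocd as L
from lipocd.errors import (
    FlatSignalError,
    NoMicellizationError,
    ValidationError,
)


def _curve(conc, fluo, cd=0.0, **kw):
    conc = np.asarray(conc, float)
    return L.TitrationCurve(
        conc_um=conc,
        rel_fluorescence_pct=np.asarray(fluo, float),
        replicate=np.zeros(conc.size, int),
        cd_conc_m=cd,
        **kw,
    )


def _clean_spec(binding, cd=0.0, seed=0, **kw):
    return L.SyntheticTitrationSpec(
        binding=binding, cd_conc_m=cd, seed=seed, noise_sd=0.0, **kw
    )


class TestEstimateCmc:
    def test_noise_free_exact_recovery(self, resv4la_params):
        curve = L.make_titration(_clean_spec(resv4la_params))
        fit = L.estimate_cmc(curve)
        assert fit.cmc_um == pytest.approx(6.0, rel=1e-9)
        assert fit.post_slope > fit.pre_slope

    def test_recovery_across_random_truths(self):
        """20 randomized generator settings, exact recovery for each."""
        rng = np.random.default_rng(20250801)
        for _ in range(20):
            cmc0 = float(10 ** rng.uniform(-2.5, 1.8))
            kc = float(rng.uniform(0.0, 5000.0))
            post = float(rng.uniform(3.0, 20.0))
            base = float(rng.uniform(0.0, 0.5))
            truth = L.BindingParams.one_to_one(cmc0, kc)
            cd = float(rng.uniform(0.0, 0.005))
            spec = _clean_spec(
                truth, cd=cd, seed=int(rng.integers(2**31)),
                post_slope=post, baseline_slope=base,
            )
            curve = L.make_titration(spec)
            expected = L.eval_cmc_1to1(truth, cd)
            fit = L.estimate_cmc(curve)
            assert abs(fit.cmc_um - expected) / expected < 1e-6

    def test_nanomolar_regime_uses_log_axis(self, resv4dha_params):
        curve = L.make_titration(_clean_spec(resv4dha_params))
        fit = L.estimate_cmc(curve)
        assert fit.log_axis
        assert fit.cmc_um == pytest.approx(0.001, rel=1e-9)

    def test_flat_signal_rejected(self):
        c = _curve(np.arange(1.0, 11.0), np.full(10, 5.0))
        with pytest.raises(FlatSignalError):
            L.estimate_cmc(c)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            _curve([1, 2, 3, 4, 5], [1, 1, 2, 3, 4])

    def test_too_few_levels_rejected(self):
        # 6 points but only 3 distinct concentrations
        c = _curve([1, 1, 2, 2, 3, 3], [1, 1, 1, 2, 5, 5.5])
        with pytest.raises(ValidationError):
            L.estimate_cmc(c)

    def test_no_micellization_on_single_line(self):
        x = np.arange(1.0, 13.0)
        c = _curve(x, 2.0 * x + 1.0)
        with pytest.raises(NoMicellizationError):
            L.estimate_cmc(c)

    def test_scale_equivariance(self, resv4la_params):
        curve = L.make_titration(_clean_spec(resv4la_params))
        fit = L.estimate_cmc(curve)
        scaled = _curve(curve.conc_um * 7.5, curve.rel_fluorescence_pct)
        fit2 = L.estimate_cmc(scaled)
        assert fit2.cmc_um == pytest.approx(7.5 * fit.cmc_um, rel=1e-9)

    def test_signal_offset_invariance(self, resv4la_params):
        spec = L.SyntheticTitrationSpec(
            binding=resv4la_params, seed=3, noise_sd=1.0
        )
        curve = L.make_titration(spec)
        fit = L.estimate_cmc(curve)
        shifted = _curve(curve.conc_um, curve.rel_fluorescence_pct + 40.0)
        # replicate ids differ but do not enter the fit
        fit2 = L.estimate_cmc(shifted)
        assert fit2.cmc_um == pytest.approx(fit.cmc_um, rel=1e-12)

    def test_duplicating_replicates_leaves_fit_unchanged(self, resv4la_params):
        spec = L.SyntheticTitrationSpec(binding=resv4la_params, seed=4, noise_sd=1.5)
        c1 = L.make_titration(spec)
        doubled = L.TitrationCurve(
            conc_um=np.concatenate([c1.conc_um, c1.conc_um]),
            rel_fluorescence_pct=np.concatenate(
                [c1.rel_fluorescence_pct, c1.rel_fluorescence_pct]
            ),
            replicate=np.concatenate([c1.replicate, c1.replicate + 10]),
            cd_conc_m=c1.cd_conc_m,
        )
        f1, f2 = L.estimate_cmc(c1), L.estimate_cmc(doubled)
        assert f2.cmc_um == pytest.approx(f1.cmc_um, rel=1e-12)
        assert f2.pre_slope == pytest.approx(f1.pre_slope, abs=1e-12)
        assert f2.post_slope == pytest.approx(f1.post_slope, rel=1e-12)

    def test_warns_when_intersection_outside_split_gap(self):
        # pre segment flat at 5; post line 8x - 10 intersects at x = 1.875,
        # well below the last pre-micellar point at x = 3
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([5.0, 5.0, 5.0, 70.0, 78.0, 86.0])
        fit = L.estimate_cmc(_curve(x, y))
        assert fit.warnings

    def test_fixed_baseline_option(self, resv4la_params):
        curve = L.make_titration(_clean_spec(resv4la_params))
        fit = L.estimate_cmc(curve, L.BreakpointOptions(fix_baseline_slope=True))
        assert fit.pre_slope == 0.0
        assert fit.cmc_um == pytest.approx(6.0, rel=1e-9)


class TestBatch:
    def test_empty_batch(self):
        assert L.estimate_cmc_batch([]) == []

    def test_round_trip_across_cd_levels(self, resv4la_params):
        cds = [0.0, 0.001, 0.0025, 0.005, 0.01]
        curves = [
            L.make_titration(_clean_spec(resv4la_params, cd=cd, seed=i))
            for i, cd in enumerate(cds)
        ]
        outcomes = L.estimate_cmc_batch(curves)
        assert [o.cd_conc_m for o in outcomes] == cds
        for o in outcomes:
            expected = L.eval_cmc_1to1(resv4la_params, o.cd_conc_m)
            assert abs(o.fit.cmc_um - expected) / expected < 1e-6

    def test_failures_are_isolated(self, resv4la_params):
        curves = [
            L.make_titration(_clean_spec(resv4la_params, cd=cd, seed=i))
            for i, cd in enumerate([0.0, 0.001, 0.0025, 0.005])
        ]
        flat = _curve(np.arange(1.0, 11.0), np.full(10, 5.0), cd=0.01, guest="synthetic")
        outcomes = L.estimate_cmc_batch(curves + [flat])
        assert sum(o.ok for o in outcomes) == 4
        assert outcomes[-1].error is not None

    def test_mixed_conditions_rejected(self, resv4la_params):
        a = L.make_titration(_clean_spec(resv4la_params, seed=0))
        spec_b = L.SyntheticTitrationSpec(
            binding=resv4la_params,
            cd_conc_m=0.001,
            seed=1,
            noise_sd=0.0,
            condition=L.ConditionSpec(ph=2.0),
        )
        b = L.make_titration(spec_b)
        with pytest.raises(ValidationError):
            L.estimate_cmc_batch([a, b])

    def test_duplicate_cd_rejected(self, resv4la_params):
        a = L.make_titration(_clean_spec(resv4la_params, seed=0))
        b = L.make_titration(_clean_spec(resv4la_params, seed=1))
        with pytest.raises(ValidationError):
            L.estimate_cmc_batch([a, b])
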