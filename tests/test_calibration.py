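"""Scaling optimization, unit restoration, and metabolite correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import idifpet as ip
from idifpet.calibration import POPULATION_METABOLITE_MODEL, MetaboliteModel
from idifpet.errors import NonIdentifiableError, StateError


class TestOptimizeScaling:
    def test_exact_mixture_system(self):
        """Weights built as (alpha/2, (1-alpha)/4) make the weight-sum system
        exact with scales (2, 4)."""
        alphas = np.array([0.2, 0.5, 0.8])
        W = np.column_stack([alphas / 2.0, (1 - alphas) / 4.0])
        s = ip.optimize_scaling(W)
        assert s.s_aif == pytest.approx(2.0, rel=1e-10)
        assert s.s_tissue == pytest.approx(4.0, rel=1e-10)
        assert s.objective_value == pytest.approx(0.0, abs=1e-20)

    def test_rank_one_weights_not_identifiable(self):
        W = np.column_stack([np.array([0.5, 0.25, 0.1]), np.zeros(3)])
        with pytest.raises(NonIdentifiableError):
            ip.optimize_scaling(W)

    def test_closed_form_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0.1, 1.0, size=(12, 2))
        s = ip.optimize_scaling(W, clip_range=(1e-6, 1e6))
        grid = np.arange(0.1, 10.0, 1e-3)
        # profile the quadratic: for each s_aif on the grid the optimal
        # s_tissue is closed-form, so scan one axis only
        w1, w2 = W[:, 0], W[:, 1]
        best = (np.inf, None, None)
        for sa in grid:
            st_opt = float(w2 @ (1 - sa * w1)) / float(w2 @ w2)
            obj = float(np.sum((sa * w1 + st_opt * w2 - 1) ** 2))
            if obj < best[0]:
                best = (obj, sa, st_opt)
        assert s.s_aif == pytest.approx(best[1], abs=1e-3)
        assert s.s_tissue == pytest.approx(best[2], abs=1e-3)
        assert s.objective_value == pytest.approx(best[0], abs=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_closed_form_equals_numeric_path(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.05, 1.0, size=(8, 2))
        closed = ip.optimize_scaling(W, clip_range=(1e-9, 1e9))
        numeric = ip.optimize_scaling(W, method="numeric", clip_range=(1e-9, 1e9))
        assert numeric.s_aif == pytest.approx(closed.s_aif, rel=1e-6)
        assert numeric.s_tissue == pytest.approx(closed.s_tissue, rel=1e-6)

    def test_conventions_are_reciprocal(self):
        alphas = np.array([0.1, 0.4, 0.9])
        W = np.column_stack([alphas / 2.0, (1 - alphas) / 4.0])
        printed = ip.optimize_scaling(W, convention="as_printed")
        recip = ip.optimize_scaling(W, convention="reciprocal")
        assert recip.s_aif == pytest.approx(1.0 / printed.s_aif, rel=1e-10)
        assert recip.aif_multiplier == pytest.approx(printed.aif_multiplier,
                                                     rel=1e-10)

    def test_implausible_scale_flagged(self):
        alphas = np.array([0.2, 0.5, 0.8])
        W = np.column_stack([alphas * 1e3, (1 - alphas) * 1e3])
        with pytest.warns(UserWarning, match="implausible"):
            ip.optimize_scaling(W)
        with pytest.raises(NonIdentifiableError):
            ip.optimize_scaling(W, strict=True)


class TestScaleIdif:
    def test_unit_scale_is_identity(self, noisy_extraction):
        fr = noisy_extraction.factorization
        s = ip.ScalingFactors(1.0, 1.0, 0.0, convention="reciprocal")
        out = ip.scale_idif(fr, s)
        assert out.state == "whole_blood"
        assert np.allclose(out.values, fr.normalized_aif)

    def test_doubling_scale_doubles_values(self, noisy_extraction):
        fr = noisy_extraction.factorization
        one = ip.scale_idif(fr, ip.ScalingFactors(3.0, 1.0, 0.0, "reciprocal"))
        two = ip.scale_idif(fr, ip.ScalingFactors(6.0, 1.0, 0.0, "reciprocal"))
        assert np.allclose(two.values, 2 * one.values)

    def test_printed_convention_inverts(self, noisy_extraction):
        fr = noisy_extraction.factorization
        printed = ip.scale_idif(fr, ip.ScalingFactors(0.5, 1.0, 0.0, "as_printed"))
        recip = ip.scale_idif(fr, ip.ScalingFactors(2.0, 1.0, 0.0, "reciprocal"))
        assert np.allclose(printed.values, recip.values)

    def test_end_to_end_recovery(self, recovery_runs):
        """Scaled IDIF tracks the true frame-averaged whole-blood curve,
        pooled over a small subject cohort; the error norm weights frames by
        duration (continuous-time L2)."""
        from idifpet.kinetics import feng_aif, fine_grid, frame_average

        rels = []
        for _, _, truth, ext in recovery_runs:
            grid = fine_grid(60.0)
            tf = frame_average(grid, feng_aif(truth.feng, grid), truth.schedule)
            d = truth.schedule.durations_s
            err = ext.whole_blood.values - tf
            rels.append(
                np.sqrt(np.average(err**2, weights=d)
                        / np.average(tf**2, weights=d))
            )
        assert np.mean(rels) < 0.10


class TestCompositeFractionFit:
    @staticmethod
    def _table(a, b, times_min=(5.0, 15.0, 30.0, 60.0), wb_level=10.0):
        mm = MetaboliteModel(a, b) if a > 0 else MetaboliteModel(0.0, b)
        t = np.asarray(times_min)
        comp = np.asarray(mm.multiplier(t))
        share = np.sqrt(comp)
        return ip.BloodSampleTable(t * 60.0, np.full_like(t, wb_level),
                                   wb_level * share, share)

    def test_exact_recovery_of_population_constants(self):
        tables = [self._table(0.29, 0.03) for _ in range(4)]
        mm = ip.fit_composite_fraction(tables)
        assert mm.a == pytest.approx(0.29, abs=1e-6)
        assert mm.b == pytest.approx(0.03, abs=1e-6)
        assert mm.source == "fitted"

    def test_unit_fractions_give_zero_amplitude(self):
        # b is unidentified when a = 0, so the amplitude is only pinned to
        # the optimizer's tolerance along that flat direction
        tables = [self._table(0.0, 0.03) for _ in range(3)]
        mm = ip.fit_composite_fraction(tables)
        assert mm.a == pytest.approx(0.0, abs=1e-3)

    def test_recovery_under_subject_noise(self):
        """Subject-level zero-mean noise leaves the fitted amplitude within
        +-0.05 of truth across seeded replicates."""
        rng = np.random.default_rng(11)
        deviations = []
        for _ in range(100):
            tables = []
            for _ in range(5):
                t = np.array([5.0, 15.0, 30.0, 60.0])
                comp = POPULATION_METABOLITE_MODEL.multiplier(t)
                comp = np.clip(comp + rng.normal(0, 0.01, size=4), 0.05, 1.0)
                share = np.sqrt(comp)
                tables.append(
                    ip.BloodSampleTable(t * 60.0, np.full(4, 10.0),
                                        10.0 * share, share)
                )
            mm = ip.fit_composite_fraction(tables)
            deviations.append(abs(mm.a - 0.29))
        assert max(deviations) < 0.05

    def test_subject_missing_time_point_dropped(self):
        good = self._table(0.29, 0.03)
        bad = ip.BloodSampleTable(
            np.array([300.0, 900.0]), np.full(2, 10.0), np.full(2, 9.0),
            np.full(2, 0.9),
        )
        with pytest.warns(UserWarning, match="dropped"):
            mm = ip.fit_composite_fraction([good, bad])
        assert mm.a == pytest.approx(0.29, abs=1e-6)


class TestMetaboliteCorrection:
    def test_multiplier_identity_at_zero(self):
        mm = POPULATION_METABOLITE_MODEL
        assert mm.multiplier(0.0) == 1.0

    def test_longtime_deficit_equals_amplitude(self):
        mm = POPULATION_METABOLITE_MODEL
        assert 1.0 - mm.multiplier(1e9) == pytest.approx(0.29, abs=1e-12)

    def test_multiplier_monotone_and_bounded(self):
        mm = MetaboliteModel(0.4, 0.1)
        t = np.linspace(0, 100, 2000)
        vals = mm.multiplier(t)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals >= 1 - mm.a - 1e-12) & (vals <= 1.0))

    def test_state_machine(self, noisy_extraction):
        wb = noisy_extraction.whole_blood
        plasma = ip.apply_metabolite_correction(wb)
        assert plasma.state == "metab_corrected_plasma"
        expected = wb.values * POPULATION_METABOLITE_MODEL.multiplier(wb.times_min)
        assert np.allclose(plasma.values, expected)
        with pytest.raises(StateError):
            ip.apply_metabolite_correction(plasma)
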