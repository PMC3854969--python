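"""FRAP analysis: ratio statistic, baseline subtraction, one-phase fits,
exchange classification, compartment quantification and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ciliagate import (
    FRAPCurve,
    INTRACILIARY_SCHEDULE,
    IntensityTrace,
    RecoveryFit,
    SimConfig,
    classify_exchange,
    compare_groups,
    compartment_length,
    compartment_ratio,
    fit_recovery,
    one_phase_association,
    ratio_curve,
    subtract_baseline,
)
from ciliagate.frap import reciprocal_decline, simulate_compartment_frap


def make_trace(times, bleached, reference, background=0.0):
    raw = np.column_stack([bleached, reference])
    return IntensityTrace(
        times=np.asarray(times, dtype=float),
        roi_names=["bleached", "reference"],
        raw=raw,
        background=background,
    )


class TestRatioCurve:
    def test_identical_series_give_unit_curve(self):
        t = [-10, -5, 1, 15, 30]
        vals = [50.0, 52.0, 20.0, 30.0, 40.0]
        trace = make_trace(t, vals, vals)
        curve = ratio_curve(trace, "bleached", "reference", 0.0)
        assert np.allclose(curve.values, 1.0)

    def test_hand_computed_three_point_example(self):
        # BG = 10; pre-bleach (60, 60) -> R_pre = 1; post (35, 60) -> 0.5;
        # post (47.5, 60) -> 0.75
        trace = make_trace(
            [-10, -5, 1, 15],
            [60.0, 60.0, 35.0, 47.5],
            [60.0, 60.0, 60.0, 60.0],
            background=10.0,
        )
        curve = ratio_curve(trace, "bleached", "reference", 0.0)
        assert np.allclose(curve.values, [1.0, 1.0, 0.5, 0.75])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.05, max_value=20.0))
    def test_uniform_attenuation_invariance(self, c):
        """Acquisition photobleaching scales both ROIs equally and must
        leave the ratio curve unchanged (the statistic's design rationale)."""
        t = np.array([-10.0, -5.0, 1.0, 15.0, 30.0, 60.0])
        bleached = np.array([60.0, 58.0, 25.0, 31.0, 40.0, 52.0])
        reference = np.array([55.0, 56.0, 54.0, 50.0, 49.0, 47.0])
        base = ratio_curve(make_trace(t, bleached, reference), "bleached",
                           "reference", 0.0)
        scaled = ratio_curve(
            make_trace(t, c * bleached, c * reference), "bleached",
            "reference", 0.0,
        )
        assert np.allclose(base.values, scaled.values, rtol=1e-12)

    def test_nonpositive_reference_names_the_timepoint(self):
        trace = make_trace(
            [-10, -5, 1, 15], [60, 60, 30, 40], [60, 60, 5.0, 60],
            background=10.0,
        )
        with pytest.raises(ValueError, match="t = 1"):
            ratio_curve(trace, "bleached", "reference", 0.0)

    def test_missing_roi_raises(self):
        trace = make_trace([-10, -5, 1, 15], [1, 1, 1, 1], [1, 1, 1, 1])
        with pytest.raises(KeyError):
            ratio_curve(trace, "nope", "reference", 0.0)


class TestSubtractBaseline:
    def _curve(self, post_vals, pre=(1.0, 1.0)):
        t = np.array([-10.0, -5.0] + list(np.linspace(1, 300, len(post_vals))))
        v = np.concatenate([pre, post_vals])
        return FRAPCurve(times=t, values=v, n_prebleach=2)

    def test_flat_baseline_is_identity(self):
        curve = self._curve([0.4, 0.5, 0.6, 0.7])
        baseline = self._curve([0.05, 0.05, 0.05, 0.05])
        out = subtract_baseline(curve, baseline)
        assert np.allclose(out.values, curve.values)

    def test_baseline_equal_to_curve_pins_at_floor(self):
        curve = self._curve([0.4, 0.5, 0.6, 0.7])
        out = subtract_baseline(curve, curve)
        assert np.allclose(out.post_values, 0.4)

    def test_residual_recovery_removed_pointwise(self):
        r = np.array([0.0, 0.02, 0.04, 0.05])
        curve = self._curve([0.4, 0.55, 0.68, 0.8])
        baseline = self._curve(0.05 + r)
        out = subtract_baseline(curve, baseline)
        assert np.allclose(out.post_values, curve.post_values - r)

    def test_disjoint_spans_rejected(self):
        curve = self._curve([0.4, 0.5, 0.6, 0.7])
        t = np.array([-10.0, -5.0, 500.0, 600.0, 700.0, 800.0])
        baseline = FRAPCurve(
            times=t, values=np.array([1.0, 1.0, 0.1, 0.1, 0.1, 0.1]),
            n_prebleach=2,
        )
        with pytest.raises(ValueError, match="span"):
            subtract_baseline(curve, baseline)


class TestFitRecovery:
    def _exact_curve(self, f0, plateau, t_half, schedule=INTRACILIARY_SCHEDULE):
        t = schedule.times
        k = np.log(2) / t_half
        vals = np.where(t < 0, 1.0, one_phase_association(t, f0, plateau, k))
        return FRAPCurve(times=t, values=vals, n_prebleach=2)

    def test_exact_curve_recovered_to_machine_precision(self):
        curve = self._exact_curve(0.4, 1.0, 124.0)
        fit = fit_recovery(curve)
        assert abs(fit.t_half - 124.0) / 124.0 < 1e-6
        assert fit.r_squared > 1.0 - 1e-12
        assert fit.passes_gate

    def test_constant_curve_fails_gate(self):
        t = INTRACILIARY_SCHEDULE.times
        vals = np.where(t < 0, 1.0, 0.4)
        fit = fit_recovery(FRAPCurve(times=t, values=vals, n_prebleach=2))
        assert fit.plateau == pytest.approx(0.4, abs=1e-6)
        assert fit.f0 == pytest.approx(0.4, abs=1e-6)
        assert fit.r_squared <= 0.0
        assert not fit.passes_gate

    def test_too_few_post_points_rejected(self):
        t = np.array([-10.0, -5.0, 1.0, 15.0, 30.0])
        vals = np.array([1.0, 1.0, 0.4, 0.5, 0.6])
        with pytest.raises(ValueError, match="post-bleach"):
            fit_recovery(FRAPCurve(times=t, values=vals, n_prebleach=2))

    def test_fit_idempotence(self):
        """Fitting the fit's own predictions returns identical parameters."""
        rng = np.random.default_rng(7)
        t = INTRACILIARY_SCHEDULE.times
        vals = np.where(
            t < 0, 1.0, one_phase_association(t, 0.35, 0.95, np.log(2) / 80.0)
        ) + np.where(t < 0, 0.0, rng.normal(0, 0.03, t.size))
        vals /= vals[:2].mean()
        first = fit_recovery(FRAPCurve(times=t, values=vals, n_prebleach=2))
        pred = np.where(
            t < 0, 1.0, one_phase_association(t, first.f0, first.plateau, first.k)
        )
        second = fit_recovery(FRAPCurve(times=t, values=pred, n_prebleach=2))
        assert abs(second.k - first.k) < 1e-9
        assert abs(second.plateau - first.plateau) < 1e-9
        assert abs(second.f0 - first.f0) < 1e-9

    @pytest.mark.parametrize("t_half", [20.0, 120.0])
    def test_noisy_recovery_within_fifteen_percent(self, t_half):
        k = np.log(2) / t_half
        t = INTRACILIARY_SCHEDULE.times
        estimates = []
        for s in range(50):
            rng = np.random.default_rng(1300 + s)
            vals = np.where(t < 0, 1.0, one_phase_association(t, 0.4, 1.0, k))
            vals = vals + rng.normal(0, 0.05, t.size)
            vals = vals / vals[:2].mean()
            estimates.append(
                fit_recovery(FRAPCurve(times=t, values=vals, n_prebleach=2)).t_half
            )
        assert abs(np.median(estimates) - t_half) / t_half < 0.15

    def test_gate_is_exactly_r2_threshold(self):
        just_above = RecoveryFit(0.01, np.log(2) / 0.01, 0.4, 1.0,
                                 0.75 + 1e-12, 10, True)
        at = RecoveryFit(0.01, np.log(2) / 0.01, 0.4, 1.0, 0.75, 10, True)
        assert just_above.passes_gate
        assert not at.passes_gate


class TestClassifyExchange:
    def _fit(self, t_half, plateau, f0=0.05):
        return RecoveryFit(np.log(2) / t_half, t_half, f0, plateau, 0.95, 10, True)

    def test_missing_null_control_is_indeterminate(self):
        out = classify_exchange({"pcm_only": self._fit(20, 0.95)})
        assert out.status == "indeterminate"
        assert out.warning is not None

    def test_recovering_null_control_flags_external_source(self):
        fits = {
            "pcm_only": self._fit(20, 0.95),
            "cilium_only": self._fit(20, 0.95),
            "both": self._fit(100, 0.98, f0=0.05),  # recovers to pre-bleach
        }
        out = classify_exchange(fits)
        assert out.status == "indeterminate"
        assert out.recovery_source == "external"

    def test_fast_complete_recovery_is_exchanging(self):
        fits = {
            "pcm_only": self._fit(20, 0.95),
            "cilium_only": self._fit(25, 0.9),
            "both": self._fit(100, 0.08, f0=0.05),
        }
        out = classify_exchange(fits, reciprocal_decline=0.3)
        assert out.status == "exchanging"
        assert out.recovery_source == "reciprocal_pool"

    def test_slow_recovery_is_restricted(self):
        fits = {
            "pcm_only": self._fit(300, 0.9),
            "cilium_only": self._fit(400, 0.9),
            "both": self._fit(100, 0.08, f0=0.05),
        }
        assert classify_exchange(fits).status == "restricted"

    def test_end_to_end_compromised_barrier_classified_exchanging(self):
        cfg = SimConfig(p_tz=1.0, tz_occupancy=True, n_molecules=2000, seed=11)
        fits = {}
        for i, design in enumerate(("pcm_only", "cilium_only", "both")):
            curve, _ = simulate_compartment_frap(cfg, design, seed=cfg.seed + i)
            fits[design] = fit_recovery(curve)
        _, tr = simulate_compartment_frap(cfg, "cilium_only", seed=cfg.seed + 1)
        decline = reciprocal_decline(tr, "pcm", 0.0)
        out = classify_exchange(fits, decline)
        assert out.status == "exchanging"
        assert out.recovery_source == "reciprocal_pool"

    def test_end_to_end_intact_barrier_classified_restricted(self):
        cfg = SimConfig(p_tz=0.01, n_molecules=2000, seed=12)
        fits = {}
        for i, design in enumerate(("pcm_only", "cilium_only", "both")):
            curve, _ = simulate_compartment_frap(cfg, design, seed=cfg.seed + i)
            fits[design] = fit_recovery(curve)
        assert classify_exchange(fits).status == "restricted"


class TestDiffusionMonotonicity:
    def test_median_thalf_strictly_decreasing_in_diffusivity(self):
        """Faster lateral diffusion shortens the fitted recovery half-time
        of a 40%-of-MS bleach (median over 20 replicates per D)."""
        medians = []
        for d_idx, D in enumerate((0.05, 0.1, 0.2)):
            est = []
            for i in range(20):
                cfg = SimConfig(
                    D=D, p_tz=0.0, n_molecules=800,
                    seed=70000 + 100 * d_idx + i,
                )
                curve, _ = simulate_compartment_frap(
                    cfg, "partial_ms", seed=cfg.seed
                )
                est.append(fit_recovery(curve).t_half)
            medians.append(float(np.median(est)))
        assert medians[0] > medians[1] > medians[2]


class TestCompartmentQuant:
    def test_pcm_at_background_gives_fraction_one(self):
        assert compartment_ratio(90.0, 10.0, 10.0).ciliary_fraction == 1.0

    def test_equal_signals_give_half(self):
        assert compartment_ratio(60.0, 60.0, 10.0).ciliary_fraction == 0.5

    def test_hand_example(self):
        q = compartment_ratio(90.0, 40.0, 10.0)
        assert q.ciliary_fraction == pytest.approx(80.0 / 110.0)

    def test_both_below_background_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compartment_ratio(5.0, 5.0, 10.0)

    @pytest.mark.parametrize("threshold", [0.2, 0.5, 0.8])
    def test_boxcar_profile_measures_exact_support(self, threshold):
        profile = np.zeros(100)
        profile[10:40] = 50.0
        assert compartment_length(profile, 0.1, threshold) == pytest.approx(3.0)

    def test_longest_run_wins(self):
        profile = np.zeros(100)
        profile[5:25] = 50.0  # 20 px
        profile[40:45] = 50.0  # 5 px
        assert compartment_length(profile, 0.1) == pytest.approx(2.0)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            compartment_length(np.full(50, 3.0), 0.1, background=3.0)

    def test_simulated_steady_state_length_within_one_pixel(self):
        """A snapshot of the intact-barrier steady state measures the MS
        compartment at its configured 3 µm length."""
        cfg = SimConfig(n_molecules=4000, seed=33)
        rng = np.random.default_rng(cfg.seed)
        from ciliagate.simulate import _initial_positions

        x = _initial_positions(cfg, rng)
        x = x[x >= cfg.tz_end]  # the ciliary compartment signal
        px = 0.1
        edges = np.arange(0.0, cfg.total_length + px, px)
        profile, _ = np.histogram(x, bins=edges)
        length = compartment_length(profile.astype(float), px)
        assert abs(length - cfg.L_ms) <= px + 1e-9


class TestCompareGroups:
    def test_identical_groups_adjusted_p_is_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        _, _, pairwise = compare_groups(g)
        assert pairwise[("a", "b")] == 1.0

    def test_pairwise_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        f_stat, _, _ = compare_groups({"a": a, "b": b})
        t_stat, _ = stats.ttest_ind(a, b)
        assert f_stat == pytest.approx(t_stat**2, rel=1e-10)

    def test_power_to_detect_shifted_mean(self):
        """Three groups, one shifted by 3 sd (n = 20): the shifted-vs-others
        adjusted p-values are < 0.05 in >= 95% of replicates."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(40000 + s)
            groups = {
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 1, 20),
                "c": rng.normal(3, 1, 20),
            }
            _, _, pw = compare_groups(groups)
            if pw[("a", "c")] < 0.05 and pw[("b", "c")] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0]})
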