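import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmargin import (
    BeamIntervals,
    FractionExcluded,
    ImagingSeries,
    ModelerTrace,
    PredictorTrace,
    TrackingBundle,
    assign_deformation,
    assign_segmentation,
    compute_patient_budget,
    correlation_error,
    expanded_uncertainty,
    motion_range,
    prediction_error,
    synthetic_e2e_records,
    targeting_budget,
)


def make_bundle(t_mod, pos_mod, t_img=None, pos_img=None, t_pred=None, pos_pred=None,
                horizon_ms=115.0):
    t_mod = np.asarray(t_mod, dtype=float)
    if t_img is None:
        t_img, pos_img = t_mod[:2], np.asarray(pos_mod)[:2]
    if t_pred is None:
        t_pred, pos_pred = t_mod, pos_mod
    return TrackingBundle(
        imaging=ImagingSeries(t=t_img, pos=pos_img),
        modeler=ModelerTrace(t=t_mod, pos=pos_mod),
        predictor=PredictorTrace(t=t_pred, pos=pos_pred, horizon_ms=horizon_ms),
        beam=BeamIntervals([[0.0, float(t_mod[-1]) + 1.0]]),
    )


class TestCorrelationError:
    def test_modeler_equal_to_imaging_gives_zero(self):
        t = np.arange(0.0, 100.0, 1.0)
        pos = np.column_stack([np.sin(t), np.cos(t), t * 0.01])
        bundle = make_bundle(t, pos, t_img=t[5:90:10], pos_img=pos[5:90:10])
        series = correlation_error(bundle)
        np.testing.assert_allclose(series.errors, 0.0, atol=1e-12)
        assert len(series) == len(bundle.imaging)

    def test_constant_modeler_offset_gives_minus_offset(self):
        t = np.arange(0.0, 50.0, 0.5)
        truth = np.column_stack([np.sin(t), np.zeros_like(t), np.zeros_like(t)])
        bundle = make_bundle(t, truth + [2.0, 0.0, 0.0],
                             t_img=t[10:80:10], pos_img=truth[10:80:10])
        series = correlation_error(bundle)
        np.testing.assert_allclose(series.errors[:, 0], -2.0, atol=1e-12)

    def test_out_of_span_imaging_samples_dropped_with_warning(self):
        t = np.arange(10.0, 50.0, 0.5)
        pos = np.zeros((t.size, 3))
        with pytest.warns(UserWarning, match="outside the modeler"):
            series = correlation_error(
                make_bundle(t, pos, t_img=[5.0, 20.0, 30.0], pos_img=np.zeros((3, 3)))
            )
        assert len(series) == 2

    def test_fewer_than_two_usable_samples_excludes_fraction(self):
        t = np.arange(0.0, 10.0, 0.5)
        with pytest.warns(UserWarning):
            with pytest.raises(FractionExcluded):
                correlation_error(
                    make_bundle(t, np.zeros((t.size, 3)),
                                t_img=[5.0, 20.0], pos_img=np.zeros((2, 3)))
                )

    def test_sd_invariant_to_common_translation(self, rng):
        t = np.arange(0.0, 200.0, 0.25)
        mod = rng.normal(0, 1, (t.size, 3))
        img_t = t[40:760:40]
        img = rng.normal(0, 1, (img_t.size, 3))
        base = correlation_error(make_bundle(t, mod, t_img=img_t, pos_img=img))
        shifted = correlation_error(
            make_bundle(t, mod + 7.5, t_img=img_t, pos_img=img + 7.5)
        )
        np.testing.assert_allclose(
            base.errors.std(axis=0, ddof=1), shifted.errors.std(axis=0, ddof=1),
            atol=1e-9,
        )


class TestPredictionError:
    def test_exact_horizon_shift_gives_zero_error(self):
        t = np.arange(0.0, 60.0, 1 / 26)
        pos = np.column_stack([5 * np.sin(2 * np.pi * t / 4), np.cos(t), t * 0.02])
        ahead = np.column_stack(
            [np.interp(t + 0.115, t, pos[:, k]) for k in range(3)]
        )
        series = prediction_error(make_bundle(t, pos, t_pred=t, pos_pred=ahead))
        np.testing.assert_allclose(series.errors, 0.0, atol=1e-12)

    def test_linear_ramp_with_lagging_predictor_gives_v_times_horizon(self):
        v = 10.0  # mm/s on S-I
        t = np.arange(0.0, 30.0, 1 / 26)
        pos = np.column_stack([v * t, np.zeros_like(t), np.zeros_like(t)])
        series = prediction_error(make_bundle(t, pos, t_pred=t, pos_pred=pos))
        np.testing.assert_allclose(series.errors[:, 0], v * 0.115, atol=1e-9)
        assert series.t[-1] <= t[-1] - 0.115 + 1e-9  # boundary samples dropped

    def test_zero_order_hold_matches_brute_force_interpolation(self):
        A, T = 5.0, 4.0
        t = np.arange(0.0, 40.0, 1 / 26)
        si = A * np.sin(2 * np.pi * t / T)
        pos = np.column_stack([si, np.zeros_like(t), np.zeros_like(t)])
        series = prediction_error(make_bundle(t, pos, t_pred=t, pos_pred=pos))
        # oracle: explicit per-sample loop interpolating the sampled sinusoid
        expected = []
        for tj in series.t:
            ta = tj + 0.115
            i = int(np.searchsorted(t, ta)) - 1
            w = (ta - t[i]) / (t[i + 1] - t[i])
            expected.append((1 - w) * si[i] + w * si[i + 1] - si[int(round(tj * 26))])
        np.testing.assert_allclose(series.errors[:, 0], expected, atol=1e-9)

    def test_horizon_beyond_span_excludes_fraction(self):
        t = np.array([0.0, 0.05])
        with pytest.raises(FractionExcluded):
            prediction_error(
                make_bundle(t, np.zeros((2, 3)), t_pred=[10.0], pos_pred=np.zeros((1, 3)),
                            horizon_ms=115.0)
            )


class TestExpandedUncertainty:
    def test_all_zero_samples(self):
        s = expanded_uncertainty([0.0, 0.0, 0.0])
        assert (s.mu_abs, s.sd, s.U) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        s = expanded_uncertainty([-1.0, 0.0, 1.0])
        assert s.mu_abs == 0.0
        assert s.sd == pytest.approx(1.0)
        assert s.U == pytest.approx(2.0)

    def test_u_identity_holds_exactly(self, rng):
        x = rng.normal(0.3, 1.2, 500)
        s = expanded_uncertainty(x)
        assert s.U == s.mu_abs + 2 * s.sd

    def test_mean_abs_variant(self):
        s = expanded_uncertainty([-1.0, 1.0], absolute="mean_abs")
        assert s.mu_abs == pytest.approx(1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            expanded_uncertainty([1.0])


class TestAssignedBudgets:
    def test_segmentation_default_constants(self):
        sigma, u = assign_segmentation()
        assert sigma == pytest.approx(0.54)
        assert u == pytest.approx(1.46)

    @pytest.mark.parametrize(
        "mean, sd, expected", [((0.0), 0.0, (0.0, 0.0)), (0.5, 1.0, (1.0, 2.5))]
    )
    def test_segmentation_override(self, mean, sd, expected):
        assert assign_segmentation(mean, sd) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ranges, inside, expected",
        [
            ((15.0, 10.0, 5.0), True, (0.75, 1.5)),
            ((25.0, 10.0, 5.0), False, (1.25, 2.5)),
            ((20.0, 20.0, 20.0), True, (0.75, 1.5)),   # boundary: "not larger than 2 cm"
            ((20.0, 5.0, 5.0), False, (0.75, 1.5)),
            ((20.1, 5.0, 5.0), False, (1.25, 2.5)),
        ],
    )
    def test_deformation_rule(self, ranges, inside, expected):
        assert assign_deformation(ranges, inside) == expected


class TestTargetingBudget:
    def test_synthetic_records_reproduce_reference_uncertainties(self):
        table = targeting_budget(synthetic_e2e_records())
        np.testing.assert_allclose(table["Sigma_T"], [0.18, 0.33, 0.25], atol=1e-9)
        np.testing.assert_allclose(table["U_T"], [0.49, 0.86, 0.64], atol=1e-9)

    def test_all_zero_offsets(self):
        table = targeting_budget(np.zeros((5, 3)))
        assert (table[["Sigma_T", "U_T"]].to_numpy() == 0).all()

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            targeting_budget(np.zeros((1, 3)))

    def test_sanity_bound(self):
        bad = np.zeros((3, 3))
        bad[0, 0] = 6.0
        with pytest.raises(ValueError, match="5 mm"):
            targeting_budget(bad)


class TestMotionRange:
    def test_constant_trace_is_zero(self):
        with pytest.warns(UserWarning, match="fewer than 100"):
            assert motion_range(np.full(50, 3.0)) == 0.0

    def test_linear_grid_percentile_arithmetic(self):
        x = np.arange(101.0)  # 0..100 mm
        assert motion_range(x) == pytest.approx(98.0)

    def test_dense_cosine_matches_empirical_percentiles(self):
        t = np.linspace(0, 400, 200_000)
        x = 5.0 * np.cos(2 * np.pi * t / 4)  # peak-to-peak 10 mm
        samples = np.sort(x)
        r = 0.01 * (samples.size - 1)
        lo = samples[int(r)] + (r - int(r)) * (samples[int(r) + 1] - samples[int(r)])
        r = 0.99 * (samples.size - 1)
        hi = samples[int(r)] + (r - int(r)) * (samples[int(r) + 1] - samples[int(r)])
        assert motion_range(x) == pytest.approx(hi - lo, abs=1e-12)
        assert motion_range(x) == pytest.approx(10.0, abs=0.2)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.0, 50.0), st.integers(0, 10_000))
    def test_monotone_under_amplitude_scaling(self, k, seed):
        x = np.random.RandomState(seed).normal(0, 2, 300)
        assert motion_range(k * x) == pytest.approx(k * motion_range(x), rel=1e-9, abs=1e-9)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            motion_range(np.array([]))


class TestPatientBudget:
    def test_budget_recovers_injected_structure(self, small_cohort):
        targeting = targeting_budget(synthetic_e2e_records())
        patient = small_cohort[0]
        bundles = [b for _, b in patient.fractions]
        budget, series = compute_patient_budget(bundles, targeting=targeting)
        assert budget.n_fractions == len(bundles)
        # U = |mu| + 2 sigma identity re-derivable from the pooled series
        pooled = np.concatenate([s.errors for s in series["correlation"]], axis=0)
        for k in range(3):
            mu, sd = abs(pooled[:, k].mean()), pooled[:, k].std(ddof=1)
            assert budget.U_C[k] == pytest.approx(mu + 2 * sd)
        np.testing.assert_allclose(budget.Sigma_S, 0.54)
        np.testing.assert_allclose(budget.U_S, 1.46)
        assert budget.Sigma_D[0] in (0.75, 1.25)

    def test_single_fraction_patient_rejected(self, small_cohort):
        targeting = targeting_budget(synthetic_e2e_records())
        with pytest.raises(FractionExcluded):
            compute_patient_budget(
                [small_cohort[0].fractions[0][1]], targeting=targeting
            )
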