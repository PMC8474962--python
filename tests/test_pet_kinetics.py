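"""TAC extraction, image-derived input function, Patlak fit, MR_FDG."""

import numpy as np
import pytest

from petquant.imgcore import (
    DynamicSeries,
    FrameSchedule,
    ImageVolume,
    TimeActivityCurve,
    Units,
    VOIMask,
)
from petquant.pet_kinetics import (
    KineticConfig,
    derive_idif,
    extract_tac,
    mrfdg,
    patlak_fit,
)
from petquant.phantom import (
    AIFParams,
    PhantomScene,
    TwoTCParams,
    build_dynamic_phantom,
    frame_averaged_aif,
    simulate_2tc_tac,
)


def _series_from_array(arr4d, schedule, spacing=(0.4, 0.4, 0.4)):
    frames = tuple(
        ImageVolume(values=arr4d[..., i], spacing=spacing, units=Units.BQ_PER_ML)
        for i in range(arr4d.shape[3])
    )
    return DynamicSeries(frames=frames, schedule=schedule)


@pytest.fixture()
def small_series(rng):
    sched = FrameSchedule(starts=np.arange(6) * 10.0, durations=np.full(6, 10.0))
    return _series_from_array(rng.uniform(1.0, 5.0, (5, 5, 4, 6)), sched)


class TestExtractTAC:
    def test_single_voxel_mask_returns_voxel_course(self, small_series):
        mask = np.zeros((5, 5, 4), bool)
        mask[2, 3, 1] = True
        tac = extract_tac(small_series, VOIMask.like(small_series.grid, mask))
        np.testing.assert_array_equal(tac.values, small_series.as_4d()[2, 3, 1])

    def test_uniform_frames_give_uniform_value(self):
        sched = FrameSchedule(starts=[0.0, 10.0], durations=[10.0, 10.0])
        arr = np.stack([np.full((3, 3, 3), 7.0), np.full((3, 3, 3), 2.0)], axis=-1)
        series = _series_from_array(arr, sched)
        tac = extract_tac(series, VOIMask.like(series.grid, np.ones((3, 3, 3), bool)))
        np.testing.assert_allclose(tac.values, [7.0, 2.0])

    def test_bruteforce_masked_mean(self, small_series, rng):
        sel = rng.random((5, 5, 4)) > 0.5
        tac = extract_tac(small_series, VOIMask.like(small_series.grid, sel))
        arr = small_series.as_4d()
        expected = [
            np.mean([arr[i, j, k, f] for (i, j, k) in zip(*np.nonzero(sel))])
            for f in range(6)
        ]
        np.testing.assert_allclose(tac.values, expected, rtol=1e-12)

    def test_empty_mask_rejected(self, small_series):
        with pytest.raises(ValueError):
            extract_tac(small_series, VOIMask.like(small_series.grid, np.zeros((5, 5, 4), bool)))


class TestDeriveIDIF:
    def test_uniform_series_any_k(self, hour_schedule):
        arr = np.ones((4, 4, 4, 19)) * np.linspace(5, 1, 19)
        series = _series_from_array(arr, hour_schedule)
        box = VOIMask.like(series.grid, np.ones((4, 4, 4), bool), label="cava")
        for k in (1, 7, 64):
            idif = derive_idif(series, box, k=k)
            np.testing.assert_allclose(idif.values, np.linspace(5, 1, 19))

    def test_k_equals_box_size_reduces_to_tac(self, small_series, rng):
        sel = rng.random((5, 5, 4)) > 0.3
        box = VOIMask.like(small_series.grid, sel, label="cava")
        idif = derive_idif(small_series, box, k=box.count)
        tac = extract_tac(small_series, box)
        np.testing.assert_allclose(idif.values, tac.values, rtol=1e-12)

    def test_hot_voxels_selected_by_early_window(self, hour_schedule):
        arr = np.zeros((3, 3, 1, 19))
        arr[0, 0, 0, :] = 1.0
        arr[1, 1, 0, :5] = 50.0  # hot only during the bolus window
        arr[2, 2, 0, -4:] = 100.0  # hot late (spill-in), must not be picked
        series = _series_from_array(arr, hour_schedule)
        box = VOIMask.like(series.grid, np.ones((3, 3, 1), bool), label="cava")
        idif = derive_idif(series, box, k=1)
        np.testing.assert_array_equal(idif.values, arr[1, 1, 0])

    def test_non_bolus_curve_triggers_qc_warning(self, hour_schedule):
        arr = np.ones((2, 2, 1, 19)) * np.linspace(1, 10, 19)  # uptake-like, no bolus
        series = _series_from_array(arr, hour_schedule)
        box = VOIMask.like(series.grid, np.ones((2, 2, 1), bool), label="cava")
        with pytest.warns(UserWarning, match="bolus"):
            derive_idif(series, box, k=2)

    def test_k_larger_than_box_rejected(self, small_series):
        box = np.zeros((5, 5, 4), bool)
        box[0, 0, :2] = True
        with pytest.raises(ValueError, match="fewer than k"):
            derive_idif(small_series, VOIMask.like(small_series.grid, box), k=7)

    def test_phantom_idif_tracks_true_input(self):
        series, truth = build_dynamic_phantom(PhantomScene(seed=42))
        idif = derive_idif(series, truth["masks"]["cava"], k=7)
        cp = truth["cp"]
        i_peak = int(np.argmax(idif.values))
        t_peak = int(np.argmax(cp.values))
        assert abs(i_peak - t_peak) <= 1  # within one frame
        assert idif.values.max() >= 0.7 * cp.values.max()


class TestPatlakFit:
    def test_exact_line_recovered(self):
        # constant input, perfectly linear tissue curve: slope/intercept exact
        sched = FrameSchedule(starts=np.arange(12) * 300.0, durations=np.full(12, 300.0))
        t = sched.mid_times_min
        d = sched.durations / 60.0
        cp = TimeActivityCurve(times_min=t, values=np.ones(12), durations_min=d)
        ct = TimeActivityCurve(times_min=t, values=0.02 * t + 0.05, durations_min=d)
        fit = patlak_fit(ct, cp, t_star_min=20.0)
        assert fit.ki == pytest.approx(0.02, rel=1e-12)
        assert fit.intercept == pytest.approx(0.05, rel=1e-9)
        assert fit.se_ki == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rel_se_percent < 10.0 and fit.passes_quality_gate

    def test_noiseless_2tc_recovers_closed_form_ki(self, default_aif, hour_schedule):
        kin = TwoTCParams(K1=0.1, k2=0.2, k3=0.05, vb=0.0)
        ct = simulate_2tc_tac(default_aif, kin, hour_schedule)
        cp = frame_averaged_aif(default_aif, hour_schedule)
        fit = patlak_fit(ct, cp, t_star_min=20.0)
        assert fit.ki == pytest.approx(kin.ki, rel=0.02)

    def test_t_star_stability_past_equilibration(self, default_aif, hour_schedule):
        kin = TwoTCParams(K1=0.1, k2=0.2, k3=0.05, vb=0.0)
        ct = simulate_2tc_tac(default_aif, kin, hour_schedule)
        cp = frame_averaged_aif(default_aif, hour_schedule)
        ki20 = patlak_fit(ct, cp, 20.0).ki
        ki25 = patlak_fit(ct, cp, 25.0).ki
        assert abs(ki25 - ki20) / ki20 < 0.005

    def test_scale_invariance_and_ct_linearity(self, default_aif, hour_schedule, rng):
        kin = TwoTCParams()
        ct = simulate_2tc_tac(default_aif, kin, hour_schedule)
        cp = frame_averaged_aif(default_aif, hour_schedule)
        base = patlak_fit(ct, cp, 20.0)
        s = float(rng.uniform(0.5, 3.0))
        both = patlak_fit(
            TimeActivityCurve(ct.times_min, s * ct.values, durations_min=ct.durations_min),
            TimeActivityCurve(cp.times_min, s * cp.values, durations_min=cp.durations_min),
            20.0,
        )
        assert both.ki == pytest.approx(base.ki, rel=1e-12)
        only_ct = patlak_fit(
            TimeActivityCurve(ct.times_min, s * ct.values, durations_min=ct.durations_min),
            cp,
            20.0,
        )
        assert only_ct.ki == pytest.approx(s * base.ki, rel=1e-12)

    def test_too_few_late_frames_rejected(self, default_aif, hour_schedule):
        ct = simulate_2tc_tac(default_aif, TwoTCParams(), hour_schedule)
        cp = frame_averaged_aif(default_aif, hour_schedule)
        with pytest.raises(ValueError, match=">= 3 frames"):
            patlak_fit(ct, cp, t_star_min=50.0)

    def test_nonpositive_input_rejected_with_frames(self, hour_schedule):
        t = hour_schedule.mid_times_min
        cp_vals = np.ones(19)
        cp_vals[-2] = 0.0
        ct = TimeActivityCurve(t, np.ones(19))
        cp = TimeActivityCurve(t, cp_vals)
        with pytest.raises(ValueError, match=r"frames \[17\]"):
            patlak_fit(ct, cp, 20.0)

    def test_time_grid_mismatch_rejected(self, hour_schedule):
        t = hour_schedule.mid_times_min
        with pytest.raises(ValueError, match="time grid"):
            patlak_fit(
                TimeActivityCurve(t, np.ones(19)), TimeActivityCurve(t + 0.5, np.ones(19)), 20.0
            )


class TestMRFDG:
    def test_zero_flux(self):
        assert mrfdg(0.0) == 0.0

    def test_cohort_mean_backcomputation(self):
        # Ki 0.039 with glucose 6.0 / LC 0.6 -> 0.39
        assert mrfdg(0.039) == pytest.approx(0.39)

    def test_linear_in_glucose(self):
        base = mrfdg(0.02, KineticConfig(blood_glucose_mmol_l=6.0))
        assert mrfdg(0.02, KineticConfig(blood_glucose_mmol_l=12.0)) == pytest.approx(2 * base)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            KineticConfig(lumped_constant=0.0)
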