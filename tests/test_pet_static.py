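"""SUV conversion, segmentation rules, and static metabolic metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from petquant.imgcore import ImageVolume, ScanMeta, Units, VOIMask
from petquant.pet_static import (
    SegRule,
    decay_correct_dose,
    liver_reference,
    segment_fixed,
    segment_iso40,
    static_metrics,
    to_suv,
)
from tests.conftest import full_mask, make_volume


class TestDecayCorrection:
    def test_zero_interval_unchanged(self):
        assert decay_correct_dose(8.3, 0.0) == pytest.approx(8.3)

    def test_one_half_life_halves(self):
        assert decay_correct_dose(8.0, 109.77) == pytest.approx(4.0)

    def test_ten_minute_decay(self):
        # 9.0 * 2^(-10/109.77); frozen from direct evaluation of the formula
        assert decay_correct_dose(9.0, 10.0) == pytest.approx(8.449263, abs=1e-6)

    def test_negative_interval_grows(self):
        assert decay_correct_dose(4.0, -109.77) == pytest.approx(8.0)


class TestToSUV:
    def _meta(self, dose=8.3, weight=25.0):
        return ScanMeta(injected_dose_mbq=dose, body_weight_g=weight)

    def test_dose_per_weight_concentration_is_unity(self):
        meta = self._meta()
        c = meta.injected_dose_mbq * 1e6 / meta.body_weight_g  # Bq/ml
        act = make_volume(np.full((3, 3, 3), c), units=Units.BQ_PER_ML)
        suv = to_suv(act, meta)
        np.testing.assert_allclose(suv.values, 1.0, rtol=1e-12)
        assert suv.units == Units.SUV

    def test_cohort_scale_example(self):
        # 332 kBq/ml at 8.3 MBq in a 25 g mouse -> SUV 1.0
        act = make_volume(np.full((2, 2, 2), 332e3), units=Units.BQ_PER_ML)
        suv = to_suv(act, self._meta(8.3, 25.0))
        np.testing.assert_allclose(suv.values, 1.0, rtol=1e-12)

    def test_linear_in_body_weight(self, rng):
        act = make_volume(rng.uniform(1e3, 1e6, (4, 4, 4)), units=Units.BQ_PER_ML)
        s1 = to_suv(act, self._meta(weight=20.0))
        s2 = to_suv(act, self._meta(weight=40.0))
        np.testing.assert_allclose(s2.values, 2.0 * s1.values, rtol=1e-12)

    def test_wrong_units_rejected(self):
        act = make_volume(np.ones((2, 2, 2)), units=Units.SUV)
        with pytest.raises(ValueError, match="Bq/ml"):
            to_suv(act, self._meta())


def _flood_fill_oracle(above: np.ndarray, seed_idx) -> np.ndarray:
    """Brute-force 26-connected flood fill from the seed voxel."""
    out = np.zeros_like(above)
    stack = [tuple(seed_idx)]
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    while stack:
        p = stack.pop()
        if out[p] or not above[p]:
            continue
        out[p] = True
        for off in offsets:
            q = tuple(np.add(p, off))
            if all(0 <= qi < si for qi, si in zip(q, above.shape)) and above[q] and not out[q]:
                stack.append(q)
    return out


class TestIso40:
    def test_worked_example_threshold_display(self):
        vals = np.full((6, 6, 6), 0.2)
        vals[3, 3, 3] = 3.8
        suv = make_volume(vals)
        _, thr = segment_iso40(suv, full_mask(suv))
        assert thr == pytest.approx(1.52)
        assert round(thr, 1) == 1.5  # reported display threshold

    def test_uniform_sphere_recovered_exactly(self):
        shape = (20, 20, 20)
        idx = np.indices(shape)
        sphere = ((idx - 9.5) ** 2).sum(axis=0) <= 36.0
        vals = np.where(sphere, 4.0, 0.1)
        suv = make_volume(vals)
        mask, thr = segment_iso40(suv, full_mask(suv))
        assert thr == pytest.approx(1.6)
        np.testing.assert_array_equal(mask.values, sphere)

    def test_component_matches_flood_fill_oracle(self, rng):
        vals = ndimage.gaussian_filter(rng.random((16, 16, 16)), 1.5)
        suv = make_volume(vals)
        mask, thr = segment_iso40(suv, full_mask(suv))
        above = vals >= thr
        seed = np.unravel_index(np.argmax(vals), vals.shape)
        np.testing.assert_array_equal(mask.values, _flood_fill_oracle(above, seed))

    def test_max_voxel_always_inside_and_all_above_threshold(self, rng):
        vals = rng.random((12, 12, 12))
        suv = make_volume(vals)
        mask, thr = segment_iso40(suv, full_mask(suv))
        assert mask.values[np.unravel_index(np.argmax(vals), vals.shape)]
        assert np.all(vals[mask.values] >= 0.4 * vals.max() - 1e-12)

    def test_exclusions_remove_hot_organ(self):
        vals = np.full((10, 10, 10), 0.1)
        vals[1, 1, 1] = 9.0  # "bladder"
        vals[7, 7, 7] = 3.0  # tumor
        suv = make_volume(vals)
        excl = np.zeros((10, 10, 10), bool)
        excl[:3, :3, :3] = True
        mask, thr = segment_iso40(
            suv, full_mask(suv), [VOIMask.like(suv, excl, label="bladder")]
        )
        assert thr == pytest.approx(1.2)
        assert mask.values[7, 7, 7] and not mask.values[1, 1, 1]

    def test_empty_search_region_rejected(self):
        suv = make_volume(np.ones((4, 4, 4)))
        everything = VOIMask.like(suv, np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            segment_iso40(suv, everything, [everything])


class TestFixedThreshold:
    def test_all_below_threshold_is_empty_with_flag(self):
        suv = make_volume(np.full((5, 5, 5), 2.4))
        with pytest.warns(UserWarning, match="no voxels"):
            mask = segment_fixed(suv, full_mask(suv), threshold=2.5)
        assert mask.is_empty

    def test_zero_threshold_returns_search_region(self):
        suv = make_volume(np.random.default_rng(0).random((5, 5, 5)))
        mask = segment_fixed(suv, full_mask(suv), threshold=0.0)
        assert mask.count == 125

    @given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_grows_mask(self, t1, t2):
        lo, hi = sorted((t1, t2))
        vals = np.random.default_rng(7).random((6, 6, 6)) * 5.0
        suv = make_volume(vals)
        m_lo = segment_fixed(suv, full_mask(suv), threshold=lo)
        m_hi = segment_fixed(suv, full_mask(suv), threshold=hi)
        assert np.all(m_lo.values | ~m_hi.values)  # m_hi subset of m_lo

    def test_fixed_smaller_than_iso40_when_iso_threshold_lower(self):
        # blurred lesion whose SUVmax ~ 3.8: iso threshold 1.5 < 2.5 fixed
        shape = (24, 24, 24)
        idx = np.indices(shape)
        blob = np.exp(-((idx - 11.5) ** 2).sum(axis=0) / (2 * 9.0))
        vals = 3.8 * blob / blob.max()
        suv = make_volume(vals)
        iso_mask, thr = segment_iso40(suv, full_mask(suv))
        fixed_mask = segment_fixed(suv, full_mask(suv), threshold=2.5)
        assert thr < 2.5
        assert fixed_mask.count < iso_mask.count
        assert np.all(iso_mask.values | ~fixed_mask.values)  # fixed subset of iso


class TestStaticMetrics:
    def test_arithmetic_example(self):
        vals = np.full((10, 10, 10), 0.0)
        vals.ravel()[:100] = 2.0
        suv = make_volume(vals)
        mask = VOIMask.like(suv, vals > 0)
        m = static_metrics(suv, mask)
        assert m.mtv_mm3 == pytest.approx(6.4)
        assert m.suv_mean == pytest.approx(2.0)
        assert m.tlg == pytest.approx(12.8)

    def test_tlg_identity_and_bruteforce_oracle(self, rng):
        for _ in range(20):
            vals = rng.uniform(0.1, 5.0, (8, 8, 8))
            sel = rng.random((8, 8, 8)) > 0.6
            if not sel.any():
                continue
            suv = make_volume(vals)
            m = static_metrics(suv, VOIMask.like(suv, sel))
            assert m.tlg == m.suv_mean * m.mtv_mm3  # exact identity
            # brute-force masked loop
            acc = [vals[i] for i in zip(*np.nonzero(sel))]
            assert m.suv_mean == pytest.approx(np.mean(acc), rel=1e-12)
            assert m.suv_max == pytest.approx(np.max(acc), rel=1e-12)
            assert m.mtv_mm3 == pytest.approx(len(acc) * 0.064, rel=1e-12)

    def test_empty_mask_rejected(self):
        suv = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            static_metrics(suv, VOIMask.like(suv, np.zeros((3, 3, 3), bool)))


class TestLiverReference:
    def test_uniform_liver_values(self):
        for level in (0.53, 1.0):
            suv = make_volume(np.full((5, 5, 5), level))
            mask = VOIMask.like(suv, np.ones((5, 5, 5), bool), label="liver")
            assert liver_reference(suv, mask) == pytest.approx(level)

    def test_bruteforce_oracle(self, rng):
        vals = rng.uniform(0.3, 0.8, (6, 6, 6))
        sel = rng.random((6, 6, 6)) > 0.5
        suv = make_volume(vals)
        got = liver_reference(suv, VOIMask.like(suv, sel, label="liver"))
        assert got == pytest.approx(float(np.mean([vals[i] for i in zip(*np.nonzero(sel))])))

    def test_empty_liver_rejected(self):
        suv = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            liver_reference(suv, VOIMask.like(suv, np.zeros((3, 3, 3), bool), label="liver"))
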