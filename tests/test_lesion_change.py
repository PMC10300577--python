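"""Subtraction-image Z-maps, change labelling, event taxonomy, TLVC."""

import numpy as np
import pytest
from scipy.stats import norm

from mslat.lesion_change import (
    ChangeLabelMap,
    LesionEvent,
    LesionEventSet,
    ZMap,
    classify_lesion_events,
    estimate_interval_change,
    label_change_voxels,
    subtraction_image,
    total_lesion_volume_change,
    zscore_normalize,
)
from mslat.phantom import (
    ChangeSpec,
    LesionEvent as PhantomEvent,
    apply_longitudinal_change,
)


def _mask_box(shape=(30, 30, 20)):
    m = np.zeros(shape, bool)
    m[2:28, 2:28, 2:18] = True
    return m


class TestSubtraction:
    def test_identical_inputs_give_zero(self, rng):
        v = rng.normal(size=(10, 10, 10))
        m = np.ones(v.shape, bool)
        assert np.allclose(subtraction_image(v, v, m), 0.0)

    def test_offset_and_antisymmetry(self, rng):
        v1 = rng.normal(size=(10, 10, 10))
        m = np.ones(v1.shape, bool)
        v2 = v1 + 5.0
        D = subtraction_image(v1, v2, m)
        assert np.allclose(D[m], 5.0)
        assert np.allclose(subtraction_image(v2, v1, m), -D)

    def test_masked_out_voxels_are_zero(self, rng):
        v1 = rng.normal(size=(10, 10, 10))
        m = np.zeros(v1.shape, bool)
        m[3:7, 3:7, 3:7] = True
        D = subtraction_image(v1, v1 + 2.0, m)
        assert np.all(D[~m] == 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            subtraction_image(
                np.zeros((5, 5, 5)), np.zeros((6, 5, 5)), np.ones((5, 5, 5), bool)
            )


class TestZScore:
    def test_reference_stats_normalise_nonlesional_tissue(self, rng):
        m = _mask_box()
        D = rng.normal(3.0, 7.0, m.shape)
        lesion = np.zeros_like(m)
        lesion[10:14, 10:14, 8:12] = True
        zm = zscore_normalize(D, m, lesion)
        nl = m & ~lesion
        assert zm.z[nl].mean() == pytest.approx(0.0, abs=1e-6)
        assert zm.z[nl].std() == pytest.approx(1.0, abs=1e-6)

    def test_noise_exceedance_matches_gaussian_tail(self, rng):
        m = np.ones((50, 50, 50), bool)
        D = rng.normal(0.0, 4.0, m.shape)
        zm = zscore_normalize(D, m, np.zeros_like(m))
        frac = np.mean(np.abs(zm.z) > 1.5)
        expected = 2 * (1 - norm.cdf(1.5))  # 0.1336
        assert 0.12 <= frac <= 0.15
        assert frac == pytest.approx(expected, abs=0.01)

    def test_affine_rescaling_invariance(self, rng):
        m = _mask_box()
        D = rng.normal(size=m.shape)
        z1 = zscore_normalize(D, m, np.zeros_like(m)).z
        z2 = zscore_normalize(2.5 * D + 7.0, m, np.zeros_like(m)).z
        assert np.allclose(z1, z2, atol=1e-9)

    def test_constant_difference_rejected(self):
        m = _mask_box()
        with pytest.raises(ValueError, match="degenerate"):
            zscore_normalize(np.full(m.shape, 4.0), m, np.zeros_like(m))

    def test_too_few_nonlesional_voxels_rejected(self, rng):
        m = np.zeros((10, 10, 10), bool)
        m[4:6, 4:6, 4:6] = True
        with pytest.raises(ValueError, match="non-lesional"):
            zscore_normalize(rng.normal(size=m.shape), m, np.zeros_like(m))


class TestLabelChange:
    def _zmap(self, z):
        return ZMap(z=z, reference_stats=(0.0, 1.0), brain_mask=np.ones(z.shape, bool))

    def test_threshold_is_strict(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = 1.5  # exactly at threshold: NOT changing
        z[1, 0, 0] = 1.5000001
        mask = np.ones(z.shape, bool)
        lab = label_change_voxels(self._zmap(z), mask, threshold=1.5)
        assert lab.labels[0, 0, 0] == 0
        assert lab.labels[1, 0, 0] == 1

    def test_decrease_and_outside_mask(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = -2.0
        z[3, 3, 3] = 3.0
        mask = np.zeros(z.shape, bool)
        mask[0, 0, 0] = True  # (3,3,3) outside the lesion mask
        lab = label_change_voxels(self._zmap(z), mask)
        assert lab.labels[0, 0, 0] == -1
        assert lab.labels[3, 3, 3] == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            label_change_voxels(self._zmap(np.zeros((2, 2, 2))), np.ones((2, 2, 2), bool), 0.0)


class TestClassifyEvents:
    SPACING = (1.0, 1.0, 1.0)

    def _change(self, shape, increase=(), decrease=()):
        lab = np.zeros(shape, np.int8)
        for v in increase:
            lab[v] = 1
        for v in decrease:
            lab[v] = -1
        return ChangeLabelMap(labels=lab, threshold=1.5)

    def test_new_lesion_gets_component_volume(self):
        shape = (12, 12, 12)
        m1 = np.zeros(shape, bool)
        m2 = np.zeros(shape, bool)
        m2[4:7, 4:7, 4:6] = True  # 18 voxels, only at follow-up
        inc = [tuple(v) for v in np.argwhere(m2)]
        ev = classify_lesion_events(m1, m2, self._change(shape, increase=inc), self.SPACING)
        assert len(ev.events) == 1
        assert ev.events[0].category == "new"
        assert ev.events[0].volume_ml == pytest.approx(18 * 1e-3)

    def test_identical_masks_below_threshold_give_no_events(self):
        shape = (10, 10, 10)
        m = np.zeros(shape, bool)
        m[3:6, 3:6, 3:6] = True
        ev = classify_lesion_events(m, m, self._change(shape), self.SPACING)
        assert ev.events == []

    def test_matched_pair_net_change_volume(self):
        """10 increase and 4 decrease voxels in a matched pair -> enlarging 0.006 mL."""
        shape = (14, 14, 14)
        m1 = np.zeros(shape, bool)
        m1[4:8, 4:8, 4:7] = True
        m2 = m1.copy()
        m2[3, 4:9, 4:6] = True  # overlapping, slightly different
        inc = [(3, 4 + j, 4 + k) for j in range(5) for k in range(2)]  # 10 voxels
        dec = [(7, 4 + j, 4) for j in range(4)]  # 4 voxels inside the union
        ev = classify_lesion_events(
            m1, m2, self._change(shape, increase=inc, decrease=dec), self.SPACING
        )
        assert len(ev.events) == 1
        assert ev.events[0].category == "enlarging"
        assert ev.events[0].volume_ml == pytest.approx(0.006)

    def test_disappearing_requires_decrease_evidence(self):
        shape = (12, 12, 12)
        m1 = np.zeros(shape, bool)
        m1[4:7, 4:7, 4:6] = True
        m2 = np.zeros(shape, bool)
        dec = [tuple(v) for v in np.argwhere(m1)]
        ev = classify_lesion_events(m1, m2, self._change(shape, decrease=dec), self.SPACING)
        assert [e.category for e in ev.events] == ["disappearing"]
        # without any decrease voxel the vanished component emits nothing
        ev2 = classify_lesion_events(m1, m2, self._change(shape), self.SPACING)
        assert ev2.events == []


class TestTlvc:
    def _events(self, spec):
        evs = [
            LesionEvent(i + 1, cat, np.zeros((1, 3), int), vol)
            for i, (cat, vol) in enumerate(spec)
        ]
        return LesionEventSet(events=evs, spacing=(1, 1, 1))

    def test_formula_on_mixed_events(self):
        res = total_lesion_volume_change(
            self._events(
                [("new", 0.5), ("enlarging", 0.3), ("shrinking", 0.2), ("disappearing", 0.1)]
            )
        )
        assert res.tlvc_ml == pytest.approx(0.5)
        assert res.positive_ml == pytest.approx(0.8)
        assert res.negative_ml == pytest.approx(0.3)

    def test_only_disappearing_is_negative(self):
        res = total_lesion_volume_change(self._events([("disappearing", 0.4)]))
        assert res.tlvc_ml == pytest.approx(-0.4)

    def test_empty_set_is_zero(self):
        res = total_lesion_volume_change(self._events([]))
        assert res.tlvc_ml == 0.0


class TestEndToEnd:
    def test_null_interval_calibration(self, lesioned_baseline):
        """Noise-only pairs: mean TLVC within 3 SE of zero over 20 replicates."""
        vals = []
        for k in range(20):
            follow, _ = apply_longitudinal_change(
                lesioned_baseline, ChangeSpec(), seed=100 + k
            )
            res = estimate_interval_change(lesioned_baseline, follow, register=False)
            vals.append(res.tlvc.tlvc_ml)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * max(se, 1e-9)

    def test_growth_and_shrinkage_sign_coherence(self, lesioned_baseline):
        grow = ChangeSpec(
            lesion_events=(
                PhantomEvent("enlarge", (32.0, 14.0, 28.0), delta_radius_mm=1.2),
            )
        )
        shrink = ChangeSpec(
            lesion_events=(
                PhantomEvent("shrink", (32.0, 14.0, 28.0), delta_radius_mm=1.2),
            )
        )
        f1, _ = apply_longitudinal_change(lesioned_baseline, grow, seed=31)
        f2, _ = apply_longitudinal_change(lesioned_baseline, shrink, seed=32)
        r1 = estimate_interval_change(lesioned_baseline, f1, register=False)
        r2 = estimate_interval_change(lesioned_baseline, f2, register=False)
        assert r1.tlvc.tlvc_ml > 0
        assert r2.tlvc.tlvc_ml < 0

    def test_visit_swap_negates_tlvc(self, lesioned_baseline):
        change = ChangeSpec(
            lesion_events=(
                PhantomEvent("enlarge", (32.0, 14.0, 28.0), delta_radius_mm=1.0),
                PhantomEvent("disappear", (48.0, 32.0, 28.0)),
            )
        )
        follow, _ = apply_longitudinal_change(lesioned_baseline, change, seed=41)
        fwd = estimate_interval_change(lesioned_baseline, follow, register=False)
        rev = estimate_interval_change(follow, lesioned_baseline, register=False)
        assert rev.tlvc.tlvc_ml == pytest.approx(-fwd.tlvc.tlvc_ml, abs=0.05)
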