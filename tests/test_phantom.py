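"""Generator correctness: analytic truth, determinism, cohort structure."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from mslat.phantom import (
    ChangeSpec,
    CohortSpec,
    Lesion,
    LesionEvent,
    PhantomSpec,
    apply_longitudinal_change,
    make_baseline_phantom,
    simulate_cohort,
)

SPHERE = lambda r: 4.0 / 3.0 * np.pi * r**3


class TestBaseline:
    def test_noiseless_phantom_is_piecewise_constant_in_tissue_interiors(self, clean_baseline):
        """Away from tissue interfaces (no partial volume) intensities are
        exactly the tissue means."""
        spec = clean_baseline.spec
        sp = np.asarray(spec.voxel_size_mm)
        axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, sp)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        c = spec.centre_mm

        def rho(radii):
            r = np.asarray(radii)
            return np.sqrt(
                ((xx - c[0]) / r[0]) ** 2
                + ((yy - c[1]) / r[1]) ** 2
                + ((zz - c[2]) / r[2]) ** 2
            )

        margin = 4.0  # mm clear of every interface
        inner = np.asarray(spec.brain_radii_mm) - spec.gm_thickness_mm
        wm_core = (rho(inner - margin) < 1.0) & (
            rho(np.asarray(spec.ventricle_radii_mm) + margin) > 1.0
        )
        assert wm_core.sum() > 500
        assert np.allclose(
            clean_baseline.pd_img[wm_core], spec.tissue_means["pd"]["wm"]
        )
        vent_core = rho(np.asarray(spec.ventricle_radii_mm) - margin) < 1.0
        assert vent_core.sum() > 20
        assert np.allclose(
            clean_baseline.pd_img[vent_core], spec.tissue_means["pd"]["csf"]
        )

    def test_same_seed_is_bit_identical(self, lesioned_spec):
        a = make_baseline_phantom(lesioned_spec, seed=5)
        b = make_baseline_phantom(lesioned_spec, seed=5)
        assert np.array_equal(a.pd_img, b.pd_img)
        assert np.array_equal(a.t1_img, b.t1_img)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate grid"):
            PhantomSpec(grid_shape=(8, 64, 20))

    def test_lesion_voxel_volume_close_to_analytic_sphere(self):
        """Voxelised 3 mm lesion volume within 15% of (4/3)pi r^3, and equal
        to a brute-force voxel-centre-inside count within one voxel shell."""
        centre = (32.0, 14.0, 28.5)  # mid-slice in z
        spec = PhantomSpec(lesions=(Lesion(centre, 3.0),))
        vol = make_baseline_phantom(spec, seed=0)
        est = vol.lesion_mask.sum() * np.prod(spec.voxel_size_mm)
        assert abs(est - SPHERE(3.0)) / SPHERE(3.0) < 0.15
        # independent oracle: count voxel centres inside the sphere
        sp = np.asarray(spec.voxel_size_mm)
        axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, sp)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        inside = (
            (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2
        ) <= 9.0
        assert abs(int(vol.lesion_mask.sum()) - int(inside.sum())) <= 8

    def test_lesions_hyperintense_on_pd(self, lesioned_baseline):
        spec = lesioned_baseline.spec
        wm = (
            lesioned_baseline.brain_mask
            & ~lesioned_baseline.ventricle_mask
            & ~lesioned_baseline.lesion_mask
        )
        assert (
            lesioned_baseline.pd_img[lesioned_baseline.lesion_mask].mean()
            > lesioned_baseline.pd_img[wm].mean() + 5 * spec.noise_sd
        )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="ventricle"):
            PhantomSpec(ventricle_radii_mm=(30.0, 30.0, 30.0))
        with pytest.raises(ValueError, match="hyperintense"):
            PhantomSpec(
                tissue_means={
                    "pd": {"wm": 800, "gm": 900, "csf": 1100, "lesion": 700},
                    "t1": {"wm": 1000, "gm": 800, "csf": 300, "lesion": 700},
                }
            )


class TestLongitudinalChange:
    def test_identity_change_reproduces_baseline(self, clean_baseline):
        follow, truth = apply_longitudinal_change(
            clean_baseline, ChangeSpec(), seed=9
        )
        assert np.array_equal(follow.pd_img, clean_baseline.pd_img)
        assert truth.true_tlvc_ml == 0.0
        assert truth.true_pbvc_percent == 0.0

    def test_scaling_truth_is_analytic(self, clean_baseline):
        _, truth = apply_longitudinal_change(
            clean_baseline, ChangeSpec(brain_scale=0.99), seed=9
        )
        assert truth.true_pbvc_percent == pytest.approx(100 * (0.99**3 - 1))
        assert truth.true_pbvc_percent == pytest.approx(-2.9701)

    def test_brain_mask_volume_ratio_tracks_scale(self, clean_baseline):
        s = 0.97  # large enough to exceed voxelisation granularity
        follow, _ = apply_longitudinal_change(
            clean_baseline, ChangeSpec(brain_scale=s), seed=9
        )
        ratio = follow.brain_mask.sum() / clean_baseline.brain_mask.sum()
        # within one boundary-voxel shell of s^3
        shell = np.count_nonzero(
            clean_baseline.brain_mask & ~ndi.binary_erosion(clean_baseline.brain_mask)
        ) / clean_baseline.brain_mask.sum()
        assert abs(ratio - s**3) < shell

    def test_disappear_event_forces_negative_tlvc(self):
        r = (300.0 / np.pi) ** (1 / 3)  # sphere of exactly 0.4 mL
        spec = PhantomSpec(lesions=(Lesion((32.0, 14.0, 28.0), r),))
        base = make_baseline_phantom(spec, seed=2)
        _, truth = apply_longitudinal_change(
            base,
            ChangeSpec(lesion_events=(LesionEvent("disappear", (32.0, 14.0, 28.0)),)),
            seed=3,
        )
        assert truth.true_tlvc_ml == pytest.approx(-0.4)

    def test_tlvc_identity_over_event_mix(self, lesioned_baseline):
        events = (
            LesionEvent("enlarge", (32.0, 14.0, 28.0), delta_radius_mm=1.0),
            LesionEvent("disappear", (48.0, 32.0, 28.0)),
            LesionEvent("new", (44.0, 18.0, 28.5), radius_mm=2.5),
        )
        _, truth = apply_longitudinal_change(
            lesioned_baseline, ChangeSpec(lesion_events=events), seed=4
        )
        v = truth.true_event_volumes_ml
        assert truth.true_tlvc_ml == pytest.approx(
            v["new"] + v["enlarging"] - v["shrinking"] - v["disappearing"]
        )

    def test_merging_lesions_rejected(self, lesioned_baseline):
        with pytest.raises(ValueError, match="merge"):
            apply_longitudinal_change(
                lesioned_baseline,
                ChangeSpec(
                    lesion_events=(
                        LesionEvent("new", (36.0, 16.0, 28.0), radius_mm=3.0),
                    )
                ),
                seed=1,
            )

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError, match="brain_scale"):
            ChangeSpec(brain_scale=0.5)


class TestCohort:
    def test_covariate_table_structure_and_determinism(self):
        cs = CohortSpec(n_subjects=4, n_sites=3, n_intervals=2)
        a = simulate_cohort(cs, seed=21)
        b = simulate_cohort(cs, seed=21)
        assert a.covariates.equals(b.covariates)
        assert a.covariates["site"].nunique() <= 3
        assert len(a.covariates) == 4 * 2
        assert set(a.covariates.columns) >= {
            "subject", "site", "age", "sex", "treatment", "cdms", "interval",
        }

    def test_three_sites_present_in_larger_cohort(self):
        cs = CohortSpec(n_subjects=20, n_sites=3, n_intervals=1)
        coh = simulate_cohort(cs, seed=2)
        assert coh.covariates["site"].nunique() == 3

    def test_truth_tlvc_is_signed_event_sum(self):
        coh = simulate_cohort(CohortSpec(n_subjects=5, n_intervals=2), seed=8)
        for iv in coh.intervals:
            v = iv.truth.true_event_volumes_ml
            assert iv.truth.true_tlvc_ml == pytest.approx(
                v["new"] + v["enlarging"] - v["shrinking"] - v["disappearing"]
            )

    def test_zero_coupling_leaves_tlvc_and_dilation_independent(self):
        """Under coupling_beta = 0 the TLVC / ventricular-change correlation
        is consistent with independence (|mean r| < 0.2 over 4 cohorts of 40)."""
        rs = []
        for seed in (11, 12, 13, 14):
            coh = simulate_cohort(
                CohortSpec(n_subjects=40, n_intervals=1, coupling_beta=0.0), seed
            )
            t = np.array([iv.truth.true_tlvc_ml for iv in coh.intervals])
            p = np.array([iv.truth.true_pvvc_percent for iv in coh.intervals])
            rs.append(np.corrcoef(t, p)[0, 1])
        assert abs(np.mean(rs)) < 0.2

    def test_coupling_injects_linear_displacement(self):
        beta = 0.3
        coh = simulate_cohort(
            CohortSpec(n_subjects=10, n_intervals=1, coupling_beta=beta), seed=5
        )
        for iv in coh.intervals:
            assert iv.truth.true_coupled_displacement_mm == pytest.approx(
                beta * iv.truth.true_tlvc_ml
            )

    def test_invalid_cohort_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)
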