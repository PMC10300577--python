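"""Template selection, map preparation, GLM, TFCE, permutation, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy import stats

from mslat.voxelwise import (
    build_design,
    build_template,
    glm_fit,
    make_template_space,
    mask_adjacency,
    permutation_fwe,
    prepare_displacement_map,
    select_template_subjects,
    summarize_regions,
    tfce_enhance,
)


@pytest.fixture(scope="module")
def template():
    shape = (24, 24, 12)
    xx, yy, zz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cx, cy, cz = [(s - 1) / 2 for s in shape]
    brain = ((xx - cx) / 10) ** 2 + ((yy - cy) / 10) ** 2 + ((zz - cz) / 4.6) ** 2 <= 1
    vent = ((xx - cx) / 3.5) ** 2 + ((yy - cy) / 4.5) ** 2 + ((zz - cz) / 2) ** 2 <= 1
    return make_template_space(brain, vent, (1.0, 1.0, 3.0))


def tfce_brute_force(stat_map, mask, E=0.5, H=2.0, dh=0.05):
    """Independent threshold-loop oracle using per-threshold labelling."""
    out = np.zeros(stat_map.shape)
    st = ndi.generate_binary_structure(3, 3)
    vals = np.where(mask, stat_map, 0.0)
    for sign in (1, -1):
        v = np.maximum(sign * vals, 0.0)
        hmax = v.max()
        k = 1
        while k * dh <= hmax + 1e-12:
            h = k * dh
            lab, _ = ndi.label(v >= h, structure=st)
            sizes = np.bincount(lab.ravel())
            out += sign * np.where(v >= h, sizes[lab] ** E * h**H * dh, 0.0)
            k += 1
    return out


class TestTemplateSelection:
    def test_all_subjects_when_k_equals_n(self):
        nbv = {f"s{i}": 0.5 + 0.01 * i for i in range(5)}
        assert sorted(select_template_subjects(nbv, 5)) == sorted(nbv)

    def test_k_one_picks_median_subject(self):
        nbv = {f"s{i}": float(i) for i in range(11)}
        # median percentile grid point of 0..10 -> value nearest 5.05
        assert select_template_subjects(nbv, 1) == ["s5"]

    def test_ties_broken_by_subject_id(self):
        nbv = {"b": 1.0, "a": 1.0, "c": 1.0}
        assert select_template_subjects(nbv, 1) == ["a"]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            select_template_subjects({"a": 1.0}, 2)

    def test_template_is_mean_of_normalised_inputs(self):
        a = np.zeros((6, 6, 6))
        a[1:5, 1:5, 1:5] = 100.0
        b = a * 3.0
        out = build_template({"a": a, "b": b}, {"a": 1.0, "b": 2.0}, k=2)
        # both normalise to the same volume; mean equals either
        expected = a / np.percentile(a[a != 0], 99) * 10000
        assert np.allclose(out, expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            build_template(
                {"a": np.ones((4, 4, 4)), "b": np.ones((5, 4, 4))},
                {"a": 1.0, "b": 2.0}, k=2,
            )


class TestTemplateSpace:
    def test_atlas_regions_disjoint_and_cover_edge(self, template):
        total = np.zeros(template.edge_mask.shape, int)
        for m in template.atlas.values():
            total += m.astype(int)
        assert total.max() <= 1
        # every edge voxel inside the brain belongs to some region
        in_brain_edge = template.edge_mask & template.brain_mask
        covered = np.zeros_like(in_brain_edge)
        for m in template.atlas.values():
            covered |= m
        assert (covered | ~in_brain_edge).all()

    def test_periventricular_surrounds_ventricles(self, template):
        pv = template.atlas["periventricular"]
        assert pv.sum() > 0
        vent_edge_halo = ndi.binary_dilation(pv, iterations=1)
        assert (template.atlas["frontal"] & pv).sum() == 0
        assert vent_edge_halo.sum() >= pv.sum()


class TestPrepareMap:
    def test_zero_in_zero_out(self, template):
        out = prepare_displacement_map(np.zeros(template.edge_mask.shape), template)
        assert np.allclose(out.data, 0.0)

    def test_single_voxel_matches_masked_gaussian(self, template):
        v = np.zeros(template.edge_mask.shape)
        seed_vox = tuple(np.argwhere(template.edge_mask)[40])
        v[seed_vox] = -1.0
        out = prepare_displacement_map(v, template, dilate_vox=0, sigma_mm=5.0)
        sig_vox = 5.0 / np.asarray(template.spacing)
        expected = np.zeros_like(v)
        expected[seed_vox] = -1.0
        expected = ndi.gaussian_filter(expected, sig_vox, mode="constant")
        expected[~template.edge_mask] = 0.0
        assert np.allclose(out.data, expected, atol=1e-12)
        peak = np.unravel_index(np.argmin(out.data), out.data.shape)
        assert peak == seed_vox

    def test_dilation_propagates_max_magnitude_value(self, template):
        v = np.zeros(template.edge_mask.shape)
        idx = np.argwhere(template.edge_mask)[50]
        v[tuple(idx)] = -2.0
        nb = tuple(idx + np.array([1, 0, 0]))
        v[nb] = 0.5
        out_nodil = prepare_displacement_map(v, template, dilate_vox=0, sigma_mm=0.8)
        out_dil = prepare_displacement_map(v, template, dilate_vox=1, sigma_mm=0.8)
        # dilation spreads the -2 into previously-zero neighbours: mass grows
        assert np.abs(out_dil.data).sum() > np.abs(out_nodil.data).sum()

    def test_output_zero_outside_edge_mask(self, template, rng):
        v = rng.normal(size=template.edge_mask.shape)
        out = prepare_displacement_map(v, template)
        assert np.all(out.data[~template.edge_mask] == 0)

    def test_nonpositive_sigma_rejected(self, template):
        with pytest.raises(ValueError):
            prepare_displacement_map(
                np.zeros(template.edge_mask.shape), template, sigma_mm=0.0
            )


class TestDesignAndGlm:
    def _cov(self, n, rng, sites=2):
        return pd.DataFrame(
            {
                "site": rng.integers(sites, size=n),
                "age": rng.normal(31.5, 8.35, n),
                "sex": rng.integers(2, size=n),
                "tlvc": rng.normal(0, 1, n),
            }
        )

    def test_site_indicators_sum_to_intercept(self, rng):
        X, c, names = build_design(self._cov(20, rng), regressor="tlvc")
        site_cols = [j for j, n in enumerate(names) if n.startswith("site[")]
        assert np.allclose(X[:, site_cols].sum(axis=1), 1.0)
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_interaction_contrast_tests_slope_difference(self, rng):
        cov = self._cov(30, rng)
        cov["treatment"] = np.where(np.arange(30) % 2 == 0, "ET", "DT")
        X, c, names = build_design(cov, regressor="tlvc", interaction="treatment")
        assert (c != 0).sum() == 2
        slope_cols = [n for n, ci in zip(names, c) if ci != 0]
        assert all("tlvc:" in n for n in slope_cols)

    def test_exact_linear_response_recovered(self, rng):
        cov = self._cov(25, rng)
        X, c, _ = build_design(cov, regressor="tlvc")
        x = cov["tlvc"] - cov["tlvc"].mean()
        Y = np.outer(2.0 * x, np.ones(7))
        beta, t = glm_fit(Y, X, c)
        assert np.allclose(beta, 2.0, atol=1e-9)
        assert np.all(np.abs(t) > 1e5)

    def test_intercept_absorbs_response_offset(self, rng):
        cov = self._cov(25, rng)
        X, c, _ = build_design(cov, regressor="tlvc")
        Y = rng.normal(size=(25, 9))
        b1, _ = glm_fit(Y, X, c)
        b2, _ = glm_fit(Y + 11.0, X, c)
        assert np.allclose(b1, b2, atol=1e-9)

    def test_null_t_distribution_is_student(self, rng):
        cov = self._cov(24, rng)
        X, c, _ = build_design(cov, regressor="tlvc")
        Y = rng.normal(size=(24, 5000))
        _, t = glm_fit(Y, X, c)
        df = 24 - X.shape[1]
        ks = stats.kstest(t, stats.t(df).cdf)
        assert ks.pvalue > 0.01

    def test_collinear_design_rejected_with_name(self, rng):
        cov = self._cov(20, rng)
        X, c, names = build_design(cov, regressor="tlvc")
        X2 = np.column_stack([X, X[:, -1]])
        with pytest.raises(ValueError, match="collinear"):
            glm_fit(rng.normal(size=(20, 3)), X2, np.append(c, 0.0))

    def test_zero_variance_voxels_get_zero_t(self, rng):
        cov = self._cov(20, rng)
        X, c, _ = build_design(cov, regressor="tlvc")
        Y = np.zeros((20, 3))
        _, t = glm_fit(Y, X, c)
        assert np.all(t == 0)


class TestTfce:
    def test_all_zero_map(self):
        mask = np.ones((6, 6, 6), bool)
        assert np.allclose(tfce_enhance(np.zeros((6, 6, 6)), mask), 0.0)

    def test_isolated_voxel_matches_discrete_sum(self):
        mask = np.ones((9, 9, 9), bool)
        m = np.zeros((9, 9, 9))
        m[4, 4, 4] = 2.0
        dh = 0.1
        out = tfce_enhance(m, mask, dh=dh)
        ks = np.arange(1, int(np.floor(2.0 / dh)) + 1)
        expected = np.sum(1.0**0.5 * (ks * dh) ** 2 * dh)
        assert out[4, 4, 4] == pytest.approx(expected, rel=1e-9)
        assert np.count_nonzero(out) == 1

    def test_matches_brute_force_oracle_on_random_maps(self, rng):
        mask = np.ones((8, 8, 8), bool)
        for _ in range(5):
            m = rng.normal(size=(8, 8, 8))
            mine = tfce_enhance(m, mask, dh=0.05)
            oracle = tfce_brute_force(m, mask, dh=0.05)
            assert np.max(np.abs(mine - oracle)) <= 0.01 * np.abs(oracle).max()

    def test_coarse_dh_close_to_fine(self, rng):
        mask = np.ones((10, 10, 10), bool)
        m = ndi.gaussian_filter(rng.normal(size=(10, 10, 10)), 1.5)
        m /= np.abs(m).max()
        fine = tfce_enhance(m, mask, dh=0.005)
        coarse = tfce_enhance(m, mask, dh=0.01)
        top = np.abs(fine) > 0.1 * np.abs(fine).max()
        rel = np.abs(coarse[top] - fine[top]) / np.abs(fine[top])
        assert np.median(rel) < 0.05

    def test_scaling_monotonicity(self, rng):
        mask = np.ones((8, 8, 8), bool)
        m = np.abs(rng.normal(size=(8, 8, 8)))
        c = 1.7
        base = tfce_enhance(m, mask, n_steps=200)
        scaled = tfce_enhance(c * m, mask, n_steps=200)
        sel = base > 1e-9
        assert np.all(scaled[sel] >= (c**2.0) * base[sel] * (1 - 0.05))


class TestPermutationFwe:
    def _setup(self, template, rng, n=16):
        cov = pd.DataFrame(
            {
                "site": rng.integers(2, size=n),
                "age": rng.normal(30, 8, n),
                "sex": rng.integers(2, size=n),
                "tlvc": rng.normal(0, 1, n),
            }
        )
        X, c, _ = build_design(cov, regressor="tlvc")
        return cov, X, c

    def test_constant_data_gives_all_p_one(self, template, rng):
        _, X, c = self._setup(template, rng)
        maps = np.ones((16,) + template.edge_mask.shape)
        res = permutation_fwe(maps, X, c, template, n_perm=120, seed=1)
        assert np.all(res.fwe_p_map[template.edge_mask] == 1.0)

    def test_same_seed_reproduces_p_map(self, template, rng):
        _, X, c = self._setup(template, rng)
        maps = rng.normal(size=(16,) + template.edge_mask.shape)
        r1 = permutation_fwe(maps, X, c, template, n_perm=150, seed=9)
        r2 = permutation_fwe(maps, X, c, template, n_perm=150, seed=9)
        assert np.array_equal(r1.fwe_p_map, r2.fwe_p_map)

    def test_strong_association_detected(self, template, rng):
        cov, X, c = self._setup(template, rng, n=24)
        signal = template.edge_mask.astype(float)
        x = (cov["tlvc"] - cov["tlvc"].mean()).to_numpy()
        maps = (
            0.8 * x[:, None, None, None] * signal[None]
            + rng.normal(0, 0.5, (24,) + template.edge_mask.shape)
        )
        res = permutation_fwe(maps, X, c, template, n_perm=200, seed=3)
        assert (res.fwe_p_map[template.edge_mask] < 0.05).mean() > 0.5

    def test_too_few_rows_rejected(self, template, rng):
        _, X, c = self._setup(template, rng, n=16)
        with pytest.raises(ValueError, match="small"):
            permutation_fwe(
                np.zeros((6,) + template.edge_mask.shape), X[:6], c, template,
                n_perm=100, seed=0,
            )

    def test_too_few_permutations_rejected(self, template, rng):
        _, X, c = self._setup(template, rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fwe(
                np.zeros((16,) + template.edge_mask.shape), X, c, template,
                n_perm=50, seed=0,
            )


class TestRegionReport:
    def _sig_maps(self, template, n_sig, region="periventricular", beta=0.02):
        p = np.ones(template.edge_mask.shape)
        b = np.zeros_like(p)
        vox = np.argwhere(template.atlas[region] & template.edge_mask)[:n_sig]
        for v in vox:
            p[tuple(v)] = 0.01
            b[tuple(v)] = beta
        return p, b

    def test_below_minimum_voxels_empty(self, template):
        p, b = self._sig_maps(template, 14)
        rep = summarize_regions(p, b, template)
        assert rep.empty

    def test_pv_cluster_reported_with_direction(self, template):
        p, b = self._sig_maps(template, 20, beta=0.02)
        rep = summarize_regions(p, b, template)
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row["n_voxels"] == 20
        assert "PV" in row["location"]
        assert row["relationship"] == "Faster Atrophy/Lower TLVC"
        p2, b2 = self._sig_maps(template, 20, beta=-0.02)
        assert (
            summarize_regions(p2, b2, template).iloc[0]["relationship"]
            == "Faster Atrophy/Higher TLVC"
        )

    def test_alpha_one_reports_all_edge_voxels(self, template, rng):
        p = rng.uniform(size=template.edge_mask.shape)
        b = rng.normal(size=template.edge_mask.shape)
        rep = summarize_regions(p, b, template, alpha=1.0 + 1e-9)
        assert rep.iloc[0]["n_voxels"] == int(template.edge_mask.sum())

    def test_invariant_under_monotone_p_transform(self, template, rng):
        p = rng.uniform(size=template.edge_mask.shape)
        b = rng.normal(size=template.edge_mask.shape)
        rep1 = summarize_regions(p, b, template, alpha=0.3)
        rep2 = summarize_regions(p**3, b, template, alpha=0.3**3)
        if rep1.empty:
            assert rep2.empty
        else:
            assert rep1.iloc[0]["n_voxels"] == rep2.iloc[0]["n_voxels"]
            assert rep1.iloc[0]["mean_beta"] == pytest.approx(rep2.iloc[0]["mean_beta"])
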