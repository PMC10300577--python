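"""Template-space displacement maps and mass-univariate permutation inference.

The voxel-wise analysis asks, at every brain-edge voxel, whether the local
edge displacement (negative = faster atrophy) varies with each subject's
total lesion volume change over the same interval.  The chain is:

1. build a study-specific template by averaging percentile-normalised T1
   volumes of subjects selected across the normalised-brain-volume
   distribution;
2. dilate each subject's edge displacement map, mask it with the template
   brain-edge image, smooth with an isotropic Gaussian (sigma 5 mm) and
   re-mask — giving the per-subject dependent variable;
3. fit a voxel-wise GLM (age, sex, site covariates), enhance the t-map with
   threshold-free cluster enhancement (TFCE, E = 0.5, H = 2, 26-connectivity)
   and obtain family-wise-error corrected p-values from the permutation
   distribution of the maximum enhanced statistic (Freedman-Lane scheme);
4. report clusters of at least 15 significant voxels (p < 0.05) with their
   atlas location, peak, and mean regression coefficient.

TFCE is computed by an incremental union-find sweep over descending
thresholds (exact for the discrete threshold grid), compiled with numba so
that full permutation runs stay cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage as ndi

from .preprocess import normalize_percentile

log = logging.getLogger(__name__)

ATLAS_REGIONS = (
    "infratentorial", "periventricular", "frontal", "occipital", "parietal",
    "temporal",
)
REGION_ABBREV = {
    "infratentorial": "INF", "periventricular": "PV", "frontal": "FL",
    "occipital": "OL", "parietal": "PL", "temporal": "TL",
}


# ---------------------------------------------------------------------------
# template space


@dataclass
class TemplateSpace:
    """Common analysis grid: template image, brain-edge mask, geometric atlas."""

    template_img: np.ndarray | None
    brain_mask: np.ndarray
    edge_mask: np.ndarray
    atlas: dict  # region name -> bool mask
    spacing: tuple[float, float, float]

    def __post_init__(self):
        regs = list(self.atlas.values())
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                overlap = a & b & self.edge_mask
                if overlap.any():
                    raise ValueError("atlas regions overlap within the edge mask")


def select_template_subjects(nbv_values: dict, k: int) -> list:
    """Pick ``k`` subjects spread across the normalised-brain-volume range.

    ``nbv_values`` maps subject id -> NBV.  Subjects are chosen nearest to
    ``k`` equally spaced percentiles of the NBV distribution (1st..100th),
    without replacement, deterministically (ties broken by subject id).
    """
    ids = sorted(nbv_values)
    if k > len(ids):
        raise ValueError(f"cannot select {k} subjects from {len(ids)}")
    vals = np.array([nbv_values[i] for i in ids], dtype=np.float64)
    if k == 1:
        pct = np.array([50.5])
    else:
        pct = np.linspace(1, 100, k)
    targets = np.percentile(vals, np.clip(pct, 0, 100))
    chosen: list = []
    free = set(range(len(ids)))
    for t in targets:
        best = min(free, key=lambda j: (abs(vals[j] - t), ids[j]))
        chosen.append(ids[best])
        free.remove(best)
    return chosen


def build_template(volumes: dict, nbv_values: dict, k: int) -> np.ndarray:
    """Average the percentile-normalised volumes of the selected subjects."""
    sel = select_template_subjects(nbv_values, k)
    shapes = {volumes[s].shape for s in sel}
    if len(shapes) != 1:
        raise ValueError("template volumes must share a common grid")
    acc = np.zeros(volumes[sel[0]].shape, dtype=np.float64)
    for s in sel:
        acc += normalize_percentile(volumes[s])
    return acc / len(sel)


def make_template_space(
    brain_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    spacing: tuple[float, float, float],
    template_img: np.ndarray | None = None,
    edge_halo_vox: int = 2,
    pv_dist_mm: float = 8.0,
) -> TemplateSpace:
    """Geometric template space for phantom cohorts on a shared grid.

    The brain-edge mask is the union of the outer brain boundary and the
    ventricular boundary, dilated by ``edge_halo_vox`` to tolerate
    inter-subject boundary jitter.  The atlas partitions the brain into six
    disjoint geometric regions mirroring the standard anatomical split:
    periventricular (within ``pv_dist_mm`` of the ventricles), infratentorial
    (lowest fifth of the brain's z extent), and frontal / occipital /
    parietal / temporal by anterior-posterior and superior-inferior position.
    """
    brain = np.asarray(brain_mask, bool)
    vent = np.asarray(ventricle_mask, bool)
    b_edge = brain & ~ndi.binary_erosion(brain)
    v_edge = vent & ~ndi.binary_erosion(vent)
    edge = b_edge | v_edge
    if edge_halo_vox > 0:
        edge = ndi.binary_dilation(edge, iterations=edge_halo_vox)
    edge &= ndi.binary_dilation(brain, iterations=edge_halo_vox)

    sp = np.asarray(spacing, dtype=np.float64)
    dist_vent = ndi.distance_transform_edt(~vent, sampling=sp)
    pv = brain & (dist_vent <= pv_dist_mm)
    idx = np.argwhere(brain)
    z_mm = idx[:, 2] * sp[2]
    z_lo, z_hi = z_mm.min(), z_mm.max()
    z_inf = z_lo + 0.2 * (z_hi - z_lo)
    zvol = np.arange(brain.shape[2])[None, None, :] * sp[2] * np.ones(brain.shape)
    yvol = np.arange(brain.shape[1])[None, :, None] * sp[1] * np.ones(brain.shape)
    inf = brain & (zvol <= z_inf) & ~pv
    rem = brain & ~pv & ~inf
    y_mm = idx[:, 1] * sp[1]
    y_c, y_ext = y_mm.mean(), y_mm.max() - y_mm.min()
    frontal = rem & (yvol >= y_c + 0.18 * y_ext)
    occipital = rem & (yvol <= y_c - 0.18 * y_ext)
    mid = rem & ~frontal & ~occipital
    z_c = z_mm.mean()
    parietal = mid & (zvol > z_c)
    temporal = mid & (zvol <= z_c)
    atlas = {
        "infratentorial": inf, "periventricular": pv, "frontal": frontal,
        "occipital": occipital, "parietal": parietal, "temporal": temporal,
    }
    return TemplateSpace(
        template_img=template_img, brain_mask=brain, edge_mask=edge,
        atlas=atlas, spacing=tuple(spacing),
    )


# ---------------------------------------------------------------------------
# displacement map preparation


@dataclass
class SmoothedDisplacementMap:
    data: np.ndarray
    sigma_mm: float

    def __post_init__(self):
        assert np.isfinite(self.data).all()


def prepare_displacement_map(
    disp_map: np.ndarray,
    template: TemplateSpace,
    dilate_vox: int = 2,
    sigma_mm: float = 5.0,
) -> SmoothedDisplacementMap:
    """Dilate, edge-mask, Gaussian-smooth and re-mask one displacement map.

    Dilation is value-propagating with a max-magnitude rule: a zero voxel
    takes the neighbouring value of largest absolute magnitude within the
    cubic footprint (ties resolved towards the positive value); non-zero
    voxels keep their own value.  Smoothing uses a per-axis sigma of
    ``sigma_mm`` converted to voxels.  Output is exactly zero outside the
    template edge mask.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    v = np.asarray(disp_map, dtype=np.float64)
    if dilate_vox > 0:
        size = 2 * dilate_vox + 1
        d_pos = ndi.grey_dilation(np.maximum(v, 0.0), size=size)
        d_neg = ndi.grey_dilation(np.maximum(-v, 0.0), size=size)
        dil = np.where(d_pos >= d_neg, d_pos, -d_neg)
        v = np.where(v != 0.0, v, dil)
    v = np.where(template.edge_mask, v, 0.0)
    sig_vox = sigma_mm / np.asarray(template.spacing, dtype=np.float64)
    v = ndi.gaussian_filter(v, sig_vox, mode="constant")
    v = np.where(template.edge_mask, v, 0.0)
    return SmoothedDisplacementMap(data=v, sigma_mm=sigma_mm)


# ---------------------------------------------------------------------------
# design matrices and GLM


def build_design(
    covariates: pd.DataFrame,
    regressor: str = "true_tlvc_ml",
    interaction: str | None = None,
    demean: bool = True,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Design matrix with site indicators, age, sex and the TLVC regressor.

    Site is cell-means coded: one indicator per site and no separate
    intercept column (the indicators sum to the intercept).  With
    ``interaction`` (a two-level column such as ``treatment``), the regressor
    enters as two group-specific slope columns plus a group main effect, and
    the returned contrast tests the slope difference; otherwise the contrast
    picks the single regressor column.

    Returns ``(X, contrast, column_names)``.
    """
    df = covariates.reset_index(drop=True)
    cols, names = [], []
    sites = sorted(df["site"].unique())
    for s in sites:
        cols.append((df["site"] == s).astype(float).to_numpy())
        names.append(f"site[{s}]")
    age = df["age"].to_numpy(dtype=float)
    cols.append(age - age.mean() if demean else age)
    names.append("age")
    cols.append(df["sex"].to_numpy(dtype=float))
    names.append("sex")
    x = df[regressor].to_numpy(dtype=float)
    if demean:
        x = x - x.mean()
    if interaction is None:
        cols.append(x)
        names.append(regressor)
        contrast = np.zeros(len(cols))
        contrast[-1] = 1.0
    else:
        levels = sorted(df[interaction].unique())
        if len(levels) != 2:
            raise ValueError(
                f"interaction column {interaction!r} must have exactly 2 levels, "
                f"got {levels}"
            )
        g = (df[interaction] == levels[1]).to_numpy(dtype=float)
        cols.append(g)
        names.append(f"{interaction}[{levels[1]}]")
        cols.append(x * (1 - g))
        names.append(f"{regressor}:{interaction}[{levels[0]}]")
        cols.append(x * g)
        names.append(f"{regressor}:{interaction}[{levels[1]}]")
        contrast = np.zeros(len(cols))
        contrast[-2], contrast[-1] = 1.0, -1.0
    X = np.column_stack(cols)
    _check_rank(X, names)
    return X, contrast, names


def _check_rank(X: np.ndarray, names: list):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify a culprit column by leave-one-out rank
        for j in range(X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == r:
                raise ValueError(
                    f"rank-deficient design: column {names[j]!r} is collinear"
                )
        raise ValueError("rank-deficient design matrix")


def glm_fit(
    maps: np.ndarray, design: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise OLS: returns (contrast beta map, t map) over map columns.

    ``maps`` is (n_observations, n_voxels).  Voxels with zero residual
    variance get t = 0.
    """
    Y = np.asarray(maps, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    c = np.asarray(contrast, dtype=np.float64)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("maps/design row mismatch")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} columns")
    _check_rank(X, [f"col{j}" for j in range(p)])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    cb = c @ beta
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    k = float(c @ xtx_inv @ c)
    denom = np.sqrt(np.maximum(k * sigma2, 0.0))
    # zero residual variance: t is 0 for a zero effect, +/-inf-like for an
    # exact fit (capped so downstream enhancement stays finite)
    scale = max(float(np.abs(cb).max(initial=0.0)), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            denom > 1e-12 * scale,
            cb / np.maximum(denom, 1e-300),
            np.where(np.abs(cb) > 1e-12 * scale, np.sign(cb) * 1e9, 0.0),
        )
    return cb, t


# ---------------------------------------------------------------------------
# TFCE


def mask_adjacency(mask: np.ndarray, connectivity: int = 26):
    """CSR neighbour lists between in-mask voxels (6/18/26-connectivity)."""
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    lab = -np.ones(mask.shape, dtype=np.int64)
    lab[mask] = np.arange(n)
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append(d)
    pairs_src, pairs_dst = [], []
    idx = np.argwhere(mask)
    shape = np.array(mask.shape)
    for d in offsets:
        nb = idx + np.array(d)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = lab[tuple(idx[ok].T)]
        dst = lab[tuple(nb[ok].T)]
        keep = dst >= 0
        pairs_src.append(src[keep])
        pairs_dst.append(dst[keep])
    src = np.concatenate(pairs_src) if pairs_src else np.empty(0, np.int64)
    dst = np.concatenate(pairs_dst) if pairs_dst else np.empty(0, np.int64)
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr[1:], src, 1)
    indptr = np.cumsum(indptr)
    return indptr, dst.astype(np.int64)


@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        parent[i], i = root, parent[i]
    return root


@njit(cache=True)
def _tfce_core(vals, indptr, indices, E, H, dh, n_steps):
    """TFCE of non-negative ``vals`` on the mask graph.

    Sweeps thresholds from high to low, growing connected components with a
    union-find; at each threshold every supra-threshold voxel accrues
    ``extent^E * h^H * dh`` of its current component.  Exact for the discrete
    threshold grid h = dh, 2dh, ..., <= max(vals).
    """
    n = vals.size
    out = np.zeros(n)
    hmax = 0.0
    for i in range(n):
        if vals[i] > hmax:
            hmax = vals[i]
    if hmax <= 0.0:
        return out
    if dh <= 0.0:
        dh = hmax / n_steps
    k_top = int(np.floor(hmax / dh + 1e-12))
    if k_top < 1:
        return out
    order = np.argsort(-vals)
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    ptr = 0
    for k in range(k_top, 0, -1):
        h = k * dh
        while ptr < n and vals[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            for jj in range(indptr[v], indptr[v + 1]):
                nb = indices[jj]
                if parent[nb] != -1:
                    ra = _uf_find(parent, v)
                    rb = _uf_find(parent, nb)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            ptr += 1
        hh = h**H * dh
        for j in range(ptr):
            v = order[j]
            r = _uf_find(parent, v)
            out[v] += size[r] ** E * hh
    return out


def tfce_enhance(
    stat_map: np.ndarray,
    mask: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
    connectivity: int = 26,
    adjacency=None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    Positive and negative tails are enhanced separately (the negative tail by
    enhancing ``-map`` and negating).  ``dh`` fixes the threshold step; when
    ``None`` each tail uses ``max/n_steps``.  Pass a precomputed
    ``mask_adjacency`` result to amortise graph construction.
    """
    mask = np.asarray(mask, bool)
    if adjacency is None:
        adjacency = mask_adjacency(mask, connectivity)
    indptr, indices = adjacency
    vals = np.asarray(stat_map, dtype=np.float64)[mask]
    out = np.zeros(mask.shape)
    dh_eff = 0.0 if dh is None else float(dh)
    pos = np.maximum(vals, 0.0)
    neg = np.maximum(-vals, 0.0)
    enh = _tfce_core(pos, indptr, indices, E, H, dh_eff, n_steps) - _tfce_core(
        neg, indptr, indices, E, H, dh_eff, n_steps
    )
    out[mask] = enh
    return out


# ---------------------------------------------------------------------------
# permutation FWE


@dataclass
class VoxelwiseResult:
    beta_map: np.ndarray
    t_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p_map: np.ndarray  # 1 outside mask
    perm_max: np.ndarray
    mask: np.ndarray


def permutation_fwe(
    maps: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    template: TemplateSpace,
    n_perm: int = 5000,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 50,
    connectivity: int = 26,
    two_sided: bool = False,
) -> VoxelwiseResult:
    """FWE-corrected voxel-wise inference by Freedman-Lane permutation.

    ``maps`` is a stack (n_observations, *grid) of smoothed displacement
    maps.  The reduced model (contrast-free columns) is fitted, its residuals
    are permuted and added back to the reduced fit, the full model is refit,
    and the maximum TFCE-enhanced t-statistic of each permutation forms the
    null distribution:  p(v) = (1 + #{perm max >= observed}) / (n_perm + 1).
    By default one-sided in the direction of the contrast (flip the contrast
    for the other tail); with ``two_sided=True`` the maximum is taken over
    both enhanced tails and compared against |observed|.  Deterministic for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(design, dtype=np.float64)
    c = np.asarray(contrast, dtype=np.float64)
    n = X.shape[0]
    if n < 8:
        raise ValueError("permutation space too small: need >= 8 observations")
    mask = template.edge_mask
    Y = np.asarray(maps, dtype=np.float64).reshape(n, -1)[:, mask.ravel()]
    adjacency = mask_adjacency(mask, connectivity)

    cb, t_obs = glm_fit(Y, X, c)
    indptr, indices = adjacency
    enh_obs = _signed_tfce(t_obs, indptr, indices, E, H, n_steps)

    # Freedman-Lane: reduced model = columns not involved in the contrast
    red = np.abs(c) < 1e-12
    Z = X[:, red]
    if Z.size:
        Rz = np.eye(n) - Z @ np.linalg.pinv(Z)
    else:
        Rz = np.eye(n)
    E_res = Rz @ Y
    F_fit = Y - E_res
    rng = np.random.default_rng(seed)
    xtx_inv = np.linalg.inv(X.T @ X)
    P = X @ xtx_inv @ X.T
    w = X @ xtx_inv @ c
    k = float(c @ xtx_inv @ c)
    df = n - X.shape[1]
    maxima = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(n)
        Yp = E_res[perm] + F_fit
        numer = w @ Yp
        resid = Yp - P @ Yp
        sigma2 = (resid * resid).sum(axis=0) / df
        denom = np.sqrt(np.maximum(k * sigma2, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            tp = np.where(denom > 1e-12, numer / denom, 0.0)
        enh = _tfce_core(
            np.maximum(tp, 0.0), indptr, indices, E, H, 0.0, n_steps
        )
        if two_sided:
            enh_n = _tfce_core(
                np.maximum(-tp, 0.0), indptr, indices, E, H, 0.0, n_steps
            )
            maxima[j] = max(
                enh.max() if enh.size else 0.0, enh_n.max() if enh_n.size else 0.0
            )
        else:
            maxima[j] = enh.max() if enh.size else 0.0
    sorted_max = np.sort(maxima)
    # p(v) = (1 + #{perm max >= enh_obs(v)}) / (n_perm + 1)
    obs_stat = np.abs(enh_obs) if two_sided else enh_obs
    n_ge = n_perm - np.searchsorted(sorted_max, obs_stat, side="left")
    p_vals = (1.0 + n_ge) / (n_perm + 1.0)

    out_shape = mask.shape
    beta_map = _unmask(cb, mask)
    t_map = _unmask(t_obs, mask)
    tfce_map = _unmask(enh_obs, mask)
    p_map = np.ones(out_shape)
    p_map[mask] = p_vals
    return VoxelwiseResult(
        beta_map=beta_map, t_map=t_map, tfce_map=tfce_map, fwe_p_map=p_map,
        perm_max=maxima, mask=mask,
    )


def _signed_tfce(t_vals, indptr, indices, E, H, n_steps):
    return _tfce_core(
        np.maximum(t_vals, 0.0), indptr, indices, E, H, 0.0, n_steps
    ) - _tfce_core(np.maximum(-t_vals, 0.0), indptr, indices, E, H, 0.0, n_steps)


def _unmask(vals, mask):
    out = np.zeros(mask.shape)
    out[mask] = vals
    return out


# ---------------------------------------------------------------------------
# region report


def summarize_regions(
    fwe_p_map: np.ndarray,
    beta_map: np.ndarray,
    template: TemplateSpace,
    alpha: float = 0.05,
    min_voxels: int = 15,
    tfce_map: np.ndarray | None = None,
    interval: str = "",
    label_frac: float = 0.10,
) -> pd.DataFrame:
    """Cluster-report of significant voxels, mirroring the trial's tables.

    Empty when fewer than ``min_voxels`` voxels reach ``p < alpha``.
    Otherwise one row with: significant-voxel count V, the atlas regions
    holding at least ``label_frac`` of the significant voxels, the peak
    coordinate (minimum p, ties by maximum |TFCE|), the mean regression
    coefficient over significant voxels, and the direction reading
    (beta > 0: faster atrophy with lower TLVC; beta < 0: faster atrophy with
    higher TLVC).
    """
    sig = (fwe_p_map < alpha) & template.edge_mask
    cols = [
        "interval", "n_voxels", "location", "peak_voxel", "mean_beta",
        "relationship",
    ]
    if sig.sum() < min_voxels:
        return pd.DataFrame(columns=cols)
    v = int(sig.sum())
    labels = []
    for name in ATLAS_REGIONS:
        frac = (sig & template.atlas[name]).sum() / v
        if frac >= label_frac:
            labels.append(REGION_ABBREV[name])
    idx = np.argwhere(sig)
    pvals = fwe_p_map[sig]
    if tfce_map is not None:
        tf = np.abs(tfce_map[sig])
        order = np.lexsort((-tf, pvals))
    else:
        order = np.argsort(pvals, kind="stable")
    peak = tuple(int(x) for x in idx[order[0]])
    mean_beta = float(beta_map[sig].mean())
    relationship = (
        "Faster Atrophy/Lower TLVC" if mean_beta > 0 else "Faster Atrophy/Higher TLVC"
    )
    return pd.DataFrame(
        [[interval, v, "/".join(labels), peak, mean_beta, relationship]],
        columns=cols,
    )
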