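"""Intensity conditioning for 2-D multi-slice acquisitions.

Covers the steps applied before subtraction/atrophy analysis: per-slice gain
correction for interleaved acquisitions, 99th-percentile intensity
normalisation, lesion filling on the T1-like channel, and low-order
multiplicative bias flattening.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

SLICE_AXIS = 2  # slice-select axis of the 2-D acquisition (slowest, 3 mm)


def correct_slice_intensity(
    vol: np.ndarray, brain_mask: np.ndarray, min_voxels: int = 50
) -> np.ndarray:
    """Remove slice-to-slice multiplicative gain variation.

    Each slice along the slice axis is rescaled so that its in-mask median
    equals the volume-wide median of slice medians.  Slices with fewer than
    ``min_voxels`` in-mask voxels get a gain interpolated from neighbouring
    valid slices (the whole slice, background included, is scaled).
    """
    vol = np.asarray(vol, dtype=np.float64)
    n_slices = vol.shape[SLICE_AXIS]
    medians = np.full(n_slices, np.nan)
    for k in range(n_slices):
        sl_mask = np.take(brain_mask, k, axis=SLICE_AXIS)
        if sl_mask.sum() >= min_voxels:
            medians[k] = np.median(np.take(vol, k, axis=SLICE_AXIS)[sl_mask])
    valid = np.isfinite(medians) & (medians > 0)
    if not np.any(valid):
        # nothing to anchor the correction on: return unchanged
        log.warning("slice correction skipped: no slice has enough in-mask voxels")
        return vol.copy()
    target = np.median(medians[valid])
    gains = np.ones(n_slices)
    gains[valid] = target / medians[valid]
    if np.any(~valid):
        idx = np.arange(n_slices)
        gains[~valid] = np.interp(idx[~valid], idx[valid], gains[valid])
        log.info(
            "interpolated slice gains for %d slice(s) with < %d in-mask voxels",
            int(np.sum(~valid)), min_voxels,
        )
    shape = [1, 1, 1]
    shape[SLICE_AXIS] = n_slices
    return vol * gains.reshape(shape)


def normalize_percentile(vol: np.ndarray, target: float = 10000.0) -> np.ndarray:
    """Divide by the 99th percentile of the non-zero voxels, times ``target``.

    Scale-invariant: ``normalize_percentile(k * vol) == normalize_percentile(vol)``
    for any k > 0.
    """
    vol = np.asarray(vol, dtype=np.float64)
    nz = vol[vol != 0]
    if nz.size == 0:
        raise ValueError("cannot percentile-normalise an all-zero volume")
    p99 = np.percentile(nz, 99)
    if p99 <= 0:
        raise ValueError("99th percentile of non-zero voxels is not positive")
    return vol / p99 * target


def fill_lesions(
    t1_vol: np.ndarray,
    lesion_mask: np.ndarray,
    brain_mask: np.ndarray,
    radius_vox: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Replace lesion voxels with locally matched normal-appearing tissue.

    Each lesion voxel receives the mean of non-lesional brain intensity within
    a cubic neighbourhood of half-width ``radius_vox`` (falling back to the
    global non-lesional mean where the neighbourhood is empty), plus Gaussian
    noise matched to the local non-lesional SD, so filled areas do not create
    artificially flat patches that would bias edge finding.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if np.any(lesion_mask & ~brain_mask):
        raise ValueError("lesion mask must be contained in the brain mask")
    n_brain = brain_mask.sum()
    if n_brain == 0 or lesion_mask.sum() > 0.5 * n_brain:
        raise ValueError("lesion mask covers more than half the brain: implausible")
    out = np.asarray(t1_vol, dtype=np.float64).copy()
    if not lesion_mask.any():
        return out
    normal = brain_mask & ~lesion_mask
    size = 2 * radius_vox + 1
    w = normal.astype(np.float64)
    local_n = ndi.uniform_filter(w, size=size) * size**3
    local_sum = ndi.uniform_filter(out * w, size=size) * size**3
    local_sq = ndi.uniform_filter(out**2 * w, size=size) * size**3
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = local_sum / local_n
        local_var = np.maximum(local_sq / local_n - local_mean**2, 0.0)
    gmean = out[normal].mean()
    gsd = out[normal].std()
    les = lesion_mask
    mean_f = np.where(local_n[les] >= 8, local_mean[les], gmean)
    sd_f = np.where(local_n[les] >= 8, np.sqrt(local_var[les]), gsd)
    rng = np.random.default_rng(seed)
    out[les] = mean_f + rng.normal(0.0, 1.0, size=mean_f.shape) * sd_f
    return out


def flatten_bias(
    vol: np.ndarray, brain_mask: np.ndarray, order: int = 2
) -> np.ndarray:
    """Remove smooth multiplicative bias by a log-domain polynomial fit.

    A polynomial of the given ``order`` (0-3) in the voxel coordinates is
    least-squares fitted to log-intensity over the mask and divided out; the
    in-mask mean intensity is preserved.  Non-positive in-mask values are
    shifted above zero before the log (logged).
    """
    if order not in (0, 1, 2, 3):
        raise ValueError("order must be one of 0, 1, 2, 3")
    vol = np.asarray(vol, dtype=np.float64)
    mask = np.asarray(brain_mask, dtype=bool)
    vals = vol[mask]
    shift = 0.0
    if np.min(vals) <= 0:
        shift = -np.min(vals) + 1e-3 * max(np.ptp(vals), 1.0)
        log.info("flatten_bias: shifted intensities by %.3g before log", shift)
    logv = np.log(vals + shift)
    coords = np.argwhere(mask).astype(np.float64)
    coords = (coords - coords.mean(axis=0)) / np.maximum(coords.std(axis=0), 1.0)
    X = _poly_design(coords, order)
    beta, *_ = np.linalg.lstsq(X, logv, rcond=None)
    fit = X @ beta
    corrected = np.exp(logv - fit) - 0.0
    # rescale to preserve the in-mask mean, then undo the shift
    corrected *= (vals + shift).mean() / corrected.mean()
    out = vol.copy()
    out[mask] = corrected - shift
    return out


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones(len(coords))]
    if order >= 1:
        cols += [coords[:, i] for i in range(3)]
    if order >= 2:
        cols += [coords[:, i] * coords[:, j] for i in range(3) for j in range(i, 3)]
    if order >= 3:
        cols += [
            coords[:, i] * coords[:, j] * coords[:, k]
            for i in range(3) for j in range(i, 3) for k in range(j, 3)
        ]
    return np.column_stack(cols)
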