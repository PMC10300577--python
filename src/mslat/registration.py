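"""Rigid registration and halfway-space resampling of visit pairs.

Longitudinal change is measured in a *halfway space*: the full rigid
transform between the two visits is split into its matrix square root, and
each image is resampled with half of the motion, so both visits suffer the
same amount of interpolation blur and neither is privileged as "the"
reference.  This mirrors the symmetric registration strategy of longitudinal
edge-displacement pipelines.

Conventions
-----------
* A :class:`RigidTransform` maps world (mm) points ``x -> R (x - c) + c + t``.
* ``estimate_rigid(moving, fixed)`` returns ``T`` mapping fixed-world points
  into moving-world points, i.e. the pull-back transform used directly by
  :func:`resample` so that ``resample(moving, T, ...)`` aligns with ``fixed``.
* Images are resampled trilinearly, masks with nearest neighbour; voxels
  sampled outside the field of view are 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

log = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """6-DOF rigid world transform: rotation about ``centre`` plus translation."""

    rotation: tuple[float, float, float]  # xyz Euler angles, radians
    translation: tuple[float, float, float]  # mm
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self):
        if not np.all(np.isfinite(self.rotation + self.translation + self.centre)):
            raise ValueError("non-finite rigid parameters")

    # ---- matrix form ------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        R = Rotation.from_euler("xyz", self.rotation).as_matrix()
        c = np.asarray(self.centre)
        t = np.asarray(self.translation)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        R = Rotation.from_matrix(M[:3, :3])
        return cls(
            rotation=tuple(R.as_euler("xyz")),
            translation=tuple(M[:3, 3]),
            centre=(0.0, 0.0, 0.0),
        )

    # ---- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of world points."""
        M = self.as_matrix()
        return points @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "RigidTransform":
        M = self.as_matrix()
        Mi = np.eye(4)
        Mi[:3, :3] = M[:3, :3].T
        Mi[:3, 3] = -M[:3, :3].T @ M[:3, 3]
        return RigidTransform.from_matrix(Mi)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.as_matrix() @ other.as_matrix())

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    def save(self, path) -> None:
        np.savetxt(path, self.as_matrix(), fmt="%.12g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


def split_halfway(T: RigidTransform) -> tuple[RigidTransform, RigidTransform]:
    """Split ``T`` into its inverse and forward matrix square roots.

    Returns ``(T_a, T_b) = (T^(-1/2), T^(1/2))`` with ``T_b o T_a^(-1) = T``:
    resampling visit a with ``T_a`` and visit b with ``T_b`` places both in
    the common halfway frame with equal interpolation.  The rotation is
    halved about its screw axis (rotation-vector halving); the translation
    half solves ``(I + R_half) t_half = t`` so the half composes exactly.
    """
    M = T.as_matrix()
    rot = Rotation.from_matrix(M[:3, :3])
    half = Rotation.from_rotvec(rot.as_rotvec() / 2.0)
    Rh = half.as_matrix()
    # (I + Rh) is singular only for a 180-degree half (i.e. 360 total): not rigidly
    # reachable here.
    th = np.linalg.solve(np.eye(3) + Rh, M[:3, 3])
    Mh = np.eye(4)
    Mh[:3, :3] = Rh
    Mh[:3, 3] = th
    T_b = RigidTransform.from_matrix(Mh)
    T_a = T_b.inverse()
    return T_a, T_b


# ---------------------------------------------------------------------------
# resampling


def resample(
    vol: np.ndarray,
    T: RigidTransform,
    spacing: tuple[float, float, float],
    interp: str = "trilinear",
    out_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Pull-back resample ``vol`` through ``T`` onto a same-spacing grid.

    The output voxel at index ``i`` takes the input value at world point
    ``T(i * spacing)``.  ``interp`` is ``trilinear`` or ``nearest``; out-of-
    field voxels are 0.  Boolean inputs are resampled nearest and returned
    boolean.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError("interp must be 'trilinear' or 'nearest'")
    was_bool = vol.dtype == bool
    if was_bool:
        interp = "nearest"
    out_shape = out_shape or vol.shape
    sp = np.asarray(spacing, dtype=np.float64)
    idx = np.indices(out_shape, dtype=np.float64).reshape(3, -1).T
    world = idx * sp
    src = T.apply(world) / sp  # input voxel coordinates
    order = 1 if interp == "trilinear" else 0
    out = ndi.map_coordinates(
        vol.astype(np.float64), src.T, order=order, mode="constant", cval=0.0
    ).reshape(out_shape)
    return out > 0.5 if was_bool else out


# ---------------------------------------------------------------------------
# similarity + optimisation


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def masked_ncc(
    moving: np.ndarray,
    fixed: np.ndarray,
    T: RigidTransform,
    spacing,
    points_vox: np.ndarray,
) -> float:
    """NCC between fixed values at mask points and moving values at T(points)."""
    sp = np.asarray(spacing, dtype=np.float64)
    world = points_vox * sp
    src = T.apply(world) / sp
    mov_vals = ndi.map_coordinates(moving, src.T, order=1, mode="constant", cval=0.0)
    fix_vals = fixed[tuple(points_vox.astype(int).T)]
    return _ncc(mov_vals, fix_vals)


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    init: RigidTransform | None = None,
    max_points: int = 20000,
) -> RigidTransform:
    """Estimate the 6-DOF transform maximising masked NCC.

    Multi-resolution local optimisation (Powell) over rotation angles and
    translations, rotating about the mask centroid.  Raises if the optimiser
    fails to at least match the initial similarity.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty registration mask")
    sp = np.asarray(spacing, dtype=np.float64)
    pts_all = np.argwhere(mask).astype(np.float64)
    centre = tuple(pts_all.mean(axis=0) * sp)
    p0 = np.zeros(6)
    if init is not None:
        p0[:3] = init.rotation
        p0[3:] = init.translation

    def make_cost(mov_img, fix_img, pts):
        def cost(p):
            T = RigidTransform(tuple(p[:3]), tuple(p[3:]), centre)
            return -masked_ncc(mov_img, fix_img, T, sp, pts)

        return cost

    rng = np.random.default_rng(0)
    # both levels pre-smooth: matching a crisp image against its own
    # resampled (blurred) copy otherwise favours interpolation-free integer
    # shifts over the true pose
    levels = [
        (ndi.gaussian_filter(moving, 2.5), ndi.gaussian_filter(fixed, 2.5), 4),
        (ndi.gaussian_filter(moving, 1.5), ndi.gaussian_filter(fixed, 1.5), 1),
    ]
    p = p0.copy()
    for mov_img, fix_img, stride in levels:
        pts = pts_all[::stride]
        if len(pts) > max_points:
            pts = pts[rng.choice(len(pts), max_points, replace=False)]
        cost = make_cost(mov_img, fix_img, pts)
        direc = np.diag([0.01, 0.01, 0.01, 1.0, 1.0, 1.0])
        res = minimize(
            cost, p, method="Powell",
            options={"direc": direc, "xtol": 1e-4, "ftol": 1e-7, "maxiter": 30},
        )
        p = res.x
    final_T = RigidTransform(tuple(p[:3]), tuple(p[3:]), centre)
    init_T = RigidTransform(tuple(p0[:3]), tuple(p0[3:]), centre)
    mov_f, fix_f, stride = levels[-1]
    pts = pts_all[::stride]
    if len(pts) > max_points:
        pts = pts[rng.choice(len(pts), max_points, replace=False)]
    sim_final = masked_ncc(mov_f, fix_f, final_T, sp, pts)
    sim_init = masked_ncc(mov_f, fix_f, init_T, sp, pts)
    if sim_final + 1e-9 < sim_init:
        raise RuntimeError(
            f"registration failed: similarity decreased {sim_init:.4f} -> {sim_final:.4f}"
        )
    log.info("rigid registration NCC %.4f -> %.4f", sim_init, sim_final)
    return final_T


# ---------------------------------------------------------------------------
# halfway pairs


@dataclass
class HalfwayPair:
    """Two visits resampled into their common halfway frame."""

    image_a_hw: np.ndarray
    image_b_hw: np.ndarray
    mask_hw: np.ndarray
    transforms: tuple[RigidTransform, RigidTransform]
    spacing: tuple[float, float, float]
    extras_a: dict | None = None  # additional channels/masks, resampled like a
    extras_b: dict | None = None


def make_halfway_pair(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing: tuple[float, float, float],
    register: bool = True,
    extras_a: dict | None = None,
    extras_b: dict | None = None,
) -> HalfwayPair:
    """Register b to a (optionally) and resample both into halfway space.

    ``extras_*`` are additional volumes tied to each visit (e.g. lesion masks,
    the T1 channel) resampled with the same half-transform; boolean arrays go
    nearest-neighbour.  With ``register=False`` the full transform is taken as
    identity (visits already on a shared grid), in which case the halfway
    resampling is a no-op rather than an interpolation.
    """
    if register:
        T = estimate_rigid(image_b, image_a, mask_a, spacing)
    else:
        T = RigidTransform.identity()
    T_a, T_b = split_halfway(T)
    is_ident = np.allclose(T.as_matrix(), np.eye(4), atol=1e-12)

    def _res(vol, Th, interp="trilinear"):
        if is_ident:
            return vol.copy()
        return resample(vol, Th, spacing, interp=interp)

    a_hw = _res(np.asarray(image_a, dtype=np.float64), T_a)
    b_hw = _res(np.asarray(image_b, dtype=np.float64), T_b)
    m_hw = _res(np.asarray(mask_a, dtype=bool), T_a) & _res(
        np.asarray(mask_b, dtype=bool), T_b
    )
    ex_a = {k: _res(v, T_a) for k, v in (extras_a or {}).items()}
    ex_b = {k: _res(v, T_b) for k, v in (extras_b or {}).items()}
    return HalfwayPair(
        image_a_hw=a_hw, image_b_hw=b_hw, mask_hw=m_hw,
        transforms=(T_a, T_b), spacing=tuple(spacing),
        extras_a=ex_a, extras_b=ex_b,
    )
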