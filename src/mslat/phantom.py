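"""Synthetic longitudinal brain phantoms with analytic ground truth.

Geometry is deliberately analytic — an ellipsoidal brain with an ellipsoidal
ventricular cavity, a thin cortical (GM) shell, and spherical white-matter
lesions — so that every quantity the pipeline later estimates (lesion event
volumes, TLVC, PBVC, PVVC) has a closed form.  Phantoms mimic 2-D dual-echo
acquisitions: anisotropic voxels (default 1x1x3 mm), a PD-like channel on
which lesions are hyperintense, a T1-like channel used for atrophy, per-slice
multiplicative gain jitter along the slice axis, a smooth multiplicative bias
field, and additive Gaussian noise.

Longitudinal change is applied by re-voxelising transformed geometry rather
than by warping images: the brain boundary is scaled by a factor ``s``
(``s < 1`` = global atrophy), the ventricular boundary is pushed outward, and
lesion events (new / enlarging / shrinking / disappearing) edit the sphere
list.  Because the follow-up is generated from the same analytic shapes, the
ground truth attached to each interval is exact, not itself an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

ML_PER_MM3 = 1e-3

EVENT_KINDS = ("new", "enlarge", "shrink", "disappear")
# reporting categories used downstream
EVENT_CATEGORY = {
    "new": "new",
    "enlarge": "enlarging",
    "shrink": "shrinking",
    "disappear": "disappearing",
}


@dataclass(frozen=True)
class Lesion:
    """A spherical white-matter lesion: centre in mm (grid world coords)."""

    centre_mm: tuple[float, float, float]
    radius_mm: float

    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3


@dataclass(frozen=True)
class PhantomSpec:
    """Static anatomy + acquisition parameters of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 20)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    brain_radii_mm: tuple[float, float, float] = (26.0, 28.0, 24.0)
    ventricle_radii_mm: tuple[float, float, float] = (8.0, 11.0, 7.0)
    gm_thickness_mm: float = 3.0
    # intensity means per channel/tissue; lesions hyperintense on PD
    tissue_means: dict = field(
        default_factory=lambda: {
            "pd": {"wm": 800.0, "gm": 900.0, "csf": 1100.0, "lesion": 1200.0},
            "t1": {"wm": 1000.0, "gm": 800.0, "csf": 300.0, "lesion": 700.0},
        }
    )
    noise_sd: float = 20.0
    slice_gain_sd: float = 0.05
    bias_amplitude: float = 0.05
    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError(
                f"degenerate grid {self.grid_shape}: need >= 16 voxels per axis"
            )
        if self.noise_sd < 0 or self.slice_gain_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd, slice_gain_sd, bias_amplitude must be >= 0")
        rv = np.asarray(self.ventricle_radii_mm)
        rb = np.asarray(self.brain_radii_mm)
        if np.any(rv >= rb):
            raise ValueError("ventricle ellipsoid must lie strictly inside brain")
        tm = self.tissue_means
        if tm["pd"]["lesion"] <= tm["pd"]["wm"]:
            raise ValueError("lesions must be hyperintense to WM on the PD channel")

    # ---- geometry helpers -------------------------------------------------
    @property
    def centre_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.voxel_size_mm)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        return aff

    def brain_volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.brain_radii_mm))

    def ventricle_volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.ventricle_radii_mm))


@dataclass(frozen=True)
class LesionEvent:
    """A requested lesion change.

    ``centre_mm`` identifies the lesion (for ``new`` it is the new centre);
    ``radius_mm`` is the sphere radius for ``new``; ``delta_radius_mm`` the
    radial growth (enlarge) or shrinkage (shrink).
    """

    kind: str
    centre_mm: tuple[float, float, float]
    radius_mm: float = 0.0
    delta_radius_mm: float = 0.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown lesion event kind {self.kind!r}")


@dataclass(frozen=True)
class ChangeSpec:
    """Longitudinal change applied between two visits."""

    brain_scale: float = 1.0
    ventricle_dilate_mm: float = 0.0
    lesion_events: tuple[LesionEvent, ...] = ()
    rigid_offset: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self):
        if not (0.9 < self.brain_scale < 1.1):
            raise ValueError("brain_scale must lie in (0.9, 1.1)")


@dataclass
class GroundTruth:
    """Exact per-interval truth attached by the generator."""

    true_tlvc_ml: float
    true_event_volumes_ml: dict
    true_pbvc_percent: float
    true_pvvc_percent: float
    true_coupled_displacement_mm: float = 0.0
    covariates: dict | None = None

    def __post_init__(self):
        pos = self.true_event_volumes_ml.get("new", 0.0) + self.true_event_volumes_ml.get(
            "enlarging", 0.0
        )
        neg = self.true_event_volumes_ml.get("shrinking", 0.0) + self.true_event_volumes_ml.get(
            "disappearing", 0.0
        )
        assert abs(self.true_tlvc_ml - (pos - neg)) < 1e-9


@dataclass
class SubjectTimepoint:
    """One subject-visit bundle on a regular anisotropic grid.

    ``spec`` is set when the visit came from the generator (and is needed to
    evolve it longitudinally); visits loaded from disk carry only images,
    masks and spacing.
    """

    pd_img: np.ndarray
    t1_img: np.ndarray
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    ventricle_mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    spec: PhantomSpec | None = None
    rigid_offset: tuple | None = None

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.spacing_mm

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        return aff


# ---------------------------------------------------------------------------
# voxelisation


def _world_coords(spec: PhantomSpec) -> np.ndarray:
    """(3, nx, ny, nz) voxel-centre coordinates in mm."""
    axes = [
        np.arange(n) * s for n, s in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def _apply_rigid_inverse(coords: np.ndarray, offset, centre: np.ndarray) -> np.ndarray:
    """Pull voxel-centre coords back through the inverse of a 6-DOF pose.

    ``offset = (rx, ry, rz, tx, ty, tz)`` — rotation (rad, xyz Euler) about
    ``centre`` followed by translation (mm).  A point y on the moved anatomy
    satisfies y = R(x - c) + c + t for anatomy point x, so we evaluate the
    static geometry at x = R^T (y - c - t) + c.
    """
    rx, ry, rz, tx, ty, tz = offset
    R = Rotation.from_euler("xyz", [rx, ry, rz]).as_matrix()
    flat = coords.reshape(3, -1)
    x = R.T @ (flat - centre[:, None] - np.array([[tx], [ty], [tz]])) + centre[:, None]
    return x.reshape(coords.shape)


def _coverage_ellipsoid(coords, centre, radii, spacing) -> np.ndarray:
    """Approximate partial-volume coverage (0..1) of an ellipsoid per voxel.

    Uses the signed distance estimate (rho - 1) / |grad rho| with rho the
    normalised ellipsoidal radius, smeared over the voxel footprint projected
    onto the surface normal — a linear-mixing partial-volume model.
    """
    c = np.asarray(centre, dtype=np.float64).reshape(3, 1, 1, 1)
    r = np.asarray(radii, dtype=np.float64).reshape(3, 1, 1, 1)
    s = np.asarray(spacing, dtype=np.float64).reshape(3, 1, 1, 1)
    u = (coords - c) / r
    rho = np.sqrt(np.sum(u * u, axis=0))
    grad = u / r  # gradient of rho^2 / 2; direction of grad rho
    gnorm = np.sqrt(np.sum(grad * grad, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = np.where(gnorm > 1e-12, grad / gnorm, 0.0)
        dist = np.where(gnorm > 1e-12, (rho - 1.0) * rho / gnorm, -1e9)
    w = np.sqrt(np.sum((nhat * s) ** 2, axis=0))
    w = np.maximum(w, 1e-6)
    return np.clip(0.5 - dist / w, 0.0, 1.0)


def _coverage_sphere(coords, centre, radius, spacing) -> np.ndarray:
    c = np.asarray(centre, dtype=np.float64).reshape(3, 1, 1, 1)
    s = np.asarray(spacing, dtype=np.float64).reshape(3, 1, 1, 1)
    d = coords - c
    dist = np.sqrt(np.sum(d * d, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = np.where(dist > 1e-9, d / dist, 0.0)
    w = np.maximum(np.sqrt(np.sum((nhat * s) ** 2, axis=0)), 1e-6)
    return np.clip(0.5 - (dist - radius) / w, 0.0, 1.0)


def _voxelise(
    spec: PhantomSpec,
    brain_radii,
    ventricle_radii,
    lesions: Sequence[Lesion],
    rigid_offset=None,
):
    """Tissue coverage fractions (partial volume) + binary masks (>= 0.5)."""
    coords = _world_coords(spec)
    if rigid_offset is not None:
        coords = _apply_rigid_inverse(coords, rigid_offset, spec.centre_mm)
    c = spec.centre_mm
    sp = spec.voxel_size_mm
    f_brain = _coverage_ellipsoid(coords, c, brain_radii, sp)
    f_vent = _coverage_ellipsoid(coords, c, ventricle_radii, sp)
    inner_radii = np.maximum(np.asarray(brain_radii) - spec.gm_thickness_mm, 1.0)
    f_inner = _coverage_ellipsoid(coords, c, inner_radii, sp)
    f_lesion = np.zeros(spec.grid_shape, dtype=np.float64)
    for les in lesions:
        f_lesion = np.maximum(
            f_lesion, _coverage_sphere(coords, les.centre_mm, les.radius_mm, sp)
        )
    brain = f_brain >= 0.5
    vent = f_vent >= 0.5
    lesion = (f_lesion >= 0.5) & brain & ~vent
    fracs = {"brain": f_brain, "vent": f_vent, "inner": f_inner, "lesion": f_lesion}
    return brain, vent, fracs, lesion


def _render(spec: PhantomSpec, fracs: dict, rng: np.random.Generator):
    """Compose intensity channels + acquisition artefacts from tissue fractions.

    Partial volume is modelled as linear mixing of tissue means, nested as
    background < brain < (GM shell | WM interior) < (ventricle CSF | lesion).
    """
    imgs = {}
    fb, fv, fi, fl = fracs["brain"], fracs["vent"], fracs["inner"], fracs["lesion"]
    for ch in ("pd", "t1"):
        tm = spec.tissue_means[ch]
        wm_like = tm["wm"] * (1 - fl) + tm["lesion"] * fl
        tissue = tm["gm"] * (1 - fi) + fi * (
            tm["csf"] * fv + (1 - fv) * wm_like
        )
        img = fb * tissue
        imgs[ch] = img
    if spec.bias_amplitude > 0:
        bias = _smooth_bias(spec, rng)
        for ch in imgs:
            imgs[ch] = imgs[ch] * bias
    if spec.slice_gain_sd > 0:
        for ch in imgs:
            gains = rng.normal(1.0, spec.slice_gain_sd, size=spec.grid_shape[2])
            imgs[ch] = imgs[ch] * gains[None, None, :]
    if spec.noise_sd > 0:
        for ch in imgs:
            imgs[ch] = imgs[ch] + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    return (
        np.clip(imgs["pd"], 0, None).astype(np.float32),
        np.clip(imgs["t1"], 0, None).astype(np.float32),
    )


def _smooth_bias(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random quadratic multiplicative bias, scaled to +/- bias_amplitude."""
    coords = _world_coords(spec)
    c = spec.centre_mm.reshape(3, 1, 1, 1)
    ext = (np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size_mm)).reshape(
        3, 1, 1, 1
    )
    u = (coords - c) / ext  # roughly [-0.5, 0.5]
    lin = rng.normal(size=3)
    quad = rng.normal(size=3)
    f = np.tensordot(lin, u, axes=(0, 0)) + np.tensordot(quad, u * u, axes=(0, 0))
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f / peak
    return 1.0 + spec.bias_amplitude * f


# ---------------------------------------------------------------------------
# public generator API


def make_baseline_phantom(spec: PhantomSpec, seed: int) -> SubjectTimepoint:
    """Voxelise a baseline visit: PD/T1 channels + brain/lesion masks.

    Deterministic for a fixed ``(spec, seed)`` pair.
    """
    _check_lesion_layout(spec, spec.lesions)
    rng = np.random.default_rng(seed)
    brain, vent, fracs, lesion = _voxelise(
        spec, spec.brain_radii_mm, spec.ventricle_radii_mm, spec.lesions
    )
    pd_img, t1_img = _render(spec, fracs, rng)
    return SubjectTimepoint(
        pd_img=pd_img,
        t1_img=t1_img,
        brain_mask=brain,
        lesion_mask=lesion,
        ventricle_mask=vent,
        spacing_mm=spec.voxel_size_mm,
        spec=spec,
    )


def _check_lesion_layout(spec: PhantomSpec, lesions: Sequence[Lesion], extra=()):
    """Reject lesion sets whose spheres touch (would merge events) or leave WM."""
    all_les = list(lesions) + list(extra)
    for i, a in enumerate(all_les):
        for b in all_les[i + 1 :]:
            gap = np.linalg.norm(
                np.asarray(a.centre_mm) - np.asarray(b.centre_mm)
            ) - (a.radius_mm + b.radius_mm)
            if gap < max(spec.voxel_size_mm):
                raise ValueError(
                    f"lesions at {a.centre_mm} and {b.centre_mm} would merge "
                    f"(surface gap {gap:.1f} mm)"
                )
    c = spec.centre_mm
    rb = np.asarray(spec.brain_radii_mm) - spec.gm_thickness_mm
    rv = np.asarray(spec.ventricle_radii_mm)
    for les in all_les:
        d = np.asarray(les.centre_mm) - c
        # inside WM ellipsoid (with radius margin), outside ventricle (with margin)
        if np.sum((d / np.maximum(rb - les.radius_mm, 1e-3)) ** 2) > 1.0:
            raise ValueError(f"lesion at {les.centre_mm} leaves the WM compartment")
        if np.sum((d / (rv + les.radius_mm)) ** 2) < 1.0:
            raise ValueError(f"lesion at {les.centre_mm} intersects the ventricles")


def _evolve_lesions(
    lesions: Sequence[Lesion], events: Sequence[LesionEvent]
) -> tuple[tuple[Lesion, ...], dict]:
    """Apply events to the baseline sphere list; return follow-up list + truth."""
    vols = {"new": 0.0, "enlarging": 0.0, "shrinking": 0.0, "disappearing": 0.0}
    current = list(lesions)

    def _find(centre):
        arr = np.asarray(centre)
        for idx, les in enumerate(current):
            if np.linalg.norm(np.asarray(les.centre_mm) - arr) < 1.0:
                return idx
        raise ValueError(f"no baseline lesion at {centre} to modify")

    sphere = lambda r: 4.0 / 3.0 * np.pi * r**3
    for ev in events:
        if ev.kind == "new":
            if ev.radius_mm <= 0:
                raise ValueError("new lesion needs radius_mm > 0")
            current.append(Lesion(tuple(ev.centre_mm), ev.radius_mm))
            vols["new"] += sphere(ev.radius_mm) * ML_PER_MM3
        elif ev.kind == "disappear":
            idx = _find(ev.centre_mm)
            vols["disappearing"] += sphere(current[idx].radius_mm) * ML_PER_MM3
            current.pop(idx)
        elif ev.kind == "enlarge":
            idx = _find(ev.centre_mm)
            les = current[idx]
            r2 = les.radius_mm + abs(ev.delta_radius_mm)
            vols["enlarging"] += (sphere(r2) - sphere(les.radius_mm)) * ML_PER_MM3
            current[idx] = replace(les, radius_mm=r2)
        elif ev.kind == "shrink":
            idx = _find(ev.centre_mm)
            les = current[idx]
            r2 = les.radius_mm - abs(ev.delta_radius_mm)
            if r2 <= 0.5:
                raise ValueError(
                    "shrink would erase the lesion; request a 'disappear' event"
                )
            vols["shrinking"] += (sphere(les.radius_mm) - sphere(r2)) * ML_PER_MM3
            current[idx] = replace(les, radius_mm=r2)
    return tuple(current), vols


def apply_longitudinal_change(
    base: SubjectTimepoint, change: ChangeSpec, seed: int
) -> tuple[SubjectTimepoint, GroundTruth]:
    """Generate the follow-up visit of an interval and its exact ground truth.

    The brain boundary is scaled by ``brain_scale`` about the grid centre, the
    ventricular surface is pushed outward by ``ventricle_dilate_mm``, lesion
    events edit the sphere list, and an optional rigid pose offset moves the
    whole head.  Noise, slice gains and bias are redrawn from ``seed``.
    """
    spec = base.spec
    s = change.brain_scale
    new_lesions, vols = _evolve_lesions(spec.lesions, change.lesion_events)
    _check_lesion_layout(spec, new_lesions)
    brain_radii = tuple(np.asarray(spec.brain_radii_mm) * s)
    vent_radii = tuple(
        np.asarray(spec.ventricle_radii_mm) + change.ventricle_dilate_mm
    )
    if np.any(np.asarray(vent_radii) >= np.asarray(brain_radii)):
        raise ValueError("ventricle dilation exceeds brain boundary")

    # follow-up spec carries the evolved geometry so intervals can be chained
    fu_spec = replace(
        spec,
        lesions=new_lesions,
        brain_radii_mm=tuple(brain_radii),
        ventricle_radii_mm=tuple(vent_radii),
    )
    brain, vent, fracs, lesion = _voxelise(
        fu_spec, brain_radii, vent_radii, new_lesions, rigid_offset=change.rigid_offset
    )
    rng = np.random.default_rng(seed)
    pd_img, t1_img = _render(fu_spec, fracs, rng)
    follow = SubjectTimepoint(
        pd_img=pd_img,
        t1_img=t1_img,
        brain_mask=brain,
        lesion_mask=lesion,
        ventricle_mask=vent,
        spacing_mm=fu_spec.voxel_size_mm,
        spec=fu_spec,
        rigid_offset=change.rigid_offset,
    )
    tlvc = (vols["new"] + vols["enlarging"]) - (vols["shrinking"] + vols["disappearing"])
    v0 = spec.ventricle_volume_mm3()
    v1 = 4.0 / 3.0 * np.pi * float(np.prod(vent_radii))
    truth = GroundTruth(
        true_tlvc_ml=tlvc,
        true_event_volumes_ml=vols,
        true_pbvc_percent=100.0 * (s**3 - 1.0),
        true_pvvc_percent=100.0 * (v1 / v0 - 1.0),
    )
    return follow, truth


# identity-change helper used in tests/examples
def identity_change() -> ChangeSpec:
    return ChangeSpec(brain_scale=1.0)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator settings.

    Defaults emulate the longitudinal structure of an early-MS trial cohort:
    yearly intervals, mild global atrophy (PBVC about -0.4 %/y), ventricular
    enlargement of a few %/y, lesion birth/growth/shrinkage/death giving a
    total lesion volume change centred near zero with ~1 mL spread, multi-site
    acquisition with site-specific intensity offsets, age ~ N(31.5, 8.35) and
    a 61.7% female fraction.
    """

    n_subjects: int = 20
    n_sites: int = 3
    n_intervals: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    radii_jitter_frac: float = 0.04
    atrophy_scale_mean: float = 0.9987
    atrophy_scale_sd: float = 0.002
    ventricle_dilate_mean_mm: float = 0.10
    ventricle_dilate_sd_mm: float = 0.10
    n_baseline_lesions_mean: float = 5.0
    lesion_radius_range_mm: tuple[float, float] = (2.5, 5.5)
    p_enlarge: float = 0.20
    p_shrink: float = 0.20
    p_disappear: float = 0.10
    new_lesion_rate: float = 1.2
    delta_radius_range_mm: tuple[float, float] = (0.8, 2.0)
    site_gain_sd: float = 0.04
    coupling_beta: float = 0.0  # mm extra ventricular dilation per mL of TLVC
    female_fraction: float = 0.617
    age_mean: float = 31.5
    age_sd: float = 8.35
    et_fraction: float = 2.0 / 3.0
    cdms_rate: float = 0.10
    rigid_jitter: float = 0.0  # SD of pose perturbation (rad / mm)

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_sites < 1 or self.n_intervals < 1:
            raise ValueError("need n_subjects >= 2, n_sites >= 1, intervals >= 1")


@dataclass
class SubjectInterval:
    """One analysed interval: the visit pair plus its generator truth."""

    subject: str
    interval: int
    visit1: SubjectTimepoint
    visit2: SubjectTimepoint
    truth: GroundTruth


@dataclass
class Cohort:
    intervals: list  # of SubjectInterval
    covariates: pd.DataFrame
    spec: CohortSpec


def _sample_lesions(spec: PhantomSpec, cohort: CohortSpec, rng) -> tuple[Lesion, ...]:
    """Rejection-sample non-touching WM lesion spheres."""
    n = int(rng.poisson(cohort.n_baseline_lesions_mean))
    placed: list[Lesion] = []
    lo, hi = cohort.lesion_radius_range_mm
    c = spec.centre_mm
    for _ in range(n):
        for _try in range(60):
            r = float(rng.uniform(lo, hi))
            # sample in a WM-centred shell: direction uniform, radius between
            # ventricle+r and wm-r along that direction
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rv = np.asarray(spec.ventricle_radii_mm)
            rb = np.asarray(spec.brain_radii_mm) - spec.gm_thickness_mm
            r_in = 1.0 / np.sqrt(np.sum((u / rv) ** 2))
            r_out = 1.0 / np.sqrt(np.sum((u / rb) ** 2))
            lo_d, hi_d = r_in + r * 1.4, r_out - r * 1.25
            if hi_d <= lo_d:
                continue
            d = float(rng.uniform(lo_d, hi_d))
            cand = Lesion(tuple(c + d * u), r)
            try:
                _check_lesion_layout(spec, placed + [cand])
            except ValueError:
                continue
            placed.append(cand)
            break
    return tuple(placed)


def _sample_events(
    lesions: Sequence[Lesion], spec: PhantomSpec, cohort: CohortSpec, rng
) -> tuple[LesionEvent, ...]:
    """Draw a valid event set; candidates breaking lesion separation are dropped."""
    events: list[LesionEvent] = []

    def _try_add(ev: LesionEvent) -> bool:
        cand = events + [ev]
        try:
            evolved, _ = _evolve_lesions(lesions, cand)
            _check_lesion_layout(spec, evolved)
        except ValueError:
            return False
        events.append(ev)
        return True

    for les in lesions:
        p = rng.uniform()
        dlo, dhi = cohort.delta_radius_range_mm
        if p < cohort.p_disappear and les.radius_mm <= 4.5:
            _try_add(LesionEvent("disappear", les.centre_mm))
        elif p < cohort.p_disappear + cohort.p_enlarge:
            _try_add(
                LesionEvent(
                    "enlarge", les.centre_mm, delta_radius_mm=float(rng.uniform(dlo, dhi))
                )
            )
        elif p < cohort.p_disappear + cohort.p_enlarge + cohort.p_shrink:
            delta = min(float(rng.uniform(dlo, dhi)), les.radius_mm - 1.0)
            if delta > 0.2:
                _try_add(LesionEvent("shrink", les.centre_mm, delta_radius_mm=delta))
    n_new = int(rng.poisson(cohort.new_lesion_rate))
    for _ in range(n_new):
        # draw a single well-separated new sphere against the evolved layout
        for _try in range(60):
            single = _sample_one_lesion(spec, cohort, rng)
            if single is None:
                break
            if _try_add(
                LesionEvent("new", single.centre_mm, radius_mm=single.radius_mm)
            ):
                break
    return tuple(events)


def _sample_one_lesion(spec, cohort, rng) -> Lesion | None:
    lo, hi = cohort.lesion_radius_range_mm
    c = spec.centre_mm
    for _try in range(40):
        r = float(rng.uniform(lo, min(hi, 4.0)))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rv = np.asarray(spec.ventricle_radii_mm)
        rb = np.asarray(spec.brain_radii_mm) - spec.gm_thickness_mm
        r_in = 1.0 / np.sqrt(np.sum((u / rv) ** 2))
        r_out = 1.0 / np.sqrt(np.sum((u / rb) ** 2))
        lo_d, hi_d = r_in + r * 1.4, r_out - r * 1.25
        if hi_d <= lo_d:
            continue
        d = float(rng.uniform(lo_d, hi_d))
        return Lesion(tuple(c + d * u), r)
    return None


def simulate_cohort(cohort_spec: CohortSpec, seed: int) -> Cohort:
    """Generate a longitudinal multi-site cohort with exact interval truth.

    Site effects are multiplicative intensity gains shared by all subjects of
    a site.  When ``coupling_beta != 0`` the ventricular dilation of each
    interval receives an extra ``coupling_beta * true_TLVC`` mm of outward
    motion, so lesion activity and regional edge displacement are coupled *in
    the images themselves*, not merely in attached numbers.
    """
    cs = cohort_spec
    rng = np.random.default_rng(seed)
    site_gain = rng.normal(1.0, cs.site_gain_sd, size=cs.n_sites)
    intervals: list[SubjectInterval] = []
    rows = []
    for i in range(cs.n_subjects):
        sid = f"S{i:03d}"
        site = int(rng.integers(cs.n_sites))
        age = float(rng.normal(cs.age_mean, cs.age_sd))
        sex = int(rng.uniform() < cs.female_fraction)  # 1 = female
        treatment = "ET" if rng.uniform() < cs.et_fraction else "DT"
        jit = rng.normal(0.0, cs.radii_jitter_frac, size=3)
        base_spec = replace(
            cs.phantom,
            brain_radii_mm=tuple(np.asarray(cs.phantom.brain_radii_mm) * (1 + jit)),
            tissue_means=_scale_means(cs.phantom.tissue_means, site_gain[site]),
        )
        base_spec = replace(base_spec, lesions=_sample_lesions(base_spec, cs, rng))
        visit = make_baseline_phantom(base_spec, seed=int(rng.integers(2**31)))
        for t in range(1, cs.n_intervals + 1):
            events = _sample_events(visit.spec.lesions, visit.spec, cs, rng)
            s = float(
                np.clip(
                    rng.normal(cs.atrophy_scale_mean, cs.atrophy_scale_sd), 0.99, 1.006
                )
            )
            dil = float(
                rng.normal(cs.ventricle_dilate_mean_mm, cs.ventricle_dilate_sd_mm)
            )
            offset = None
            if cs.rigid_jitter > 0:
                offset = tuple(rng.normal(0.0, cs.rigid_jitter, size=6))
            # provisional truth for coupling (TLVC known analytically from events)
            _, pre_vols = _evolve_lesions(visit.spec.lesions, events)
            tlvc = (pre_vols["new"] + pre_vols["enlarging"]) - (
                pre_vols["shrinking"] + pre_vols["disappearing"]
            )
            coupled = cs.coupling_beta * tlvc
            change = ChangeSpec(
                brain_scale=s,
                ventricle_dilate_mm=dil + coupled,
                lesion_events=events,
                rigid_offset=offset,
            )
            follow, truth = apply_longitudinal_change(
                visit, change, seed=int(rng.integers(2**31))
            )
            cdms = int(rng.uniform() < cs.cdms_rate)
            truth.true_coupled_displacement_mm = coupled
            truth.covariates = dict(
                subject=sid, site=f"site{site}", age=age, sex=sex,
                treatment=treatment, cdms=cdms, interval=t,
            )
            intervals.append(SubjectInterval(sid, t, visit, follow, truth))
            rows.append({**truth.covariates, "true_tlvc_ml": truth.true_tlvc_ml})
            visit = follow
    cov = pd.DataFrame(rows)
    return Cohort(intervals=intervals, covariates=cov, spec=cs)


def _scale_means(tm: dict, gain: float) -> dict:
    return {ch: {k: v * gain for k, v in d.items()} for ch, d in tm.items()}
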