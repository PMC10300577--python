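"""Subtraction-image lesion-change quantification (TLVC).

The method: the PD-weighted image of the first visit of a yearly interval is
subtracted from the second visit in halfway space; the difference image is
converted to Z-scores using the mean and SD over *non-lesional* brain tissue
(robust to site/scanner intensity differences); voxels inside the lesion
masks whose |Z| strictly exceeds a threshold (default 1.5 SD) are labelled as
changing; connected lesions are matched across the two visits and labelled
new / enlarging / shrinking / disappearing; and the yearly total lesion
volume change is

    TLVC = (new + enlarging) - (shrinking + disappearing)   [mL/year].

Sign convention: MS lesions are hyperintense on PD, so a positive subtraction
Z inside a lesion mask means tissue became more lesion-like (growth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .phantom import ML_PER_MM3, SubjectTimepoint
from .preprocess import correct_slice_intensity
from .registration import make_halfway_pair

log = logging.getLogger(__name__)

CATEGORIES = ("new", "enlarging", "shrinking", "disappearing")
_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class ZMap:
    """Z-scored subtraction image with its non-lesional reference statistics."""

    z: np.ndarray
    reference_stats: tuple[float, float]  # (mu_nl, sigma_nl)
    brain_mask: np.ndarray


@dataclass
class ChangeLabelMap:
    """Per-voxel change labels: 0 none, +1 increase, -1 decrease."""

    labels: np.ndarray
    threshold: float


@dataclass
class LesionEvent:
    lesion_id: int
    category: str
    voxels: np.ndarray  # (n, 3) int indices in halfway space
    volume_ml: float


@dataclass
class LesionEventSet:
    events: list
    spacing: tuple[float, float, float]
    interval_id: str = ""

    def volumes_by_category(self) -> dict:
        out = {c: 0.0 for c in CATEGORIES}
        for ev in self.events:
            out[ev.category] += ev.volume_ml
        return out


@dataclass
class TlvcResult:
    tlvc_ml: float
    positive_ml: float
    negative_ml: float

    def __post_init__(self):
        assert abs(self.tlvc_ml - (self.positive_ml - self.negative_ml)) < 1e-12


# ---------------------------------------------------------------------------


def subtraction_image(
    pd_visit1: np.ndarray, pd_visit2: np.ndarray, brain_mask: np.ndarray
) -> np.ndarray:
    """Voxelwise visit2 - visit1 inside the brain mask, zero outside."""
    if pd_visit1.shape != pd_visit2.shape or pd_visit1.shape != brain_mask.shape:
        raise ValueError("subtraction requires identical halfway grids")
    D = np.zeros(pd_visit1.shape, dtype=np.float64)
    m = np.asarray(brain_mask, dtype=bool)
    D[m] = np.asarray(pd_visit2, dtype=np.float64)[m] - np.asarray(
        pd_visit1, dtype=np.float64
    )[m]
    return D


def zscore_normalize(
    D: np.ndarray,
    brain_mask: np.ndarray,
    union_lesion_mask: np.ndarray,
    min_voxels: int = 1000,
) -> ZMap:
    """Z-score the subtraction image over non-lesional brain tissue.

    By construction the non-lesional in-brain voxels of the result have mean 0
    and SD 1.  Invariant to any affine rescaling of ``D``.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    nonles = brain & ~np.asarray(union_lesion_mask, dtype=bool)
    if nonles.sum() < min_voxels:
        raise ValueError(
            f"only {int(nonles.sum())} non-lesional voxels (< {min_voxels})"
        )
    mu = float(D[nonles].mean())
    sd = float(D[nonles].std())
    if sd == 0:
        raise ValueError("degenerate subtraction image: zero SD in non-lesional tissue")
    z = np.zeros(D.shape, dtype=np.float64)
    z[brain] = (D[brain] - mu) / sd
    return ZMap(z=z, reference_stats=(mu, sd), brain_mask=brain)


def label_change_voxels(
    zmap: ZMap, union_lesion_mask: np.ndarray, threshold: float = 1.5
) -> ChangeLabelMap:
    """Label in-lesion voxels whose |Z| strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = np.asarray(union_lesion_mask, dtype=bool)
    labels = np.zeros(zmap.z.shape, dtype=np.int8)
    labels[mask & (zmap.z > threshold)] = 1
    labels[mask & (zmap.z < -threshold)] = -1
    return ChangeLabelMap(labels=labels, threshold=threshold)


def classify_lesion_events(
    mask_t1: np.ndarray,
    mask_t2: np.ndarray,
    change_map: ChangeLabelMap,
    spacing: tuple[float, float, float],
    min_change_voxels: int = 1,
    interval_id: str = "",
) -> LesionEventSet:
    """Match lesions across visits and label new/enlarging/shrinking/disappearing.

    Connected components (26-connectivity) are extracted at each visit and
    matched by >= 1 voxel of overlap; many-to-many overlaps are merged into a
    single matched group (logged).  Components present only at visit 2 with at
    least ``min_change_voxels`` increase voxels are *new* (volume = component
    volume at t2); present only at visit 1 with decrease voxels are
    *disappearing* (volume = component volume at t1).  Matched groups are
    *enlarging* when the net change-voxel volume over their union (increase
    minus decrease) is positive — event volume = net volume — and *shrinking*
    when negative; matched groups with zero net change emit no event.
    """
    m1 = np.asarray(mask_t1, dtype=bool)
    m2 = np.asarray(mask_t2, dtype=bool)
    vox_ml = float(np.prod(spacing)) * ML_PER_MM3
    lab1, n1 = ndi.label(m1, structure=_STRUCT26)
    lab2, n2 = ndi.label(m2, structure=_STRUCT26)
    inc = change_map.labels == 1
    dec = change_map.labels == -1

    # overlap graph between t1 and t2 components
    both = (lab1 > 0) & (lab2 > 0)
    pairs = set(zip(lab1[both].tolist(), lab2[both].tolist()))
    # union-find over nodes ('a', i) / ('b', j) to merge many-to-many groups
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i, j in pairs:
        union(("a", i), ("b", j))
    groups: dict = {}
    for i in range(1, n1 + 1):
        groups.setdefault(find(("a", i)), {"a": [], "b": []})["a"].append(i)
    for j in range(1, n2 + 1):
        groups.setdefault(find(("b", j)), {"a": [], "b": []})["b"].append(j)

    events: list[LesionEvent] = []
    next_id = 1
    for grp in groups.values():
        in1 = np.isin(lab1, grp["a"]) if grp["a"] else np.zeros_like(m1)
        in2 = np.isin(lab2, grp["b"]) if grp["b"] else np.zeros_like(m2)
        if len(grp["a"]) > 1 or len(grp["b"]) > 1:
            log.info(
                "merged many-to-many lesion overlap: %d t1 / %d t2 components",
                len(grp["a"]), len(grp["b"]),
            )
        if not grp["a"]:  # only at follow-up: candidate new lesion
            n_inc = int(np.count_nonzero(in2 & inc))
            if n_inc >= min_change_voxels:
                vox = np.argwhere(in2)
                events.append(
                    LesionEvent(next_id, "new", vox, float(in2.sum()) * vox_ml)
                )
                next_id += 1
        elif not grp["b"]:  # only at baseline: candidate disappearing lesion
            n_dec = int(np.count_nonzero(in1 & dec))
            if n_dec >= min_change_voxels:
                vox = np.argwhere(in1)
                events.append(
                    LesionEvent(
                        next_id, "disappearing", vox, float(in1.sum()) * vox_ml
                    )
                )
                next_id += 1
        else:  # matched pair/group: net change over the union
            union_mask = in1 | in2
            n_inc = int(np.count_nonzero(union_mask & inc))
            n_dec = int(np.count_nonzero(union_mask & dec))
            net = n_inc - n_dec
            if net > 0 and n_inc >= min_change_voxels:
                vox = np.argwhere(union_mask & inc)
                events.append(
                    LesionEvent(next_id, "enlarging", vox, net * vox_ml)
                )
                next_id += 1
            elif net < 0 and n_dec >= min_change_voxels:
                vox = np.argwhere(union_mask & dec)
                events.append(
                    LesionEvent(next_id, "shrinking", vox, -net * vox_ml)
                )
                next_id += 1
    return LesionEventSet(events=events, spacing=tuple(spacing), interval_id=interval_id)


def total_lesion_volume_change(events: LesionEventSet) -> TlvcResult:
    """TLVC = (new + enlarging) - (shrinking + disappearing), in mL/year."""
    vols = events.volumes_by_category()
    pos = vols["new"] + vols["enlarging"]
    neg = vols["shrinking"] + vols["disappearing"]
    return TlvcResult(tlvc_ml=pos - neg, positive_ml=pos, negative_ml=neg)


# ---------------------------------------------------------------------------
# end-to-end interval estimator


@dataclass
class IntervalChange:
    """Everything the subtraction method produces for one interval."""

    tlvc: TlvcResult
    events: LesionEventSet
    zmap: ZMap
    change_map: ChangeLabelMap


def estimate_interval_change(
    visit1: SubjectTimepoint,
    visit2: SubjectTimepoint,
    threshold: float = 1.5,
    register: bool = True,
    min_change_voxels: int = 1,
    interval_id: str = "",
) -> IntervalChange:
    """Run the full subtraction-image chain on a visit pair.

    Slice-corrects the PD channel of both visits, places the pair in halfway
    space (``register=False`` skips the rigid estimate when visits share a
    grid), subtracts, Z-normalises over non-lesional brain, thresholds, and
    classifies lesion events into a TLVC.
    """
    pd1 = correct_slice_intensity(visit1.pd_img, visit1.brain_mask)
    pd2 = correct_slice_intensity(visit2.pd_img, visit2.brain_mask)
    pair = make_halfway_pair(
        pd1, pd2, visit1.brain_mask, visit2.brain_mask, visit1.spacing,
        register=register,
        extras_a={"lesion": visit1.lesion_mask},
        extras_b={"lesion": visit2.lesion_mask},
    )
    les1 = pair.extras_a["lesion"]
    les2 = pair.extras_b["lesion"]
    union = les1 | les2
    D = subtraction_image(pair.image_a_hw, pair.image_b_hw, pair.mask_hw)
    zmap = zscore_normalize(D, pair.mask_hw, union)
    change = label_change_voxels(zmap, union, threshold=threshold)
    events = classify_lesion_events(
        les1, les2, change, visit1.spacing,
        min_change_voxels=min_change_voxels, interval_id=interval_id,
    )
    return IntervalChange(
        tlvc=total_lesion_volume_change(events),
        events=events, zmap=zmap, change_map=change,
    )
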