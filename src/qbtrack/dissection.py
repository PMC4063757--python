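"""Bundle selection and termination classification.

The manual steps of a tract dissection are replaced by explicit, auditable
operations: an axis-aligned selection plane (keep streamlines that traverse
it), two automated artifact rules (loops by cumulative turning, cortical-gray
threading at interior points), morphological growth of cortical labels into
the underlying white matter, and endpoint-only classification of streamlines
against the grown labels, yielding one subject-level binary row per
volume of interest (VOI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .formats import FormatError, ImageGrid, LabelVolume, Tractogram

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PlaneSpec:
    """Axis-aligned plane in world mm.

    mode: ``traverse`` keeps streamlines crossing (or touching) the plane;
    ``all_below`` / ``all_above`` keep streamlines entirely on one side.
    """

    axis: str
    coordinate_mm: float
    mode: str = "traverse"

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")
        if self.mode not in ("traverse", "all_below", "all_above"):
            raise ValueError(f"unknown plane mode {self.mode!r}")


def filter_by_plane(tractogram: Tractogram, plane: PlaneSpec) -> Tractogram:
    """Select streamlines by their relation to an axis-aligned plane.

    In traverse mode a streamline is kept iff some segment has endpoints on
    opposite sides of the plane or a vertex exactly on it (inclusive rule).
    """
    ax = _AXES[plane.axis]
    kept = []
    for sl in tractogram:
        s = sl[:, ax] - plane.coordinate_mm
        if plane.mode == "traverse":
            if np.any(s == 0.0) or np.any(s[:-1] * s[1:] <= 0.0):
                kept.append(sl)
        elif plane.mode == "all_below":
            if np.all(s <= 0.0):
                kept.append(sl)
        else:
            if np.all(s >= 0.0):
                kept.append(sl)
    return Tractogram(kept, tractogram.grid, tractogram.step_mm)


def cumulative_turning_deg(sl: np.ndarray) -> float:
    """Sum of unsigned angles between consecutive segments, in degrees."""
    seg = np.diff(sl, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    ok = norms > 1e-12
    seg = seg[ok] / norms[ok, None]
    if len(seg) < 2:
        return 0.0
    cosangles = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosangles)).sum())


def _labels_at(points_mm: np.ndarray, labelvol: LabelVolume) -> np.ndarray:
    vox = np.rint(labelvol.grid.world_to_voxel(points_mm)).astype(np.int64)
    shape = np.array(labelvol.grid.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(len(vox), dtype=labelvol.labels.dtype)
    if inside.any():
        v = vox[inside]
        out[inside] = labelvol.labels[v[:, 0], v[:, 1], v[:, 2]]
    return out


def qc_filter(tractogram: Tractogram, labelvol: LabelVolume,
              max_turn_deg: float = 360.0, max_gm_interior: int = 2):
    """Exclude looping and gray-matter-threading streamlines.

    A streamline is excluded if its cumulative unsigned turning exceeds
    ``max_turn_deg`` (a loop by construction) or if its interior points enter
    more than ``max_gm_interior`` distinct cortical labels (endpoints may
    legitimately sit in two labels; interior threading is the artifact).
    Returns (filtered tractogram, exclusion report dict).
    """
    kept = []
    report = {"loop": 0, "gm_traversal": 0, "kept": 0}
    for sl in tractogram:
        if cumulative_turning_deg(sl) > max_turn_deg:
            report["loop"] += 1
            continue
        interior = sl[1:-1]
        if len(interior):
            labs = _labels_at(interior, labelvol)
            if len(set(labs[labs > 0].tolist())) > max_gm_interior:
                report["gm_traversal"] += 1
                continue
        kept.append(sl)
    report["kept"] = len(kept)
    return Tractogram(kept, tractogram.grid, tractogram.step_mm), report


def dilate_labels(labelvol: LabelVolume, wm_mask: np.ndarray,
                  depth_mm: float = 2.0) -> LabelVolume:
    """Grow each cortical label into nearby white-matter voxels.

    A white-matter voxel joins a label when its centre lies within
    ``depth_mm`` of the centre of any voxel of that label; contested voxels
    go to the nearest label (Euclidean centre distance) with ties broken
    toward the smaller label id.  Labels never shrink and growth never leaves
    ``wm_mask``.
    """
    labels = labelvol.labels
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if wm_mask.shape != labels.shape:
        raise FormatError("wm_mask shape does not match label volume")
    sampling = labelvol.grid.voxel_size
    grown = labels.copy()
    best = np.full(labels.shape, np.inf)
    candidates = wm_mask & (labels == 0)
    for lab in labelvol.label_ids:
        dist = distance_transform_edt(labels != lab, sampling=sampling)
        take = candidates & (dist <= depth_mm) & (dist < best)
        grown[take] = lab
        best[take] = dist[take]
    return LabelVolume(grown, dict(labelvol.lookup), labelvol.grid)


@dataclass
class TerminationRow:
    """Per-subject termination profile: VOI -> streamline-endpoint count.

    The binary indicator is 1 iff the count reaches ``min_streamlines``
    (default 1, matching the convention that even sparse hits are recorded,
    with the raw count preserved so stricter thresholds can be applied
    post hoc).
    """

    subject_id: str
    counts: dict
    min_streamlines: int = 1

    @property
    def indicators(self) -> dict:
        return {k: int(v >= self.min_streamlines)
                for k, v in self.counts.items()}

    def to_frame(self, lookup: dict = None) -> pd.DataFrame:
        rows = []
        inv = {v: k for k, v in (lookup or {}).items()}
        for name, count in sorted(self.counts.items()):
            rows.append({
                "voi": inv.get(name, ""),
                "name": name,
                "count": count,
                "indicator": int(count >= self.min_streamlines),
            })
        return pd.DataFrame(rows)


def classify_terminations(tractogram: Tractogram, labelvol: LabelVolume,
                          min_streamlines: int = 1,
                          subject_id: str = "") -> TerminationRow:
    """Count streamline endpoints per VOI (endpoints only, nearest voxel)."""
    counts = {name: 0 for name in labelvol.lookup.values()}
    if len(tractogram):
        endpoints = np.concatenate([sl[[0, -1]] for sl in tractogram])
        labs = _labels_at(endpoints, labelvol)
        for lab in labs[labs > 0]:
            counts[labelvol.lookup[int(lab)]] += 1
    return TerminationRow(subject_id, counts, min_streamlines)


def rectangular_plane_roi(grid: ImageGrid, axis: str, coordinate_mm: float,
                          center_mm, half_extent_mm: float) -> np.ndarray:
    """Boolean mask of a square patch of voxels on an axis-aligned plane.

    A stand-in for the hand-drawn seed ROI: voxels whose centre lies in the
    plane's voxel slab and within ``half_extent_mm`` of ``center_mm`` along
    the two in-plane axes.
    """
    ax = _AXES[axis]
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)
    half_vox = grid.voxel_size[ax] / 2.0
    in_slab = np.abs(centers[:, ax] - coordinate_mm) <= half_vox
    others = [a for a in range(3) if a != ax]
    center_mm = np.asarray(center_mm, dtype=float)
    in_patch = np.ones(len(centers), dtype=bool)
    for a in others:
        in_patch &= np.abs(centers[:, a] - center_mm[a]) <= half_extent_mm
    mask = np.zeros(grid.shape, dtype=bool)
    sel = idx[in_slab & in_patch]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask
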