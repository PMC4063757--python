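"""Group-level products: density maps, visitation masks, probability maps
and per-VOI termination summaries.

Streamline density counts each streamline at most once per voxel, with voxel
membership decided by point containment after supersampling every segment at
half-voxel spacing or finer.  Binary masks (visited by at least one
streamline) from the subjects of a group, resampled upstream to a common
grid, are averaged into probability maps (fraction of subjects) and
thresholded inclusively — the rendering convention keeps voxels visited in at
least 20% of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import FormatError, ImageGrid, Tractogram
from .dissection import TerminationRow


@dataclass
class DensityMap:
    counts: np.ndarray
    grid: ImageGrid


@dataclass
class ProbabilityMap:
    values: np.ndarray
    grid: ImageGrid
    n_subjects: int


def streamline_voxels(sl: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Unique voxel indices visited by one streamline.

    Each segment is supersampled so consecutive sample points are at most
    half the smallest voxel size apart, then points map to their containing
    (nearest-centre) voxel.
    """
    max_spacing = float(np.min(grid.voxel_size)) / 2.0
    pts = [sl[0]]
    for a, b in zip(sl[:-1], sl[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / max_spacing)), 1)
        t = np.arange(1, n + 1) / n
        pts.append(a + t[:, None] * (b - a))
    pts = np.vstack([np.atleast_2d(p) for p in pts])
    vox = np.rint(grid.world_to_voxel(pts)).astype(np.int64)
    shape = np.array(grid.shape)
    vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
    return np.unique(vox, axis=0)


def density_map(tractogram: Tractogram, grid: ImageGrid = None) -> DensityMap:
    """Streamlines-per-voxel count (each streamline once per voxel)."""
    grid = grid or tractogram.grid
    counts = np.zeros(grid.shape, dtype=np.int64)
    for sl in tractogram:
        vox = streamline_voxels(sl, grid)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return DensityMap(counts, grid)


def binary_mask(density: DensityMap) -> np.ndarray:
    """Voxels visited by at least one streamline."""
    return density.counts >= 1


def probability_map(masks, grid: ImageGrid) -> ProbabilityMap:
    """Across-subject fraction of binary visitation masks covering a voxel."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise FormatError("need at least one subject mask")
    for m in masks:
        if m.shape != grid.shape:
            raise FormatError("mask shape does not match the common grid")
    stack = np.stack(masks).astype(np.float64)
    return ProbabilityMap(stack.mean(axis=0), grid, len(masks))


def threshold_map(prob: ProbabilityMap, level: float = 0.20) -> np.ndarray:
    """Inclusive threshold mask; nested under increasing level."""
    if not 0.0 < level <= 1.0:
        raise ValueError("threshold level must be in (0, 1]")
    return prob.values >= level


@dataclass
class TerminationTable:
    """Subject x VOI binary matrix with a per-VOI percentage summary.

    ``indicators`` has one row per subject, one column per VOI; ``flags``
    (same shape, optional) marks entries supported by very few streamlines.
    """

    indicators: pd.DataFrame
    flags: pd.DataFrame = None

    def __post_init__(self) -> None:
        vals = self.indicators.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("indicator entries must be 0 or 1")

    @classmethod
    def from_rows(cls, rows) -> "TerminationTable":
        vois = list(rows[0].counts)
        for r in rows[1:]:
            if list(r.counts) != vois:
                raise FormatError("inconsistent VOI sets across subjects")
        data = {v: [r.indicators[v] for r in rows] for v in vois}
        idx = [r.subject_id or i + 1 for i, r in enumerate(rows)]
        return cls(pd.DataFrame(data, index=idx))

    @property
    def n_subjects(self) -> int:
        return len(self.indicators)


def summarize_terminations(table: TerminationTable) -> pd.Series:
    """Per-VOI percentage of subjects with indicator 1 (exact)."""
    return 100.0 * table.indicators.sum(axis=0) / table.n_subjects


def format_summary(summary: pd.Series) -> pd.Series:
    """Two-decimal percentage rendering, e.g. ``35.00%``."""
    return summary.map(lambda x: f"{x:.2f}%")
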