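"""Streamline propagation through bootstrap ODF peaks.

Seeds are laid out on a dense uniform lattice inside each ROI voxel (the
acquisition-matched default is 11^3 per voxel).  From every seed, each
retained ODF peak spawns one bidirectional streamline: two half-tracks grown
along +/- the peak axis and concatenated.  At every voxel visit a fresh
bootstrap ODF is drawn and only the peak closest to the incoming direction
continues the streamline.  Growth stops when the interpolated FA drops below
the threshold (default 0.15), the turn between consecutive steps exceeds the
maximum angle (default 60 degrees), the streamline leaves the grid, no peak
survives refinement, or a safety step cap is hit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .bootstrap import BootstrapModel, OdfSampler, philox_rng, prepare_bootstrap
from .formats import DWIVolume, ImageGrid, Tractogram
from .peaks import PeakSet, find_peaks
from .qball import ScalarVolume, fit_signal_sh, fit_tensor, fa_from_evals
from .sphere import make_sphere


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrackingConfig:
    """Stopping and seeding parameters of the propagation algorithm."""

    fa_threshold: float = 0.15
    max_angle_deg: float = 60.0
    step_mm: float = 1.1
    seeds_per_axis: int = 11
    max_steps: int = 2000
    sh_order: int = 4
    peak_min_sep_deg: float = 45.0
    peak_rel_threshold: float = 0.25
    max_peaks: int = 3
    sphere_subdivisions: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_threshold < 1.0:
            raise ConfigurationError("fa_threshold must be in (0, 1)")
        if not 0.0 < self.max_angle_deg < 90.0:
            raise ConfigurationError("max_angle_deg must be in (0, 90)")
        if self.step_mm <= 0:
            raise ConfigurationError("step_mm must be positive")
        if self.seeds_per_axis < 1:
            raise ConfigurationError("seeds_per_axis must be >= 1")


@dataclass(frozen=True)
class SeedROI:
    """Set of seed voxels (index triples) with a provenance note."""

    voxels: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        vox = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if vox.size == 0:
            raise ConfigurationError("seed ROI is empty")
        if vox.shape[1] != 3:
            raise ConfigurationError("seed voxels must be (N, 3) indices")
        object.__setattr__(self, "voxels", vox)

    @classmethod
    def from_mask(cls, mask: np.ndarray, note: str = "") -> "SeedROI":
        return cls(np.argwhere(mask), note)


def seed_grid(roi: SeedROI, grid: ImageGrid,
              seeds_per_axis: int = 11) -> np.ndarray:
    """World-mm seed points: an n^3 lattice strictly interior to each voxel.

    Per axis the fractional offsets are (i + 0.5)/n for i = 0..n-1, measured
    from the voxel's lower corner (the voxel centre sits at integer voxel
    coordinates, its cell spanning +/- 0.5).
    """
    n = int(seeds_per_axis)
    if n < 1:
        raise ConfigurationError("seeds_per_axis must be >= 1")
    for v in roi.voxels:
        if not grid.contains_voxel(v):
            raise ConfigurationError(f"seed voxel {v} outside grid")
    offs = (np.arange(n) + 0.5) / n - 0.5
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    lattice = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    vox_coords = (roi.voxels[:, None, :] + lattice[None, :, :]).reshape(-1, 3)
    return grid.voxel_to_world(vox_coords)


def select_direction(peaks: PeakSet, incoming: np.ndarray = None):
    """Pick the peak axis closest to the incoming direction.

    Returns (unit direction aligned with ``incoming``, angle in degrees), or
    None for an empty peak set.  With no incoming direction the caller is
    expected to spawn one streamline per peak instead.
    """
    if peaks.is_empty:
        return None
    if incoming is None:
        raise ValueError("incoming direction required; at seeds iterate peaks")
    dots = peaks.directions @ np.asarray(incoming, dtype=float)
    k = int(np.argmax(np.abs(dots)))
    direction = peaks.directions[k] * (1.0 if dots[k] >= 0 else -1.0)
    angle = float(np.degrees(np.arccos(min(abs(dots[k]), 1.0))))
    return direction, angle


class FAInterpolator:
    """Trilinear FA lookup in world coordinates (0 outside the grid)."""

    def __init__(self, fa: ScalarVolume):
        self.values = np.asarray(fa.values, dtype=float)
        self.grid = fa.grid

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        vox = self.grid.world_to_voxel(points_mm)
        return map_coordinates(self.values, vox.T, order=1,
                               mode="constant", cval=0.0)


class BootstrapPeakProvider:
    """Fresh bootstrap-ODF peaks per (streamline, voxel-visit)."""

    def __init__(self, model: BootstrapModel, cfg: TrackingConfig,
                 master_seed: int):
        self.sphere = make_sphere(cfg.sphere_subdivisions)
        from .qball import real_sym_sh_basis  # local to avoid cycle at import

        M = real_sym_sh_basis(model.L, self.sphere.vertices)
        self.sampler = OdfSampler(model, M)
        self.model = model
        self.cfg = cfg
        self.master_seed = int(master_seed)

    def peaks_at(self, voxel, streamline_id: int, step: int) -> PeakSet:
        voxel = tuple(int(i) for i in voxel)
        if not self.model.valid[voxel]:
            return PeakSet()
        rng = philox_rng(self.master_seed, streamline_id, step)
        odf = self.sampler.draw(voxel, rng)
        return find_peaks(
            odf, self.sphere,
            min_separation_deg=self.cfg.peak_min_sep_deg,
            relative_threshold=self.cfg.peak_rel_threshold,
            max_peaks=self.cfg.max_peaks,
        )


class TensorPeakProvider:
    """Deterministic single-peak provider from the principal tensor axis
    (the DTI baseline against which q-ball tracking is compared)."""

    def __init__(self, dwi: DWIVolume, mask: np.ndarray = None):
        tf = fit_tensor(dwi, mask=mask)
        self.directions = tf.principal_direction
        fa = fa_from_evals(tf.evals)
        self.valid = tf.valid & (fa > 0)

    def peaks_at(self, voxel, streamline_id: int, step: int) -> PeakSet:
        voxel = tuple(int(i) for i in voxel)
        if not self.valid[voxel]:
            return PeakSet()
        d = self.directions[voxel]
        n = np.linalg.norm(d)
        if n < 1e-12:
            return PeakSet()
        return PeakSet(np.asarray([d / n]), np.asarray([1.0]))


def _nearest_voxel(grid: ImageGrid, point_mm: np.ndarray) -> np.ndarray:
    return np.rint(grid.world_to_voxel(point_mm)[0]).astype(np.int64)


def _half_track(seed_mm, d0, provider, fa_interp, grid: ImageGrid,
                cfg: TrackingConfig, streamline_id: int):
    """Grow one half-track from the seed along d0.  Returns (points, reason).

    ``points`` excludes the seed itself.
    """
    points = []
    pos = np.asarray(seed_mm, dtype=float)
    direction = np.asarray(d0, dtype=float)
    for step in range(1, cfg.max_steps + 1):
        nxt = pos + cfg.step_mm * direction
        vox = _nearest_voxel(grid, nxt)
        if not grid.contains_voxel(vox):
            return points, "grid"
        if fa_interp(nxt[None, :])[0] < cfg.fa_threshold:
            return points, "fa"
        points.append(nxt)
        pos = nxt
        peaks = provider.peaks_at(vox, streamline_id, step)
        sel = select_direction(peaks, direction)
        if sel is None:
            return points, "no_peak"
        new_dir, angle = sel
        if angle > cfg.max_angle_deg:
            return points, "angle"
        direction = new_dir
    return points, "max_steps"


def propagate(seed_mm, provider, fa_interp, grid: ImageGrid,
              cfg: TrackingConfig, streamline_id: int,
              initial_axis: np.ndarray):
    """One bidirectional streamline from a seed along +/- ``initial_axis``.

    Returns (streamline array or None, tuple of the two stop reasons).
    """
    fwd, r_fwd = _half_track(seed_mm, initial_axis, provider, fa_interp,
                             grid, cfg, 2 * streamline_id)
    bwd, r_bwd = _half_track(seed_mm, -np.asarray(initial_axis), provider,
                             fa_interp, grid, cfg, 2 * streamline_id + 1)
    pts = bwd[::-1] + [np.asarray(seed_mm, dtype=float)] + fwd
    if len(pts) < 2:
        return None, (r_fwd, r_bwd)
    return np.asarray(pts), (r_fwd, r_bwd)


@dataclass
class TrackingResult:
    tractogram: Tractogram
    n_seeds: int
    stop_reasons: Counter = field(default_factory=Counter)


def track_seeds(seeds_mm, provider, fa: ScalarVolume, cfg: TrackingConfig,
                master_seed: int = 0) -> TrackingResult:
    """Propagate every seed; each retained seed-voxel peak spawns one
    bidirectional streamline."""
    grid = fa.grid
    if cfg.step_mm > float(np.min(grid.voxel_size)) + 1e-9:
        raise ConfigurationError("step_mm exceeds the smallest voxel size")
    fa_interp = FAInterpolator(fa)
    streamlines = []
    reasons = Counter()
    sl_id = 0
    for seed_idx, seed in enumerate(np.atleast_2d(seeds_mm)):
        vox = _nearest_voxel(grid, seed)
        if not grid.contains_voxel(vox):
            reasons["seed_outside_grid"] += 1
            continue
        if fa_interp(seed[None, :])[0] < cfg.fa_threshold:
            reasons["seed_low_fa"] += 1
            continue
        seed_peaks = provider.peaks_at(vox, sl_id, 0)
        if seed_peaks.is_empty:
            reasons["seed_no_peak"] += 1
            sl_id += cfg.max_peaks
            continue
        for k in range(len(seed_peaks)):
            sl, (rf, rb) = propagate(seed, provider, fa_interp, grid, cfg,
                                     sl_id + k, seed_peaks.directions[k])
            if sl is not None:
                streamlines.append(sl)
                reasons[rf] += 1
                reasons[rb] += 1
            else:
                reasons["too_short"] += 1
        sl_id += cfg.max_peaks
    tractogram = Tractogram(streamlines, grid, cfg.step_mm)
    return TrackingResult(tractogram, len(np.atleast_2d(seeds_mm)), reasons)


def track_bundle(dwi: DWIVolume, roi: SeedROI, cfg: TrackingConfig = None,
                 master_seed: int = 0, mask: np.ndarray = None,
                 method: str = "qball-bootstrap") -> TrackingResult:
    """Full reconstruction + tracking from a DWI volume and a seed ROI.

    ``method`` is ``"qball-bootstrap"`` (residual-bootstrap CSA q-ball) or
    ``"tensor"`` (deterministic principal-diffusion-direction baseline).
    Deterministic given ``master_seed``.
    """
    cfg = cfg or TrackingConfig()
    from .qball import fit_tensor_fa

    fa = fit_tensor_fa(dwi, mask=mask)
    if method == "qball-bootstrap":
        fit = fit_signal_sh(dwi, L=cfg.sh_order, mask=mask)
        model = prepare_bootstrap(fit)
        provider = BootstrapPeakProvider(model, cfg, master_seed)
    elif method == "tensor":
        provider = TensorPeakProvider(dwi, mask=mask)
    else:
        raise ConfigurationError(f"unknown tracking method {method!r}")
    seeds = seed_grid(roi, dwi.grid, cfg.seeds_per_axis)
    return track_seeds(seeds, provider, fa, cfg, master_seed)
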