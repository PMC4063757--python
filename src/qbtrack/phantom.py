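"""Synthetic acquisitions, multi-tensor bundle phantoms and table fixtures.

The generator emulates the study acquisition — 55 diffusion directions at
b = 2000 s/mm^2 plus one b0, 2.2 mm isotropic voxels — and bundle geometries
with the features the dissection pipeline must handle: a narrow gate region
through which every bundle passes (the external/extreme-capsule role),
anterior branches fanning to several frontal target labels, posterior
branches to occipital-like labels, and a perpendicular crossing bundle.
Fiber voxels use a prolate tensor with eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s
(FA ~ 0.82); the background is isotropic at 0.9e-3 mm^2/s (FA ~ 0), so the
0.15 FA stopping threshold separates bundle from background by construction.
Rician noise is parameterized by SNR = S0 / sigma.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .atlas import TerminationTable
from .formats import DWIVolume, GradientTable, ImageGrid, LabelVolume
from .tracking import SeedROI

DEFAULT_FIBER_EVALS = np.array([1.7e-3, 0.3e-3, 0.3e-3])   # mm^2/s
DEFAULT_BACKGROUND_DIFFUSIVITY = 0.9e-3                     # mm^2/s
DEFAULT_VOXEL_MM = 2.2
DEFAULT_BVAL = 2000.0
DEFAULT_N_DIRS = 55
DEFAULT_S0 = 1000.0


# ---------------------------------------------------------------------------
# acquisition scheme


def _repulsion_energy_grad(points: np.ndarray):
    """Electrostatic energy over antipodally-identified points + gradient."""
    n = len(points)
    grad = np.zeros_like(points)
    energy = 0.0
    for sign in (1.0, -1.0):
        diff = points[:, None, :] - sign * points[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        if sign < 0:
            d[d < 1e-9] = np.inf  # guard exact antipodes
        energy += 0.5 * np.sum(1.0 / d)
        g = -diff / d[..., None] ** 3
        grad += g.sum(axis=1) * (1.0 if sign > 0 else 2.0)
    return energy, grad


def make_gradient_table(n_dirs: int = DEFAULT_N_DIRS,
                        bval: float = DEFAULT_BVAL,
                        n_b0: int = 1, seed: int = 0,
                        n_iter: int = 400) -> GradientTable:
    """Acquisition scheme with directions spread by electrostatic repulsion.

    Charges interact with both each other and their antipodes, so the layout
    is optimized for axes (diffusion directions are sign-symmetric).
    Deterministic given ``seed``.
    """
    if n_dirs < 15:
        raise ValueError("need >= 15 directions for an order-4 SH fit")
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    pts = rng.normal(size=(n_dirs, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    eta = 0.05 / n_dirs
    for it in range(n_iter):
        _, grad = _repulsion_energy_grad(pts)
        # project onto the tangent plane and take a normalized step
        grad -= np.einsum("ij,ij->i", grad, pts)[:, None] * pts
        gn = np.linalg.norm(grad, axis=1, keepdims=True)
        gn[gn < 1e-12] = 1.0
        pts -= eta * grad / gn * max(1.0 - it / n_iter, 0.05)
        pts /= np.linalg.norm(pts, axis=1)[:, None]
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), pts])
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# forward signal model


def tensor_from_axis(axis, evals=DEFAULT_FIBER_EVALS) -> np.ndarray:
    """Axially symmetric diffusion tensor with given principal axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    evals = np.asarray(evals, dtype=float)
    return (evals[0] - evals[1]) * np.outer(axis, axis) + evals[1] * np.eye(3)


def multi_tensor_signal(directions, bval, fractions, tensors,
                        S0: float = DEFAULT_S0) -> np.ndarray:
    """Noise-free mixture signal S(g) = S0 * sum_i f_i exp(-b g^T D_i g)."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    g = np.atleast_2d(np.asarray(directions, dtype=float))
    out = np.zeros(len(g))
    for f, D in zip(fractions, tensors):
        quad = np.einsum("ij,jk,ik->i", g, np.asarray(D, dtype=float), g)
        out += f * np.exp(-float(bval) * quad)
    return S0 * out


def add_rician_noise(signal, snr: float, rng: np.random.Generator,
                     S0: float = DEFAULT_S0) -> np.ndarray:
    """Magnitude of the complex-Gaussian-perturbed signal, sigma = S0/snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    sigma = float(S0) / float(snr)
    signal = np.asarray(signal, dtype=float)
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2 ** 2)


# ---------------------------------------------------------------------------
# bundle phantoms


@dataclass(frozen=True)
class BundleSpec:
    """Tube around a cubic-spline centerline, with end labels."""

    name: str
    control_points_mm: np.ndarray  # (K, 3)
    radius_mm: float
    start_label: str
    end_label: str
    evals: np.ndarray = field(
        default_factory=lambda: DEFAULT_FIBER_EVALS.copy())


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple
    voxel_mm: float = DEFAULT_VOXEL_MM
    bundles: tuple = ()
    snr: float = None            # None -> noiseless
    S0: float = DEFAULT_S0
    background_diffusivity: float = DEFAULT_BACKGROUND_DIFFUSIVITY
    label_radius_mm: float = 5.5
    gate_center_mm: np.ndarray = None
    gate_radius_mm: float = 5.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom DWI volume."""

    centerlines: dict            # bundle name -> (M, 3) mm polyline
    labels: LabelVolume
    gate_mask: np.ndarray
    directions: dict             # bundle name -> (X,Y,Z,3) unit tangents
    memberships: dict            # bundle name -> (X,Y,Z) bool
    endpoint_labels: dict        # bundle name -> (start label, end label)

    @property
    def gate_roi(self) -> SeedROI:
        return SeedROI.from_mask(self.gate_mask, note="phantom gate")


def _sample_centerline(control_points: np.ndarray, step_mm: float):
    """Dense arc-length samples and unit tangents of a cubic spline."""
    cp = np.asarray(control_points, dtype=float)
    if len(cp) < 2:
        raise ValueError("centerline needs >= 2 control points")
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if len(cp) == 2:
        n = max(int(np.ceil(chord[-1] / step_mm)) + 1, 2)
        t = np.linspace(0, 1, n)
        pts = cp[0] + t[:, None] * (cp[1] - cp[0])
        tang = np.tile((cp[1] - cp[0]) / chord[-1], (n, 1))
        return pts, tang
    spl = CubicSpline(chord, cp, axis=0)
    n = max(int(np.ceil(chord[-1] / step_mm)) + 1, 2)
    s = np.linspace(0, chord[-1], n)
    pts = spl(s)
    tang = spl(s, 1)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    return pts, tang


def make_phantom(spec: PhantomSpec,
                 gtab: GradientTable = None) -> tuple:
    """Rasterize bundle tubes into a multi-tensor DWI volume.

    Per voxel the fiber compartments are the bundles whose tube contains the
    voxel centre, with equal volume fractions; other voxels get the isotropic
    background tensor.  Returns (DWIVolume, PhantomTruth).  Deterministic
    given ``spec.seed``.
    """
    grid = ImageGrid.isotropic(spec.shape, spec.voxel_mm)
    if gtab is None:
        gtab = make_gradient_table(seed=spec.seed)

    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)

    memberships, directions, centerlines = {}, {}, {}
    for b in spec.bundles:
        pts, tang = _sample_centerline(b.control_points_mm,
                                       spec.voxel_mm / 4.0)
        lo = pts.min(axis=0) - b.radius_mm
        hi = pts.max(axis=0) + b.radius_mm
        if np.any(lo < centers.min(axis=0) - spec.voxel_mm) or \
           np.any(hi > centers.max(axis=0) + spec.voxel_mm):
            raise ValueError(f"bundle {b.name!r} extends outside the grid")
        dist, nearest = cKDTree(pts).query(centers)
        member = dist <= b.radius_mm
        mvol = member.reshape(grid.shape)
        dvol = np.zeros(grid.shape + (3,))
        dvol.reshape(-1, 3)[member] = tang[nearest[member]]
        memberships[b.name] = mvol
        directions[b.name] = dvol
        centerlines[b.name] = pts

    # signal synthesis
    bg = spec.background_diffusivity * np.eye(3)
    n_vox = len(centers)
    signal = np.empty((n_vox, gtab.n_volumes))
    member_stack = np.stack(
        [memberships[b.name].reshape(-1) for b in spec.bundles]) \
        if spec.bundles else np.zeros((0, n_vox), dtype=bool)
    n_comp = member_stack.sum(axis=0)

    bvals = gtab.bvals
    dirs_all = gtab.bvecs
    bg_quad = np.einsum("ij,jk,ik->i", dirs_all, bg, dirs_all)
    bg_signal = spec.S0 * np.exp(-bvals * bg_quad)
    signal[:] = bg_signal[None, :]

    fiber_vox = np.nonzero(n_comp > 0)[0]
    for v in fiber_vox:
        tensors = []
        for k, b in enumerate(spec.bundles):
            if member_stack[k, v]:
                axis = directions[b.name].reshape(-1, 3)[v]
                tensors.append(tensor_from_axis(axis, b.evals))
        f = np.full(len(tensors), 1.0 / len(tensors))
        quad = np.stack([
            np.einsum("ij,jk,ik->i", dirs_all, D, dirs_all) for D in tensors])
        signal[v] = spec.S0 * (
            f[:, None] * np.exp(-bvals[None, :] * quad)).sum(axis=0)

    if spec.snr is not None:
        rng = np.random.Generator(np.random.Philox(key=int(spec.seed) + 1))
        signal = add_rician_noise(signal, spec.snr, rng, S0=spec.S0)

    data = signal.reshape(grid.shape + (gtab.n_volumes,))
    dwi = DWIVolume(data, grid, gtab)

    # labels at bundle endpoints
    labels = np.zeros(grid.shape, dtype=np.int32)
    lookup = {}
    next_id = 1
    endpoint_labels = {}
    for b in spec.bundles:
        for name, point in ((b.start_label, centerlines[b.name][0]),
                            (b.end_label, centerlines[b.name][-1])):
            if name not in lookup.values():
                lid = next_id
                lookup[lid] = name
                next_id += 1
            else:
                lid = {v: k for k, v in lookup.items()}[name]
            near = np.linalg.norm(centers - point, axis=1) \
                <= spec.label_radius_mm
            lvol = labels.reshape(-1)
            unset = near & (lvol == 0)
            lvol[unset] = lid
        endpoint_labels[b.name] = (b.start_label, b.end_label)
    labelvol = LabelVolume(labels, lookup, grid)

    # gate mask: bundle voxels near the gate centre
    if spec.gate_center_mm is not None:
        any_member = n_comp.reshape(grid.shape) > 0
        near_gate = (np.linalg.norm(
            centers - np.asarray(spec.gate_center_mm, dtype=float), axis=1)
            <= spec.gate_radius_mm).reshape(grid.shape)
        gate_mask = any_member & near_gate
    else:
        gate_mask = np.zeros(grid.shape, dtype=bool)

    truth = PhantomTruth(centerlines, labelvol, gate_mask, directions,
                         memberships, endpoint_labels)
    return dwi, truth


# --- presets ---------------------------------------------------------------


def _mm(*vox, voxel=DEFAULT_VOXEL_MM):
    return np.asarray(vox, dtype=float) * voxel


def straight_bundle_spec(snr: float = None, seed: int = 0) -> PhantomSpec:
    """One straight bundle along y with a mid-course gate."""
    shape = (12, 30, 9)
    v = DEFAULT_VOXEL_MM
    b = BundleSpec(
        name="main",
        control_points_mm=np.array([_mm(5.5, 3, 4), _mm(5.5, 26, 4)]),
        radius_mm=1.5 * v,
        start_label="posterior_1",
        end_label="frontal_1",
    )
    return PhantomSpec(shape=shape, bundles=(b,), snr=snr, seed=seed,
                       gate_center_mm=_mm(5.5, 14.5, 4),
                       gate_radius_mm=1.6 * v)


def crossing_spec(snr: float = None, seed: int = 0,
                  crossing_angle_deg: float = 90.0) -> PhantomSpec:
    """Main bundle along y crossed mid-course by a perpendicular bundle.

    The gate sits on the main bundle before the crossing, so through-crossing
    connectivity is the fraction of gate-seeded streamlines reaching the main
    bundle's far (anterior) label.
    """
    shape = (26, 30, 9)
    v = DEFAULT_VOXEL_MM
    main = BundleSpec(
        name="main",
        control_points_mm=np.array([_mm(12.5, 3, 4), _mm(12.5, 26, 4)]),
        radius_mm=1.5 * v,
        start_label="posterior_1",
        end_label="frontal_1",
    )
    ang = np.radians(crossing_angle_deg)
    d = np.array([np.sin(ang), np.cos(ang), 0.0])
    c = _mm(12.5, 15, 4)
    half = 10.5 * v
    cross = BundleSpec(
        name="crossing",
        control_points_mm=np.array([c - half * d, c + half * d]),
        radius_mm=1.5 * v,
        start_label="crossing_a",
        end_label="crossing_b",
    )
    return PhantomSpec(shape=shape, bundles=(main, cross), snr=snr,
                       seed=seed, gate_center_mm=_mm(12.5, 7, 4),
                       gate_radius_mm=1.6 * v)


def ifof_like_spec(snr: float = None, seed: int = 0) -> PhantomSpec:
    """Gate-and-fan geometry: four anterior branches fanning to frontal-like
    labels, three posterior branches, one perpendicular crossing bundle
    through the fan (the corona-radiata/SLF role).  Every branch threads the
    same gate point."""
    shape = (36, 44, 11)
    v = DEFAULT_VOXEL_MM
    gate = (17.5, 21.0, 5.0)
    r = 1.5 * v

    def bundle(name, start_vox, end_vox, s_lab, e_lab, mid_vox=None):
        pts = [_mm(*start_vox)]
        if mid_vox is not None:
            pts.append(_mm(*mid_vox))
        pts.append(_mm(*gate))
        pts.append(_mm(*end_vox))
        return BundleSpec(name=name,
                          control_points_mm=np.asarray(pts),
                          radius_mm=r, start_label=s_lab, end_label=e_lab)

    bundles = (
        bundle("b_front1", (10, 4, 5), (6, 40, 5), "occipital_1",
               "frontal_1"),
        bundle("b_front2", (17.5, 4, 5), (13, 40, 5), "occipital_2",
               "frontal_2"),
        bundle("b_front3", (25, 4, 5), (21.5, 40, 5), "occipital_3",
               "frontal_3"),
        bundle("b_front4", (17.5, 4, 5), (29, 40, 5), "occipital_2",
               "frontal_4"),
        BundleSpec(
            name="crossing",
            control_points_mm=np.array([_mm(3, 32, 5), _mm(33, 32, 5)]),
            radius_mm=r, start_label="crossing_a", end_label="crossing_b"),
    )
    return PhantomSpec(shape=shape, bundles=bundles, snr=snr, seed=seed,
                       gate_center_mm=_mm(*gate), gate_radius_mm=1.6 * v)


PRESETS = {
    "straight-bundle": straight_bundle_spec,
    "crossing-90": crossing_spec,
    "ifof-like": ifof_like_spec,
}


def make_preset_phantom(preset: str, snr: float = None, seed: int = 0):
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    return make_phantom(PRESETS[preset](snr=snr, seed=seed))


# ---------------------------------------------------------------------------
# packaged table fixtures


class PackagingError(RuntimeError):
    pass


def _fixture_text(name: str) -> str:
    return resources.files("qbtrack.data").joinpath(name).read_text()


def load_table_fixtures() -> dict:
    """Packaged termination tables, one per hemisphere and lobe group.

    Keys: ``anterior_left``, ``anterior_right``, ``posterior_left``,
    ``posterior_right``.  Each CSV's sha256 is checked against the recorded
    checksum, and the recomputed per-VOI percentages must equal the
    transcribed printed summary row exactly.
    """
    checksums = {}
    for line in _fixture_text("checksums.txt").splitlines():
        digest, fname = line.split()
        checksums[fname] = digest

    out = {}
    for key in ("anterior_left", "anterior_right",
                "posterior_left", "posterior_right"):
        fname = f"{key}.csv"
        text = _fixture_text(fname)
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != checksums[fname]:
            raise PackagingError(f"checksum mismatch for {fname}")
        raw = pd.read_csv(
            __import__("io").StringIO(text), dtype=str).set_index("subject")
        summary_row = raw.loc["% of 1"]
        body = raw.drop(index="% of 1")
        flags = body.apply(lambda col: col.str.endswith("*")).astype(int)
        indicators = body.apply(
            lambda col: col.str.rstrip("*").astype(int))
        table = TerminationTable(indicators, flags)
        computed = 100.0 * indicators.mean(axis=0)
        printed = summary_row.str.rstrip("%").astype(float)
        if not np.allclose(computed.to_numpy(), printed.to_numpy(),
                           atol=1e-9):
            raise PackagingError(
                f"{fname}: recomputed percentages disagree with the "
                "transcribed printed summary row")
        out[key] = table
    return out
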