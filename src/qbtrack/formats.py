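"""File formats and geometric metadata.

All world coordinates are RAS+ millimetres.  Voxel indexing is 0-based and a
voxel's world position is the centre of its cell; TrackVis' voxel-mm
convention (corner-origin) is converted at the I/O boundary.  Gradient tables
follow the FSL bval/bvec text dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "GradientTable",
    "ImageGrid",
    "DWIVolume",
    "LabelVolume",
    "Tractogram",
    "read_dwi",
    "write_dwi",
    "rotate_gradient_table",
    "read_tractogram",
    "write_tractogram",
    "read_label_volume",
    "read_lookup_table",
    "write_lookup_table",
]

#: b-values below this (s/mm^2) are treated as b=0 reference volumes.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Malformed file content or inconsistent geometric metadata."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit directions.

    ``bvecs`` rows for b0 volumes are zero vectors; all other rows are unit
    norm.  At least one b0 must be present.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"{len(bvals)} b-values but {len(bvecs)} directions"
            )
        b0 = bvals < B0_THRESHOLD
        if not b0.any():
            raise FormatError("gradient table contains no b0 volume")
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[~b0] < 1e-12):
            raise FormatError("zero direction vector paired with b > 0")
        # re-normalize diffusion directions; zero out b0 rows
        bvecs = bvecs.copy()
        bvecs[~b0] /= norms[~b0, None]
        bvecs[b0] = 0.0
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def gradients(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted (non-b0) volumes."""
        return self.bvecs[~self.b0_mask]

    @property
    def gradient_bvals(self) -> np.ndarray:
        return self.bvals[~self.b0_mask]


@dataclass(frozen=True)
class ImageGrid:
    """Voxel grid geometry: shape, voxel size (mm) and voxel-to-world affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise FormatError(f"grid shape must be 3 positive ints: {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (voxel centres at integers)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = self.inverse_affine
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.array(self.shape)))

    def same_grid(self, other: "ImageGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float) -> "ImageGrid":
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(tuple(shape), aff)


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its grid and gradient table."""

    data: np.ndarray
    grid: ImageGrid
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError("DWI data must be 4D")
        if self.data.shape[:3] != self.grid.shape:
            raise FormatError("DWI spatial shape does not match grid")
        if self.data.shape[3] != self.gtab.n_volumes:
            raise FormatError(
                f"{self.data.shape[3]} volumes but gradient table has "
                f"{self.gtab.n_volumes} entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("DWI contains non-finite values")
        if np.any(self.data < 0):
            raise FormatError("DWI contains negative signal")

    def b0_reference(self) -> np.ndarray:
        """Mean over b0 volumes (a single b0 passes through unchanged)."""
        return self.data[..., self.gtab.b0_mask].mean(axis=3)

    def diffusion_signal(self) -> np.ndarray:
        return self.data[..., ~self.gtab.b0_mask]


@dataclass
class LabelVolume:
    """Integer parcellation (0 = background) with a label->name lookup."""

    labels: np.ndarray
    lookup: dict
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integer-valued")
        if self.labels.shape != self.grid.shape:
            raise FormatError("label shape does not match grid")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise FormatError(f"labels missing from lookup: {sorted(missing)}")

    @property
    def label_ids(self):
        return sorted(set(np.unique(self.labels)) - {0})


@dataclass
class Tractogram:
    """Streamlines as polylines of world-mm points, with grid metadata."""

    streamlines: list
    grid: ImageGrid
    step_mm: float

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise FormatError("each streamline needs >= 2 points in 3D")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# readers / writers


def _load_fsl_table(path, n_rows: int) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=2, dtype=float)
    # FSL writes 3xN (bvec) / 1xN (bval); accept the transpose too
    if arr.shape[0] == n_rows:
        return arr
    if arr.shape[1] == n_rows:
        return arr.T
    raise FormatError(f"cannot interpret table of shape {arr.shape} at {path}")


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    bvals = _load_fsl_table(bval_path, 1).ravel()
    bvecs = _load_fsl_table(bvec_path, 3).T
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"{len(bvals)} bvals vs {len(bvecs)} bvecs"
        )
    return GradientTable(bvals, bvecs)


def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.17g")


def _grid_from_nifti(img) -> ImageGrid:
    return ImageGrid(tuple(img.shape[:3]), np.asarray(img.affine))


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D NIfTI plus FSL-style bval/bvec into a validated DWIVolume."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4D NIfTI, got shape {data.shape}")
    gtab = read_gradient_table(bval_path, bvec_path)
    if data.shape[3] != gtab.n_volumes:
        raise FormatError(
            f"{data.shape[3]} volumes but {gtab.n_volumes} gradient entries"
        )
    return DWIVolume(data, _grid_from_nifti(img), gtab)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path=None, bvec_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), dwi.grid.affine)
    nib.save(img, str(nifti_path))
    if bval_path is not None:
        write_gradient_table(dwi.gtab, bval_path, bvec_path)


def read_scalar_volume(nifti_path):
    img = nib.load(str(nifti_path))
    return np.asarray(img.dataobj, dtype=float), _grid_from_nifti(img)


def write_scalar_volume(values, grid: ImageGrid, nifti_path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine),
             str(nifti_path))


def read_lookup_table(path) -> dict:
    """Read a ``label<TAB-or-comma>name`` lookup file."""
    lookup = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").split("\t") if p.strip()]
        if len(parts) < 2:
            raise FormatError(f"bad lookup line: {line!r}")
        lookup[int(parts[0])] = parts[1].strip()
    return lookup


def write_lookup_table(lookup: dict, path) -> None:
    lines = [f"{k}\t{v}" for k, v in sorted(lookup.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_label_volume(nifti_path, lut_path) -> LabelVolume:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    return LabelVolume(labels, read_lookup_table(lut_path), _grid_from_nifti(img))


def write_label_volume(vol: LabelVolume, nifti_path, lut_path=None) -> None:
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int32), vol.grid.affine),
             str(nifti_path))
    if lut_path is not None:
        write_lookup_table(vol.lookup, lut_path)


def rotate_gradient_table(gtab: GradientTable, rotations) -> GradientTable:
    """Apply one proper rotation per volume to the gradient directions.

    Used after motion correction, where each volume was realigned by a rigid
    transform whose rotation must also be applied to its diffusion direction.
    b-values are unchanged.
    """
    rotations = [np.asarray(R, dtype=float) for R in rotations]
    if len(rotations) != gtab.n_volumes:
        raise FormatError(
            f"{len(rotations)} rotations for {gtab.n_volumes} volumes"
        )
    for R in rotations:
        if R.shape != (3, 3):
            raise FormatError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise FormatError("matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise FormatError("matrix is not a proper rotation (det != +1)")
    bvecs = np.array(
        [R @ v for R, v in zip(rotations, gtab.bvecs)]
    )
    return GradientTable(gtab.bvals.copy(), bvecs)


# --- TrackVis TRK ----------------------------------------------------------


def write_tractogram(tractogram: Tractogram, trk_path) -> None:
    """Write streamlines to TrackVis TRK (points converted from RAS+ mm)."""
    grid = tractogram.grid
    sl = nib.streamlines.Tractogram(
        tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    header = {
        "voxel_sizes": np.asarray(grid.voxel_size, dtype=np.float32),
        "dimensions": np.asarray(grid.shape, dtype=np.int16),
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_order": "".join(nib.aff2axcodes(grid.affine)),
    }
    nib.streamlines.save(sl, str(trk_path), header=header)


def read_tractogram(trk_path, grid: ImageGrid = None,
                    step_mm: float = None) -> Tractogram:
    """Read a TRK file back into RAS+ mm world coordinates.

    If ``grid`` is given, the header geometry must match it.
    """
    trk = nib.streamlines.load(str(trk_path))
    hdr = trk.header
    hdr_grid = ImageGrid(
        tuple(int(d) for d in hdr["dimensions"]),
        np.asarray(hdr["voxel_to_rasmm"], dtype=float),
    )
    if grid is not None and not grid.same_grid(hdr_grid, atol=1e-3):
        raise FormatError("TRK header geometry does not match expected grid")
    streamlines = [np.asarray(s, dtype=float) for s in trk.streamlines]
    if step_mm is None:
        if streamlines:
            step_mm = float(np.linalg.norm(np.diff(streamlines[0], axis=0),
                                           axis=1).mean())
        else:
            step_mm = float(np.min(hdr_grid.voxel_size)) / 2.0
    out_grid = grid if grid is not None else hdr_grid
    return Tractogram(streamlines, out_grid, step_mm)
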