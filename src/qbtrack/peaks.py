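"""Fiber-direction peaks of sampled ODFs.

Candidate peaks are strict local maxima of the (nonnegativity-clipped) ODF
over the tessellation's vertex adjacency graph, identified modulo the
antipodal map.  Candidates are then retained greedily in descending value
order subject to two rejection rules: a peak closer than 45 degrees to an
already-retained (larger) peak is dropped, and a peak whose value is below
0.25 times the maximum of the ODF is dropped.  The relative threshold is
measured above the ODF's minimum over the sphere: constant-solid-angle ODFs
carry an isotropic 1/(4*pi) baseline, and subtracting it first is what makes
a relative threshold meaningful (the convention of the reference peak
extraction this rule descends from).  Ties in value are broken by vertex
index, so the result is order-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import Sphere

DEFAULT_MIN_SEPARATION_DEG = 45.0
DEFAULT_RELATIVE_THRESHOLD = 0.25
DEFAULT_MAX_PEAKS = 3


@dataclass
class PeakSet:
    """Up to K fiber axes (unit vectors, upper hemisphere) with ODF values,
    sorted by descending value."""

    directions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_empty(self) -> bool:
        return len(self.values) == 0


def local_maxima(values: np.ndarray, sphere: Sphere) -> np.ndarray:
    """Indices of strict local maxima on the vertex adjacency graph."""
    padded = np.append(values, -np.inf)  # -1 padding rows hit the sentinel
    nbr_vals = padded[sphere.neighbors]
    return np.nonzero(values > nbr_vals.max(axis=1))[0]


def find_peaks(odf_values: np.ndarray, sphere: Sphere,
               min_separation_deg: float = DEFAULT_MIN_SEPARATION_DEG,
               relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
               max_peaks: int = DEFAULT_MAX_PEAKS) -> PeakSet:
    """Extract refined fiber-direction peaks from ODF samples on the sphere.

    ``odf_values`` are values at every vertex of ``sphere`` (full sphere; the
    function is antipodally symmetric up to rounding).  Negative lobes are
    clipped to zero before peak logic.
    """
    v = np.clip(np.asarray(odf_values, dtype=float), 0.0, None)
    if len(v) != sphere.n_vertices:
        raise ValueError("ODF sample count does not match sphere")

    cand = local_maxima(v, sphere)
    if len(cand) == 0:
        return PeakSet()

    # antipodal identification: collapse each candidate to the smaller index
    # of its pair, keeping the larger of the two sampled values
    rep = np.minimum(cand, sphere.antipode[cand])
    uniq = {}
    for r, i in zip(rep, cand):
        if r not in uniq or v[i] > v[uniq[r]]:
            uniq[r] = i
    cand = np.array(sorted(uniq.values()), dtype=np.int64)

    # relative threshold above the isotropic baseline of the sampled ODF
    vmin = v.min()
    floor = vmin + relative_threshold * (v.max() - vmin)
    cand = cand[v[cand] >= floor]
    if len(cand) == 0:
        return PeakSet()

    # descending value, ties by vertex index (stable, lexicographic)
    order = np.lexsort((cand, -v[cand]))
    cand = cand[order]

    cos_min = np.cos(np.radians(min_separation_deg))
    kept = []
    for idx in cand:
        u = sphere.vertices[idx]
        too_close = any(
            abs(float(np.dot(u, sphere.vertices[j]))) > cos_min
            for j in kept
        )
        if not too_close:
            kept.append(idx)
        if len(kept) >= max_peaks:
            break

    dirs = sphere.vertices[kept].copy()
    # store axes in the upper hemisphere (z > 0; ties resolved by y then x)
    for k, d in enumerate(dirs):
        if d[2] < -1e-12 or (
            abs(d[2]) <= 1e-12
            and (d[1] < -1e-12 or (abs(d[1]) <= 1e-12 and d[0] < 0))
        ):
            dirs[k] = -d
    return PeakSet(dirs, v[kept].copy() if kept else np.empty(0))
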