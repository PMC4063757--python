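"""Residual bootstrap of the per-voxel spherical-harmonic fit.

The linear model y = B c + r (y the double-log attenuation) is resampled by
drawing leverage-corrected residuals r~_i = r_i / sqrt(1 - h_i) with
replacement, adding them back to the fitted values, refitting through the
cached pseudo-inverse and applying the CSA transform.  One fresh ODF is drawn
per (streamline, voxel-visit) during tracking.

Randomness is counter-based: every draw is keyed by
(master seed, streamline id, step index) through a Philox bit generator, so
results are reproducible regardless of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .qball import SHCoefficients, SignalFit, csa_odf, csa_odf_coefficients


@dataclass
class BootstrapModel:
    """Everything needed to draw bootstrap ODFs without re-reading the DWI."""

    fitted: np.ndarray             # (..., Nd)
    corrected_residuals: np.ndarray  # (..., Nd)
    pinv: np.ndarray               # (R, Nd)
    hat_diag: np.ndarray           # (Nd,)
    valid: np.ndarray              # (...,)
    L: int

    @property
    def n_directions(self) -> int:
        return self.fitted.shape[-1]


def prepare_bootstrap(fit: SignalFit) -> BootstrapModel:
    """Leverage-correct the residuals of a signal fit.

    Directions with hat-matrix diagonal >= 1 carry no residual information
    (the fit interpolates them exactly); they are dropped with a warning.
    """
    h = fit.hat_diag
    keep = h < 1.0 - 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate design row(s) "
            "with leverage >= 1",
            stacklevel=2,
        )
        B = fit.design[keep]
        pinv = np.linalg.pinv(B)
        y = fit.transformed[..., keep]
        coeffs = y @ pinv.T
        fitted = coeffs @ B.T
        residuals = y - fitted
        h = np.einsum("ij,ji->i", B, pinv)
    else:
        pinv = fit.pinv
        fitted = fit.fitted
        residuals = fit.residuals
    corrected = residuals / np.sqrt(1.0 - h)
    return BootstrapModel(
        fitted=fitted,
        corrected_residuals=corrected,
        pinv=pinv,
        hat_diag=h,
        valid=fit.valid,
        L=fit.sh.L,
    )


def philox_rng(master_seed: int, streamline_id: int = 0,
               step: int = 0) -> np.random.Generator:
    """Counter-based generator keyed by (seed, streamline, step)."""
    key = (
        ((int(master_seed) & 0xFFFFFFFFFFFF) << 80)
        | ((int(streamline_id) & 0xFFFFFFFFFF) << 40)
        | (int(step) & 0xFFFFFFFFFF)
    )
    return np.random.Generator(np.random.Philox(key=key))


def bootstrap_sh(model: BootstrapModel, voxel_index,
                 rng: np.random.Generator) -> np.ndarray:
    """One bootstrap replicate of the signal SH coefficients at a voxel."""
    fitted = model.fitted[voxel_index]
    resid = model.corrected_residuals[voxel_index]
    n = model.n_directions
    draw = rng.integers(0, n, size=n)
    y_star = fitted + resid[draw]
    return y_star @ model.pinv.T


def bootstrap_odf(model: BootstrapModel, voxel_index,
                  rng: np.random.Generator) -> SHCoefficients:
    """One bootstrap CSA ODF (as SH coefficients) at a voxel."""
    coeffs = bootstrap_sh(model, voxel_index, rng)
    return csa_odf(SHCoefficients(coeffs, model.L))


class OdfSampler:
    """Vector-friendly helper binding a model to a sampling sphere.

    Precomputes the product of the design pseudo-inverse, the CSA multipliers
    and the sphere sampling matrix so a per-visit draw is two small matvecs.
    """

    def __init__(self, model: BootstrapModel, sampling_matrix: np.ndarray):
        self.model = model
        mult = csa_odf_coefficients(model.L)
        # odf_values = M @ (mult * (pinv @ y)) + iso term
        self._proj = (sampling_matrix * mult[None, :]) @ model.pinv
        self._iso = sampling_matrix[:, 0] / np.sqrt(4.0 * np.pi)

    def draw(self, voxel_index, rng: np.random.Generator) -> np.ndarray:
        """ODF values on the sphere for one bootstrap draw at a voxel."""
        fitted = self.model.fitted[voxel_index]
        resid = self.model.corrected_residuals[voxel_index]
        n = self.model.n_directions
        idx = rng.integers(0, n, size=n)
        return self._proj @ (fitted + resid[idx]) + self._iso

    def mean(self, voxel_index) -> np.ndarray:
        """ODF values from the original (non-resampled) fit."""
        return self._proj @ self.model.fitted[voxel_index] + self._iso
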