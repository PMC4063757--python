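"""Constant-solid-angle q-ball reconstruction.

The diffusion attenuation E = S/S0 is transformed to ln(-ln E) and fit with
real symmetric spherical harmonics of even order up to L (default 4, 15
coefficients).  The ODF then follows per harmonic in closed form: the
Laplace-Beltrami operator multiplies by -l(l+1), the Funk-Radon transform by
2*pi*P_l(0), and the 1/(16*pi^2) solid-angle factor plus the isotropic
1/(4*pi) term complete the estimator.  The resulting ODF integrates to 1
exactly (the l=0 coefficient is pinned to 1/sqrt(4*pi)).

Basis convention ("qbtrack-real-sym"): orthonormal real harmonics ordered by
(l, m) with l = 0, 2, ..., L and m = -l..l; m < 0 maps to sqrt(2)*Im(Y_l^|m|),
m = 0 to Y_l^0, m > 0 to sqrt(2)*Re(Y_l^m), Condon-Shortley phase included.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.special import eval_legendre, lpmv

from .formats import DWIVolume, FormatError, GradientTable, ImageGrid
from .sphere import cart2sphere

BASIS_TAG = "qbtrack-real-sym"

#: attenuation clamp applied before the double-log transform
DEFAULT_EPS = 1e-3


class ContractError(ValueError):
    """Input carries the wrong basis tag or violates a module contract."""


def sh_degrees(L: int):
    """(l, m) pairs of the even-order basis in the package's fixed ordering."""
    if L < 0 or L % 2:
        raise ContractError(f"L must be even and >= 0, got {L}")
    return [(l, m) for l in range(0, L + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(L: int) -> int:
    return (L + 1) * (L + 2) // 2


def real_sym_sh_basis(L: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the real symmetric basis at unit ``directions`` -> (N, R)."""
    theta, phi = cart2sphere(directions)
    x = np.cos(theta)
    cols = []
    for l, m in sh_degrees(L):
        am = abs(m)
        norm = np.sqrt(
            (2 * l + 1) / (4 * np.pi) * factorial(l - am) / factorial(l + am)
        )
        P = lpmv(am, l, x)
        if m == 0:
            cols.append(norm * P)
        elif m > 0:
            cols.append(np.sqrt(2.0) * norm * P * np.cos(am * phi))
        else:
            cols.append(np.sqrt(2.0) * norm * P * np.sin(am * phi))
    return np.stack(cols, axis=-1)


def build_design_matrix(gtab: GradientTable, L: int = 4) -> np.ndarray:
    """SH design matrix at the non-b0 gradient directions (rows=directions)."""
    R = n_coefficients(L)
    dirs = gtab.gradients
    if len(dirs) < R:
        raise ContractError(
            f"{len(dirs)} directions cannot determine {R} SH coefficients"
        )
    return real_sym_sh_basis(L, dirs)


@dataclass
class SHCoefficients:
    """Per-voxel real SH coefficient vectors plus the basis convention tag."""

    coeffs: np.ndarray  # (..., R)
    L: int
    basis: str = BASIS_TAG

    def __post_init__(self) -> None:
        if self.coeffs.shape[-1] != n_coefficients(self.L):
            raise ContractError(
                f"expected {n_coefficients(self.L)} coefficients for L={self.L}"
            )


@dataclass
class SignalFit:
    """Least-squares SH fit of ln(-ln E) with everything the residual
    bootstrap needs: fitted values, residuals and the hat-matrix diagonal."""

    sh: SHCoefficients
    design: np.ndarray        # (Nd, R)
    pinv: np.ndarray          # (R, Nd) cached pseudo-inverse
    fitted: np.ndarray        # (..., Nd) in transformed-signal units
    residuals: np.ndarray     # (..., Nd)
    hat_diag: np.ndarray      # (Nd,)
    valid: np.ndarray         # (...,) bool, False where signal was unusable
    eps: float

    @property
    def transformed(self) -> np.ndarray:
        return self.fitted + self.residuals


def double_log_transform(E: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """ln(-ln E) with E clamped to [eps, 1-eps] (undefined at 0 and 1)."""
    E = np.clip(E, eps, 1.0 - eps)
    return np.log(-np.log(E))


def fit_signal_sh(dwi: DWIVolume, L: int = 4, eps: float = DEFAULT_EPS,
                  mask: np.ndarray = None) -> SignalFit:
    """Fit ln(-ln(S/S0)) in the SH basis, voxelwise, by linear least squares."""
    B = build_design_matrix(dwi.gtab, L)
    pinv = np.linalg.pinv(B)
    hat_diag = np.einsum("ij,ji->i", B, pinv)

    S0 = dwi.b0_reference()
    S = dwi.diffusion_signal()
    valid = (S0 > 0) & np.all(np.isfinite(S), axis=-1)
    if mask is not None:
        valid &= mask.astype(bool)

    E = np.ones_like(S)
    np.divide(S, S0[..., None], out=E, where=valid[..., None])
    y = double_log_transform(E, eps)
    y[~valid] = 0.0

    coeffs = y @ pinv.T
    fitted = coeffs @ B.T
    residuals = y - fitted
    return SignalFit(
        sh=SHCoefficients(coeffs, L),
        design=B,
        pinv=pinv,
        fitted=fitted,
        residuals=residuals,
        hat_diag=hat_diag,
        valid=valid,
        eps=eps,
    )


def csa_odf_coefficients(L: int) -> np.ndarray:
    """Per-coefficient multipliers of the CSA transform (l=0 slot unused)."""
    mult = np.empty(n_coefficients(L))
    for k, (l, m) in enumerate(sh_degrees(L)):
        if l == 0:
            mult[k] = 0.0
        else:
            mult[k] = -l * (l + 1) * 2.0 * np.pi * eval_legendre(l, 0.0) \
                / (16.0 * np.pi ** 2)
    return mult


def csa_odf(sig_sh: SHCoefficients) -> SHCoefficients:
    """Closed-form CSA ODF from the SH fit of the double-log attenuation."""
    if sig_sh.basis != BASIS_TAG:
        raise ContractError(f"unexpected basis tag {sig_sh.basis!r}")
    mult = csa_odf_coefficients(sig_sh.L)
    out = sig_sh.coeffs * mult
    out[..., 0] = 1.0 / np.sqrt(4.0 * np.pi)  # unit sphere integral
    return SHCoefficients(out, sig_sh.L, BASIS_TAG)


def evaluate_sh(sh: SHCoefficients, directions: np.ndarray,
                sampling_matrix: np.ndarray = None) -> np.ndarray:
    """Evaluate SH-represented functions at unit directions."""
    M = sampling_matrix
    if M is None:
        M = real_sym_sh_basis(sh.L, directions)
    return sh.coeffs @ M.T


# ---------------------------------------------------------------------------
# diffusion tensor / FA


@dataclass
class ScalarVolume:
    values: np.ndarray
    grid: ImageGrid


@dataclass
class TensorFit:
    evals: np.ndarray   # (..., 3) descending, clipped at 0
    evecs: np.ndarray   # (..., 3, 3) columns are eigenvectors
    valid: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        return self.evecs[..., :, 0]


def _tensor_design(gtab: GradientTable) -> np.ndarray:
    g = gtab.gradients
    b = gtab.gradient_bvals
    cols = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    return -b[:, None] * cols


def fit_tensor(dwi: DWIVolume, mask: np.ndarray = None) -> TensorFit:
    """Unweighted log-linear least-squares single-tensor fit."""
    g = dwi.gtab.gradients
    if len(g) < 6 or np.linalg.matrix_rank(_tensor_design(dwi.gtab)) < 6:
        raise ContractError("need >= 6 non-collinear diffusion directions")
    A = _tensor_design(dwi.gtab)
    pinv = np.linalg.pinv(A)

    S0 = dwi.b0_reference()
    S = dwi.diffusion_signal()
    valid = (S0 > 0) & np.all(S > 0, axis=-1)
    if mask is not None:
        valid &= mask.astype(bool)

    logE = np.zeros_like(S)
    np.log(np.divide(S, S0[..., None], out=np.ones_like(S),
                     where=valid[..., None]),
           out=logE, where=valid[..., None])
    d = logE @ pinv.T  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    D = np.zeros(d.shape[:-1] + (3, 3))
    D[..., 0, 0] = d[..., 0]
    D[..., 1, 1] = d[..., 1]
    D[..., 2, 2] = d[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = d[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = d[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = d[..., 5]
    evals, evecs = np.linalg.eigh(D)
    evals = np.clip(evals[..., ::-1], 0.0, None)  # descending, nonneg
    evecs = evecs[..., ::-1]
    evals[~valid] = 0.0
    return TensorFit(evals, evecs, valid)


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy: normalized eigenvalue variance, in [0, 1]."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals ** 2, axis=-1)
    fa = np.zeros_like(num)
    np.divide(num, den, out=fa, where=den > 0)
    return np.sqrt(1.5 * fa)


def fit_tensor_fa(dwi: DWIVolume, mask: np.ndarray = None) -> ScalarVolume:
    """FA map from the log-linear tensor fit (invalid voxels get FA = 0)."""
    tf = fit_tensor(dwi, mask=mask)
    fa = fa_from_evals(tf.evals)
    fa[~tf.valid] = 0.0
    return ScalarVolume(np.clip(fa, 0.0, 1.0), dwi.grid)
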