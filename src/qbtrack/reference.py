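"""Independent numerical reference for the constant-solid-angle ODF.

This module deliberately shares no code with :mod:`qbtrack.qball`: the basis
is assembled from scipy's *complex* spherical harmonics, the least-squares
fit uses ``numpy.linalg.lstsq``, and the Funk-Radon transform is evaluated by
direct quadrature of great-circle integrals instead of the closed-form
2*pi*P_l(0) eigenvalue.  For band-limited integrands (order <= L) the
trapezoid rule on the circle is exact, so the route is a genuine
cross-check at machine precision, just much slower.

Definition checked:  ODF(u) = 1/(4*pi)
                       + 1/(16*pi^2) * FRT{Laplace-Beltrami ln(-ln E)}(u),
with the Laplace-Beltrami operator applied per harmonic (-l(l+1)).
"""

from __future__ import annotations

import numpy as np

try:  # scipy >= 1.15
    from scipy.special import sph_harm_y as _sph_harm_y
except ImportError:  # pragma: no cover
    from scipy.special import sph_harm as _sph_harm

    def _sph_harm_y(l, m, theta, phi):
        return _sph_harm(m, l, phi, theta)


def _angles(directions):
    d = np.atleast_2d(directions)
    theta = np.arccos(np.clip(d[:, 2], -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def _real_basis(L, directions):
    """Real symmetric orthonormal SH basis from complex harmonics."""
    theta, phi = _angles(directions)
    cols = []
    lms = []
    for l in range(0, L + 1, 2):
        for m in range(-l, l + 1):
            Y = _sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(Y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * Y.real)
            else:
                cols.append(np.sqrt(2.0) * Y.imag)
            lms.append((l, m))
    return np.stack(cols, axis=-1), lms


def _great_circle(u, n_points):
    """Unit points on the great circle perpendicular to axis ``u``."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.cos(t)[:, None] * e1 + np.sin(t)[:, None] * e2


def reference_csa_odf(signal, b0, gradient_dirs, eval_dirs, L=4,
                      eps=1e-3, n_circle=64):
    """CSA ODF values at ``eval_dirs`` for one voxel, by the numerical route.

    Parameters
    ----------
    signal : (Nd,) diffusion-weighted signal at ``gradient_dirs``.
    b0 : non-diffusion-weighted reference signal.
    gradient_dirs : (Nd, 3) unit directions.
    eval_dirs : (M, 3) unit directions at which to evaluate the ODF.
    """
    E = np.clip(np.asarray(signal, dtype=float) / float(b0), eps, 1.0 - eps)
    y = np.log(-np.log(E))

    B, lms = _real_basis(L, gradient_dirs)
    coeffs, *_ = np.linalg.lstsq(B, y, rcond=None)

    # Laplace-Beltrami in the SH domain (analytic eigenvalue), then numerical
    # Funk-Radon transform by great-circle quadrature.
    lb = coeffs * np.array([-l * (l + 1) for l, _ in lms], dtype=float)

    eval_dirs = np.atleast_2d(eval_dirs)
    out = np.empty(len(eval_dirs))
    for i, u in enumerate(eval_dirs):
        circle = _great_circle(u, n_circle)
        Bc, _ = _real_basis(L, circle)
        g = Bc @ lb
        frt = 2.0 * np.pi * g.mean()  # arc-length integral over the circle
        out[i] = 1.0 / (4.0 * np.pi) + frt / (16.0 * np.pi ** 2)
    return out
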