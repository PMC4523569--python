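"""Normalization constants, Lommel integrals and orthogonality checks.

Closed forms are expressed through the derivative ratio
``J'_nu(lam)/J'_nu(gamma lam)`` (resp. the spherical j'-ratio) and Lommel
functions; adaptive quadrature on the nondimensional coordinate rho = r/R
serves as the independent verification oracle.  All routines work in units
of R internally; R re-enters only at I/O.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np
from scipy import integrate

from .eigenvalues import ModeTable
from .geometry import check_dim
from .special import (
    bessel_cross,
    deriv_ratio,
    lommel_S,
    lommel_S_deriv,
    radial_eigenfunction,
    radial_eigenfunction_deriv,
)

Complex = Union[float, complex]

__all__ = [
    "generalized_moment_identity",
    "lommel_integral",
    "lommel_integral_quadrature",
    "normalization",
    "normalization_general",
    "normalization_quadrature",
    "orthogonality_gram",
]

#: maximum admissible Newton distance-to-root |f/f'| (relative to lambda) for
#: a value claiming to be a polished zero; a machine-precision zero sits near
#: 1e-15 while anything between zeros is of the order of the root spacing
ZERO_RESIDUAL_TOL = 1e-8

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-10, limit=400)


def _require_zero(dim: str, nu: Complex, lam: Complex, gamma: float) -> None:
    h = 1e-6 * max(1.0, abs(lam))
    f0 = bessel_cross(dim, nu, gamma, lam)
    fp = (bessel_cross(dim, nu, gamma, lam + h)
          - bessel_cross(dim, nu, gamma, lam - h)) / (2 * h)
    dist = abs(f0) / max(abs(fp), 1e-300)
    if dist > ZERO_RESIDUAL_TOL * max(1.0, abs(lam)):
        raise ValueError(
            f"lam={lam} is not a polished cross-product zero "
            f"(Newton distance {dist:.3g})"
        )


# ---------------------------------------------------------------------------
# Normalization constants
# ---------------------------------------------------------------------------

def normalization(dim: str, nu: Complex, lam: Complex, gamma: float) -> Complex:
    """Closed-form normalization constant of the radial Neumann eigenfunction.

    Annulus:  ``N = 2/(pi^2 lam^2) { [1 - nu^2/(gamma^2 lam^2)] rho_J^2
    - [1 - nu^2/lam^2] }`` with ``rho_J = J'_nu(lam)/J'_nu(gamma lam)``;
    spherical shell: the analogous j'-ratio form.  Dimensionless in units of
    R^2 (2D) resp. R^3 (3D); real and positive for real nu at a real zero.
    """
    check_dim(dim)
    _require_zero(dim, nu, lam, gamma)
    rho = deriv_ratio(dim, nu, lam, gamma)
    if dim == "cyl":
        pref = 2.0 / (math.pi**2 * lam**2)
        return pref * ((1 - nu**2 / (gamma**2 * lam**2)) * rho**2 - (1 - nu**2 / lam**2))
    c = nu * (nu + 1)
    return (
        1.0 / (2 * gamma * lam**4) * rho**2 * (1 - c / (gamma**2 * lam**2))
        + 1.0 / (2 * lam**4) * (c / lam**2 - 1)
    )


def normalization_general(dim: str, nu: Complex, lam: Complex, gamma: float) -> Complex:
    """Normalization from the general boundary-term expression for an
    arbitrary linear combination of (spherical) Bessel functions, evaluated
    numerically at the shell boundaries (the Neumann derivative terms are kept
    and evaluate to ~0 at a zero).  Specializing it must reproduce
    :func:`normalization`."""
    check_dim(dim)

    def at(t: float) -> Complex:
        val = radial_eigenfunction(dim, nu, lam, t)
        # derivative with respect to the Bessel argument z = lam*t
        dval = radial_eigenfunction_deriv(dim, nu, lam, t) / lam
        if dim == "cyl":
            return (
                t**2 / 2.0 * (1 - nu**2 / (lam**2 * t**2)) * val**2
                + t**2 / 2.0 * dval**2
            )
        return (
            t / 2.0 * (t**2 - nu * (nu + 1) / lam**2) * val**2
            + t**2 / (2.0 * lam) * val * dval
            + t**3 / 2.0 * dval**2
        )

    return at(gamma) - at(1.0)


def normalization_quadrature(dim: str, nu: Complex, lam: Complex, gamma: float) -> Complex:
    """(1/R^dim) integral of the weighted squared eigenfunction by adaptive
    quadrature — the independent oracle for :func:`normalization`."""
    check_dim(dim)
    w = 1 if dim == "cyl" else 2
    return _quad_complex(
        lambda t: t**w * radial_eigenfunction(dim, nu, lam, t) ** 2, 1.0, gamma
    )


# ---------------------------------------------------------------------------
# Lommel integrals
# ---------------------------------------------------------------------------

def lommel_integral(dim: str, alpha: Complex, nu: Complex, lam: Complex,
                    gamma: float) -> Complex:
    """Closed-form weighted integral ``(1/R^(alpha+1)) int_R^{gamma R} r^alpha
    Phi (resp. psi) dr`` at a cross-product zero.

    The annulus form uses the Lommel-function derivative at both boundaries;
    the shell form uses the pair of half-integer-order Lommel functions.
    Lommel pole errors propagate with the offending (kappa, nu) pair named.
    """
    check_dim(dim)
    _require_zero(dim, nu, lam, gamma)
    rho = deriv_ratio(dim, nu, lam, gamma)
    if dim == "cyl":
        try:
            d_outer = lommel_S_deriv(alpha, nu, gamma * lam)
            d_inner = lommel_S_deriv(alpha, nu, lam)
        except Exception as exc:
            raise type(exc)(
                f"S'_({alpha},{nu}) evaluation failed: {exc}"
            ) from exc
        return 2.0 / (math.pi * lam ** (alpha + 1)) * (rho * d_outer - d_inner)
    k1, n1 = alpha - 1.5, nu + 1.5
    k2, n2 = alpha - 0.5, nu + 0.5
    c1, c2 = alpha - nu - 2, nu
    # a vanishing prefactor removes its Lommel term entirely (this is exactly
    # how the alpha=2, nu=0 orthogonality-to-constant case arises)
    S1o = S1i = S2o = S2i = 0.0
    try:
        if abs(c1) > 0:
            S1o = lommel_S(k1, n1, gamma * lam)
            S1i = lommel_S(k1, n1, lam)
        if abs(c2) > 0:
            S2o = lommel_S(k2, n2, gamma * lam)
            S2i = lommel_S(k2, n2, lam)
    except Exception as exc:
        raise type(exc)(
            f"S_({k1},{n1}) or S_({k2},{n2}) evaluation failed: {exc}"
        ) from exc
    pref = lam ** -(2.5 + alpha)
    outer = gamma**-1.5 * rho * (gamma * lam * c1 * S1o + c2 * S2o)
    inner = lam * c1 * S1i + c2 * S2i
    return pref * (outer - inner)


def lommel_integral_quadrature(dim: str, alpha: Complex, nu: Complex, lam: Complex,
                               gamma: float) -> Complex:
    """Adaptive-quadrature oracle for :func:`lommel_integral`."""
    check_dim(dim)
    return _quad_complex(
        lambda t: t**alpha * radial_eigenfunction(dim, nu, lam, t), 1.0, gamma
    )


def generalized_moment_identity(dim: str, nu: Complex, lam: Complex, gamma: float) -> float:
    """Residual of the integrated radial Bessel equation,

    ``int rho^w [c_nu/rho^2 - lam^2] Phi(rho) drho = 0``

    with weight w=1, c_nu=nu^2 (2D) or w=2, c_nu=nu(nu+1) (3D).  Vanishes at
    every cross-product zero; the returned number is the quadrature value."""
    check_dim(dim)
    w = 1 if dim == "cyl" else 2
    c = nu**2 if dim == "cyl" else nu * (nu + 1)
    val = _quad_complex(
        lambda t: t**w * (c / t**2 - lam**2) * radial_eigenfunction(dim, nu, lam, t),
        1.0,
        gamma,
    )
    return abs(val)


# ---------------------------------------------------------------------------
# Gram matrix
# ---------------------------------------------------------------------------

def orthogonality_gram(dim: str, nu: Complex, gamma: float, modes: ModeTable) -> np.ndarray:
    """Quadrature Gram matrix of the radial eigenfunctions.

    Weight r (2D) resp. r^2 (3D); the bilinear (non-conjugated) product is
    used, so the matrix is symmetric also for complex order.  Off-diagonals
    vanish by Sturm-Liouville orthogonality; diagonals equal the closed-form
    normalization constants.
    """
    check_dim(dim)
    lams = [e.lam for e in modes.entries]
    w = 1 if dim == "cyl" else 2
    k = len(lams)
    cplx = any(abs(complex(l).imag) > 0 for l in lams) or abs(complex(nu).imag) > 0
    G = np.zeros((k, k), dtype=complex if cplx else float)
    for i in range(k):
        for j in range(i, k):
            val = _quad_complex(
                lambda t: t**w
                * radial_eigenfunction(dim, nu, lams[i], t)
                * radial_eigenfunction(dim, nu, lams[j], t),
                1.0,
                gamma,
            )
            G[i, j] = G[j, i] = val if cplx else val.real
    return G


def _quad_complex(fn, a: float, b: float) -> complex:
    re, re_err = integrate.quad(lambda t: np.real(fn(t)), a, b, **_QUAD_OPTS)
    im, im_err = integrate.quad(lambda t: np.imag(fn(t)), a, b, **_QUAD_OPTS)
    if not (np.isfinite(re) and np.isfinite(im)):
        raise RuntimeError(f"quadrature failed on [{a}, {b}]")
    return complex(re, im)
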