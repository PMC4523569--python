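"""Cross products, radial eigenfunctions and Lommel functions.

Everything downstream (eigenvalue location, normalization constants,
Lommel integrals, the diffusion model) consumes the functions defined here.

The radial Neumann eigenfunctions on the shell ``R <= r <= gamma R`` are

* annulus:          ``Phi_nu(rho) = Y'_nu(lam) J_nu(lam rho) - J'_nu(lam) Y_nu(lam rho)``
* spherical shell:  ``psi_nu(rho) = y'_nu(lam) j_nu(lam rho) - j'_nu(lam) y_nu(lam rho)``

with ``rho = r/R``; the eigenvalues ``lam`` are the zeros of the derivative
cross products ``f_nu`` / ``g_nu`` evaluated by :func:`bessel_cross`.

Real Bessel orders go through scipy's double-precision routines (which accept
complex arguments); complex orders fall back to arbitrary-precision series
evaluation via mpmath at a configurable working precision.
"""

from __future__ import annotations

import cmath
import math
import warnings
from typing import Union

import mpmath
import numpy as np
from scipy import special as sc

from .geometry import check_dim

__all__ = [
    "LommelPoleError",
    "bessel_cross",
    "boundary_value_outer",
    "classical_polynomial",
    "cyl_bessel",
    "cyl_bessel_deriv",
    "gegenbauer_A",
    "lommel_S",
    "lommel_S_deriv",
    "lommel_s_small",
    "neumann_O",
    "radial_eigenfunction",
    "schlafli_S",
    "sph_bessel",
    "sph_bessel_deriv",
]

Complex = Union[float, complex]

#: working precision (significant digits) for the complex-order mpmath path
MP_DPS = 30

_SERIES_MAX_TERMS = 500
_SERIES_RTOL = 1e-16
_SERIES_RANGE = 40.0


class LommelPoleError(ValueError):
    """Raised when no finite evaluation route exists for S_{kappa,nu}."""


def _is_real(x: Complex, tol: float = 0.0) -> bool:
    return abs(complex(x).imag) <= tol


# ---------------------------------------------------------------------------
# Bessel functions of real or complex order
# ---------------------------------------------------------------------------

def cyl_bessel(kind: str, nu: Complex, z):
    """J_nu(z) (kind='j') or Y_nu(z) (kind='y') for real or complex order."""
    if _is_real(nu):
        nu = complex(nu).real
        fn = sc.jv if kind == "j" else sc.yv
        z = np.asarray(z)
        if np.isrealobj(z) and np.all(z > 0):
            out = fn(nu, z)
        else:
            # negative or complex arguments: principal-branch continuation
            out = fn(nu, z.astype(complex))
        return out[()] if out.ndim == 0 else out
    fn = mpmath.besselj if kind == "j" else mpmath.bessely
    with mpmath.workdps(MP_DPS):
        if np.ndim(z) == 0:
            return complex(fn(complex(nu), complex(z)))
        return np.array([complex(fn(complex(nu), complex(zi))) for zi in np.ravel(z)]).reshape(np.shape(z))


def cyl_bessel_deriv(kind: str, nu: Complex, z):
    """dJ_nu/dz resp. dY_nu/dz via the symmetric recurrence (C_{nu-1}-C_{nu+1})/2."""
    return 0.5 * (cyl_bessel(kind, nu - 1, z) - cyl_bessel(kind, nu + 1, z))


def sph_bessel(kind: str, nu: Complex, z):
    """Spherical Bessel j_nu / y_nu via c_nu(z) = sqrt(pi/(2z)) C_{nu+1/2}(z)."""
    z_arr = np.asarray(z)
    real_path = np.isrealobj(z_arr) and np.all(z_arr > 0) and _is_real(nu)
    if not real_path:
        z_arr = z_arr.astype(complex)
    cyl = cyl_bessel(kind, nu + 0.5, z_arr[()] if z_arr.ndim == 0 else z_arr)
    pref = np.sqrt(np.pi / (2.0 * z_arr))
    out = np.asarray(pref * cyl)
    return out[()] if out.ndim == 0 else out


def sph_bessel_deriv(kind: str, nu: Complex, z):
    """dc_nu/dz = [nu c_{nu-1} - (nu+1) c_{nu+1}] / (2 nu + 1)."""
    return (nu * sph_bessel(kind, nu - 1, z) - (nu + 1) * sph_bessel(kind, nu + 1, z)) / (2 * nu + 1)


# ---------------------------------------------------------------------------
# Cross products and eigenfunctions
# ---------------------------------------------------------------------------

def bessel_cross(dim: str, nu: Complex, gamma: float, lam):
    """Derivative cross product whose zeros are the Neumann eigenvalues.

    ``f_nu(lam) = Y'_nu(lam) J'_nu(gamma lam) - J'_nu(lam) Y'_nu(gamma lam)``
    for ``dim='cyl'``; the spherical analogue ``g_nu`` (built from j, y) for
    ``dim='sph'``.  Real for real ``nu`` and real ``lam``; supports array
    ``lam`` for vectorized sign scans.
    """
    check_dim(dim)
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    if dim == "sph" and np.any(np.asarray(lam) == 0):
        raise ValueError("lam=0 is a pole of the spherical cross product")
    if dim == "cyl":
        ya = cyl_bessel_deriv("y", nu, lam)
        jb = cyl_bessel_deriv("j", nu, gamma * np.asarray(lam))
        ja = cyl_bessel_deriv("j", nu, lam)
        yb = cyl_bessel_deriv("y", nu, gamma * np.asarray(lam))
    else:
        ya = sph_bessel_deriv("y", nu, lam)
        jb = sph_bessel_deriv("j", nu, gamma * np.asarray(lam))
        ja = sph_bessel_deriv("j", nu, lam)
        yb = sph_bessel_deriv("y", nu, gamma * np.asarray(lam))
    out = ya * jb - ja * yb
    out = np.asarray(out)
    if not np.all(np.isfinite(out)):
        bad = np.asarray(lam)[~np.isfinite(out)] if out.ndim else lam
        raise OverflowError(f"cross product overflowed at lam={bad}")
    return out[()] if out.ndim == 0 else out


def cross_residual_relative(dim: str, nu: Complex, gamma: float, lam: Complex) -> float:
    """|cross product| relative to the magnitude of its two constituent
    products — the scale-free certificate that lam is a zero (the absolute
    cross product at a true zero is eps times the term magnitude, which grows
    rapidly with the order nu)."""
    check_dim(dim)
    if dim == "cyl":
        t1 = cyl_bessel_deriv("y", nu, lam) * cyl_bessel_deriv("j", nu, gamma * lam)
        t2 = cyl_bessel_deriv("j", nu, lam) * cyl_bessel_deriv("y", nu, gamma * lam)
    else:
        t1 = sph_bessel_deriv("y", nu, lam) * sph_bessel_deriv("j", nu, gamma * lam)
        t2 = sph_bessel_deriv("j", nu, lam) * sph_bessel_deriv("y", nu, gamma * lam)
    scale = max(abs(t1), abs(t2), 1e-300)
    return abs(t1 - t2) / scale


def radial_eigenfunction(dim: str, nu: Complex, lam: Complex, rho):
    """Radial Neumann eigenfunction at ``rho = r/R`` (rho in [1, gamma]).

    By construction the derivative with respect to rho vanishes at rho=1;
    at a cross-product zero it also vanishes at rho=gamma.  Abel's identity
    for the Wronskian fixes the inner boundary value: 2/(pi lam) for the
    annulus and 1/lam^2 for the spherical shell.
    """
    check_dim(dim)
    rho = np.asarray(rho)
    if dim == "cyl":
        out = (
            cyl_bessel_deriv("y", nu, lam) * cyl_bessel("j", nu, lam * rho)
            - cyl_bessel_deriv("j", nu, lam) * cyl_bessel("y", nu, lam * rho)
        )
    else:
        out = (
            sph_bessel_deriv("y", nu, lam) * sph_bessel("j", nu, lam * rho)
            - sph_bessel_deriv("j", nu, lam) * sph_bessel("y", nu, lam * rho)
        )
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def radial_eigenfunction_deriv(dim: str, nu: Complex, lam: Complex, rho):
    """d/drho of the radial eigenfunction (vanishes at rho=1 and, at zeros, rho=gamma)."""
    check_dim(dim)
    rho = np.asarray(rho)
    if dim == "cyl":
        out = lam * (
            cyl_bessel_deriv("y", nu, lam) * cyl_bessel_deriv("j", nu, lam * rho)
            - cyl_bessel_deriv("j", nu, lam) * cyl_bessel_deriv("y", nu, lam * rho)
        )
    else:
        out = lam * (
            sph_bessel_deriv("y", nu, lam) * sph_bessel_deriv("j", nu, lam * rho)
            - sph_bessel_deriv("j", nu, lam) * sph_bessel_deriv("y", nu, lam * rho)
        )
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def boundary_value_outer(dim: str, nu: Complex, lam: Complex, gamma: float,
                         check_tol: float = 1e-8) -> Complex:
    """Eigenfunction value at the outer boundary rho=gamma via the Wronskian.

    Valid only when ``lam`` is a polished cross-product zero; the J'-ratio and
    Y'-ratio forms are both evaluated and must agree (their disagreement flags
    a stale, non-zero ``lam``).
    """
    check_dim(dim)
    if gamma == 1.0:
        return 2.0 / (math.pi * lam) if dim == "cyl" else 1.0 / lam**2
    if dim == "cyl":
        pref = 2.0 / (math.pi * gamma * lam)
        rj = cyl_bessel_deriv("j", nu, lam) / cyl_bessel_deriv("j", nu, gamma * lam)
        ry = cyl_bessel_deriv("y", nu, lam) / cyl_bessel_deriv("y", nu, gamma * lam)
    else:
        pref = 1.0 / (gamma**2 * lam**2)
        rj = sph_bessel_deriv("j", nu, lam) / sph_bessel_deriv("j", nu, gamma * lam)
        ry = sph_bessel_deriv("y", nu, lam) / sph_bessel_deriv("y", nu, gamma * lam)
    if abs(rj - ry) > check_tol * max(abs(rj), abs(ry), 1.0):
        raise ValueError(
            f"J'-ratio and Y'-ratio forms disagree ({rj} vs {ry}): "
            f"lam={lam} is not a cross-product zero"
        )
    return pref * rj


def deriv_ratio(dim: str, nu: Complex, lam: Complex, gamma: float) -> Complex:
    """J'_nu(lam)/J'_nu(gamma lam) (cyl) resp. j'-ratio (sph), as used in the
    closed-form normalization constants and Lommel integrals.

    At a cross-product zero the J'- and Y'-ratios coincide; the pair with the
    better-conditioned denominator is used, because for nu >> lam the zero can
    sit exponentially close to a zero of one of the two outer derivatives.
    """
    check_dim(dim)
    if dim == "cyl":
        jn, jd = cyl_bessel_deriv("j", nu, lam), cyl_bessel_deriv("j", nu, gamma * lam)
        yn, yd = cyl_bessel_deriv("y", nu, lam), cyl_bessel_deriv("y", nu, gamma * lam)
    else:
        jn, jd = sph_bessel_deriv("j", nu, lam), sph_bessel_deriv("j", nu, gamma * lam)
        yn, yd = sph_bessel_deriv("y", nu, lam), sph_bessel_deriv("y", nu, gamma * lam)
    # J' and Y' share their oscillation amplitude at gamma*lam, so the larger
    # denominator is the one farther from a catastrophic cancellation
    if abs(jd) >= abs(yd):
        return jn / jd
    return yn / yd


# ---------------------------------------------------------------------------
# Lommel functions
# ---------------------------------------------------------------------------

def _near_nonpositive_int(x: Complex, tol: float = 1e-12) -> bool:
    x = complex(x)
    return abs(x.imag) <= tol and x.real <= tol and abs(x.real - round(x.real)) <= tol


def _near_int(x: Complex, tol: float = 1e-12):
    x = complex(x)
    if abs(x.imag) <= tol and abs(x.real - round(x.real)) <= tol:
        return int(round(x.real))
    return None


def lommel_s_small(kappa: Complex, nu: Complex, z: Complex) -> Complex:
    """Lommel function of the first kind,

    ``s_{kappa,nu}(z) = z^{kappa+1}/((kappa+1)^2 - nu^2)
                        * 1F2(1; (kappa-nu+3)/2, (kappa+nu+3)/2; -z^2/4)``.

    The 1F2 series is truncated at relative term size 1e-16 (at most 500
    terms); arguments beyond ``|z| ~ 40`` trigger a range warning because no
    asymptotic continuation is implemented.
    """
    denom = (kappa + 1) ** 2 - nu**2
    if abs(denom) < 1e-14:
        raise LommelPoleError(f"(kappa+1)^2 = nu^2 pole at kappa={kappa}, nu={nu}")
    a = (kappa - nu + 3) / 2
    b = (kappa + nu + 3) / 2
    if _near_nonpositive_int(a) or _near_nonpositive_int(b):
        raise LommelPoleError(
            f"1F2 lower parameter is a non-positive integer for kappa={kappa}, nu={nu}"
        )
    if abs(z) > _SERIES_RANGE:
        warnings.warn(
            f"|z|={abs(z):.3g} beyond the validated series range {_SERIES_RANGE}",
            RuntimeWarning,
            stacklevel=2,
        )
    w = -complex(z) ** 2 / 4.0
    term = 1.0 + 0j
    total = term
    for k in range(1, _SERIES_MAX_TERMS + 1):
        term *= w / ((a + k - 1) * (b + k - 1))
        total += term
        if abs(term) < _SERIES_RTOL * abs(total):
            break
    else:
        raise LommelPoleError(
            f"1F2 series did not converge within {_SERIES_MAX_TERMS} terms at z={z}"
        )
    return complex(z) ** (kappa + 1) / denom * total


def _lommel_S_series(kappa: Complex, nu: Complex, z: Complex) -> Complex:
    g1 = (1 + kappa - nu) / 2
    g2 = (1 + kappa + nu) / 2
    if _near_nonpositive_int(g1) or _near_nonpositive_int(g2):
        raise LommelPoleError(
            f"Gamma pole in the Bessel complement for kappa={kappa}, nu={nu}"
        )
    s = lommel_s_small(kappa, nu, z)
    half = (kappa - nu) / 2
    comp = (
        2 ** complex(kappa - 1)
        * complex(mpmath.gamma(complex(g1)))
        * complex(mpmath.gamma(complex(g2)))
        * (
            cmath.sin(cmath.pi * half) * cyl_bessel("j", nu, z)
            - cmath.cos(cmath.pi * half) * cyl_bessel("y", nu, z)
        )
    )
    return s + comp


def _lommel_S_closed(kappa: Complex, nu: Complex, z: Complex):
    """Registered polynomial closed forms; returns None when no pattern applies."""
    ki = _near_int(kappa)
    ni = _near_int(nu)
    if ni is not None:
        ni = abs(ni)
        if ki == 1 and ni % 2 == 0:
            return z * neumann_O(ni, z)
        if ki == 0 and ni % 2 == 1:
            return z / ni * neumann_O(ni, z)
        if ki == -1 and ni % 2 == 0 and ni != 0:
            return schlafli_S(ni, z) / (2 * ni)
    # general odd-sum closed form: kappa + nu = 2p+1, p a nonnegative integer
    p = _near_int((kappa + nu - 1) / 2)
    if p is None:
        p = _near_int((kappa - nu - 1) / 2)  # S is even in nu
        if p is not None:
            nu = -nu
    if (
        p is not None
        and p >= 0
        and not _near_nonpositive_int(p + 1 - kappa)
        and abs(2 * p + 1 - kappa) > 1e-12
    ):
        pref = (
            math.factorial(p)
            / (2 ** complex(1 - kappa) * complex(mpmath.gamma(complex(p + 1 - kappa))))
        )
        return pref * complex(z) ** kappa / (2 * p + 1 - kappa) * gegenbauer_A(2 * p, 1 - kappa, z)
    return None


def lommel_S(kappa: Complex, nu: Complex, z: Complex, route: str = "auto") -> Complex:
    """Lommel function of the second kind S_{kappa,nu}(z).

    S is an even function of nu.  Route selection:

    * ``closed_form`` - registered polynomial cases (Neumann/Schlafli
      polynomials, and the general odd kappa+nu Gegenbauer form);
    * ``series`` - Lommel's s_{kappa,nu} plus the Gamma-weighted J,Y
      complement;
    * ``recurrence`` - when the series hits a Gamma pole, kappa is shifted
      upward by 2 (at most 3 times) and the three-term recurrence
      ``S_{kappa,nu} = (z^{kappa+1} - S_{kappa+2,nu})/((kappa+1)^2 - nu^2)``
      is unwound;
    * ``auto`` (default) tries closed form, then series, then recurrence.

    Raises :class:`LommelPoleError` when no finite route exists (e.g. the
    exceptional pair S_{-1,0}).
    """
    if complex(nu).real < 0:
        nu = -nu
    if route == "closed_form":
        val = _lommel_S_closed(kappa, nu, z)
        if val is None:
            raise LommelPoleError(f"no registered closed form for kappa={kappa}, nu={nu}")
        return val
    if route == "series":
        return _lommel_S_series(kappa, nu, z)
    if route == "recurrence":
        return _lommel_S_recur(kappa, nu, z)
    if route != "auto":
        raise ValueError(f"unknown route {route!r}")
    val = _lommel_S_closed(kappa, nu, z)
    if val is not None:
        return val
    try:
        return _lommel_S_series(kappa, nu, z)
    except LommelPoleError:
        return _lommel_S_recur(kappa, nu, z)


def _lommel_S_recur(kappa: Complex, nu: Complex, z: Complex, max_shift: int = 3) -> Complex:
    factors = []
    k = kappa
    for _ in range(max_shift):
        denom = (k + 1) ** 2 - nu**2
        if abs(denom) < 1e-12:
            raise LommelPoleError(
                f"recurrence blocked by (kappa+1)^2 = nu^2 at kappa={k}, nu={nu}"
            )
        factors.append((k, denom))
        k = k + 2
        val = _lommel_S_closed(k, nu, z)
        if val is not None:
            break
        try:
            val = _lommel_S_series(k, nu, z)
            break
        except LommelPoleError:
            val = None
    if val is None:
        raise LommelPoleError(
            f"no finite route for S_{{{kappa},{nu}}} within {max_shift} recurrence shifts"
        )
    for k, denom in reversed(factors):
        val = (complex(z) ** (k + 1) - val) / denom
    return val


def lommel_S_deriv(kappa: Complex, nu: Complex, z: Complex, route: str = "auto") -> Complex:
    """d/dz S_{kappa,nu}(z) from an index-lowering recurrence,

    ``S' = (kappa-nu-1) S_{kappa-1,nu+1} + (nu/z) S_{kappa,nu}``
    or, when that lowered pair has no finite route,
    ``S' = (kappa+nu-1) S_{kappa-1,nu-1} - (nu/z) S_{kappa,nu}``,

    never by numerical differentiation.
    """
    S = lommel_S(kappa, nu, z, route=route)
    try:
        hi = lommel_S(kappa - 1, nu + 1, z, route=route)
        return (kappa - nu - 1) * hi + nu / z * S
    except LommelPoleError:
        lo = lommel_S(kappa - 1, nu - 1, z, route=route)
        return (kappa + nu - 1) * lo - nu / z * S


# ---------------------------------------------------------------------------
# Classical polynomial families
# ---------------------------------------------------------------------------

def gegenbauer_A(n: int, nu: Complex, z: Complex) -> Complex:
    """Gegenbauer polynomial (in 1/z)

    ``A_{n,nu}(z) = 2^{nu+n} (nu+n)/z^{n+1}
                    sum_{m=0}^{floor(n/2)} Gamma(nu+n-m)/m! (z/2)^{2m}``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    z = complex(z)
    total = 0j
    for m in range(n // 2 + 1):
        total += complex(mpmath.gamma(complex(nu + n - m))) / math.factorial(m) * (z / 2) ** (2 * m)
    return 2 ** complex(nu + n) * (nu + n) / z ** (n + 1) * total


def neumann_O(m: int, z: Complex) -> Complex:
    """Neumann polynomial O_m(z): O_0 = 1/z, and for m >= 1 the Watson sum
    ``O_m = (1/4) sum_k m (m-k-1)!/k! (2/z)^(m-2k+1)``."""
    if m < 0:
        raise ValueError("m must be >= 0")
    z = complex(z)
    if m == 0:
        return 1.0 / z
    total = 0j
    for k in range(m // 2 + 1):
        total += m * math.factorial(m - k - 1) / math.factorial(k) * (2.0 / z) ** (m - 2 * k + 1)
    return total / 4.0


def schlafli_S(m: int, z: Complex) -> Complex:
    """Schlafli polynomial S_m(z): S_0 = 0, and for m >= 1
    ``S_m = (2 z O_m(z) - 2 cos^2(m pi/2)) / m`` (i.e. the constant is
    subtracted only for even m)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return 0j
    const = 2.0 if m % 2 == 0 else 0.0
    return (2.0 * complex(z) * neumann_O(m, z) - const) / m


def classical_polynomial(kind: str, m: int, z: Complex) -> Complex:
    """Dispatch to the Neumann (kind='neumann_O') or Schlafli (kind='schlafli_S')
    polynomial families."""
    if kind == "neumann_O":
        return neumann_O(m, z)
    if kind == "schlafli_S":
        return schlafli_S(m, z)
    raise ValueError(f"kind must be 'neumann_O' or 'schlafli_S', got {kind!r}")
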