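"""Diffusion around magnetized cylinders and spheres.

Spins diffusing in the space between two concentric circles (capillary
model) or two concentric spheres (alveolus/cell model) sample a dipolar
local resonance frequency ``omega(x) = delta_omega * f(x)``.  With
reflecting walls the transition density has an eigenfunction expansion in
the radial Neumann modes, and the frequency autocorrelation function
collapses onto the single angular harmonic of the dipole (order 2):

    K(t) = delta_omega^2 * sum_n F_n^2 exp(-lambda_{n,2}^2 D t / R^2).

The squared expansion coefficients F_n^2 have closed forms in the
derivative ratio J'_2(lam)/J'_2(gamma lam) (resp. j'-ratio), with an
equivalent cleared/trigonometric form used for cross-validation, and obey
closed-form sum rules that certify the numerical accuracy of a truncation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.special import eval_legendre

from .eigenvalues import ModeTable, find_zeros
from .geometry import ShellGeometry, check_dim
from .orthogonality import normalization
from .special import deriv_ratio, radial_eigenfunction

__all__ = [
    "DiffusionSpec",
    "DipoleExpansion",
    "PropagatorQuery",
    "correlation_function",
    "dipole_shape",
    "expansion_coefficients",
    "propagator",
    "sph_secular_residual",
    "sum_rules",
]


@dataclass(frozen=True)
class DiffusionSpec:
    """Physical parameters of the diffusion problem.

    D is the diffusion coefficient (length^2/time), delta_omega the dipole
    field strength at the inner surface (rad/time).
    """

    dim: str
    geometry: ShellGeometry
    D: float = 1.0
    delta_omega: float = 1.0

    def __post_init__(self) -> None:
        check_dim(self.dim)
        if not self.D > 0:
            raise ValueError(f"diffusion coefficient must be positive, got {self.D}")

    @property
    def volume(self) -> float:
        return self.geometry.volume(self.dim)

    def tau(self, t) -> np.ndarray:
        """Nondimensional time Dt/R^2."""
        return np.asarray(t) * self.D / self.geometry.R**2


@dataclass
class DipoleExpansion:
    """Mode sum {lambda_{n,2}, F_n^2} powering K(t)."""

    dim: str
    gamma: float
    lams: np.ndarray
    F2: np.ndarray
    cross_form_discrepancy: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lams)


@dataclass(frozen=True)
class PropagatorQuery:
    """Evaluation point of the transition density.

    angle is phi - phi_0 (2D) or the spherical angle Omega between the two
    directions (3D, via the spherical law of cosines); t >= 0.
    """

    r: float
    r0: float
    angle: float
    t: float


# ---------------------------------------------------------------------------
# Dipole shape
# ---------------------------------------------------------------------------

def dipole_shape(dim: str, geometry: ShellGeometry, coords: Sequence[float]) -> float:
    """Dimensionless local-frequency shape of the dipole field.

    2D: f(r, phi) = (R/r)^2 cos(2 phi); 3D: f(r, theta) = (R/r)^3 (3 cos^2(theta) - 1).
    """
    check_dim(dim)
    r = float(coords[0])
    if not (geometry.R - 1e-12 <= r <= geometry.outer + 1e-12):
        raise ValueError(f"r={r} outside the shell [{geometry.R}, {geometry.outer}]")
    rho = r / geometry.R
    if dim == "cyl":
        phi = float(coords[1])
        return math.cos(2.0 * phi) / rho**2
    theta = float(coords[1])
    return (3.0 * math.cos(theta) ** 2 - 1.0) / rho**3


# ---------------------------------------------------------------------------
# Expansion coefficients and sum rules
# ---------------------------------------------------------------------------

def _f2_cyl_ratio(lam: float, gamma: float) -> float:
    """Derivative-ratio form of F_n^2 (annulus)."""
    rho = float(np.real(deriv_ratio("cyl", 2, lam, gamma)))
    num = (1.0 - rho / gamma**3) ** 2
    den = 4.0 - lam**2 + (lam**2 - 4.0 / gamma**2) * rho**2
    return 8.0 / (gamma**2 - 1.0) / lam**2 * num / den


def _f2_cyl_cleared(lam: float, gamma: float) -> float:
    """Cleared form of F_n^2 (annulus), no ratio of derivatives."""
    from .special import cyl_bessel_deriv

    ji = float(np.real(cyl_bessel_deriv("j", 2, lam)))
    jo = float(np.real(cyl_bessel_deriv("j", 2, gamma * lam)))
    num = (gamma**3 * jo - ji) ** 2
    den = gamma**2 * (4.0 - lam**2) * jo**2 + (gamma**2 * lam**2 - 4.0) * ji**2
    return 8.0 / (gamma**2 - 1.0) / lam**2 / gamma**4 * num / den


def _f2_sph_ratio(lam: float, gamma: float) -> float:
    """Spherical-Bessel derivative-ratio form of F_m^2 (shell)."""
    rho = float(np.real(deriv_ratio("sph", 2, lam, gamma)))
    num = (1.0 - rho / gamma**4) ** 2
    den = (gamma**2 * lam**2 - 6.0) / gamma**3 * rho**2 + 6.0 - lam**2
    return 216.0 / 5.0 / lam**2 / (gamma**3 - 1.0) * num / den


def _sph_u(z: float) -> float:
    """z^4 j'_2(z) = (4 z^2 - 9) sin z + z (9 - z^2) cos z."""
    return (4.0 * z**2 - 9.0) * math.sin(z) + z * (9.0 - z**2) * math.cos(z)


def _f2_sph_trig(lam: float, gamma: float) -> float:
    """Trigonometric form of F_m^2 (shell), fully cleared of Bessel calls."""
    ui = _sph_u(lam)
    uo = _sph_u(gamma * lam)
    num = (uo - ui) ** 2
    den = gamma**5 * ui**2 * (gamma**2 * lam**2 - 6.0) + (6.0 - lam**2) * uo**2
    return 216.0 / 5.0 / lam**2 / (gamma**3 - 1.0) * num / den


def expansion_coefficients(dim: str, gamma: float, n_max: int,
                           modes: Optional[ModeTable] = None,
                           cross_tol: float = 1e-10) -> DipoleExpansion:
    """{lambda_{n,2}, F_n^2} for the dipole autocorrelation mode sum.

    Both printed forms of F^2 (derivative-ratio and cleared/trigonometric)
    are evaluated and must agree to ``cross_tol`` relative, mode by mode.
    """
    check_dim(dim)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if modes is None:
        modes = find_zeros(dim, 2, gamma, n_max)
    lams = np.real(modes.lams[:n_max])
    primary = _f2_cyl_ratio if dim == "cyl" else _f2_sph_ratio
    check = _f2_cyl_cleared if dim == "cyl" else _f2_sph_trig
    F2 = np.array([primary(l, gamma) for l in lams])
    F2b = np.array([check(l, gamma) for l in lams])
    disc = float(np.max(np.abs(F2 - F2b) / np.maximum(np.abs(F2), 1e-300)))
    if disc > cross_tol:
        raise RuntimeError(
            f"the two F^2 forms disagree (max relative {disc:.3g} > {cross_tol:g})"
        )
    if np.any(F2 < 0):
        raise RuntimeError("negative F^2 encountered; stale eigenvalues?")
    return DipoleExpansion(dim=dim, gamma=gamma, lams=lams, F2=F2,
                           cross_form_discrepancy=disc,
                           metadata={"n_max": n_max, "nu": 2})


def sum_rules(dim: str, gamma: float) -> Dict[str, float]:
    """Closed-form values of the convergence-certificate mode sums.

    2D: sum F^2 = 1/(2 gamma^2); sum F^2 lam^2 = 2(1+gamma^2)/gamma^4;
    sum F^2/lam^2 = ln(gamma)/(4(gamma^2-1)); sum F^2/lam^4 = 1/32.
    3D: sum F^2 = 4/(5 gamma^3); sum F^2 lam^2 = 36(gamma^5-1)/(5 gamma^5 (gamma^3-1));
    and the bracketed closed form for sum F^2/lam^2.
    """
    check_dim(dim)
    g = gamma
    if g == 1.0:
        raise ZeroDivisionError("sum rules are singular at gamma=1 (zero shell volume)")
    if dim == "cyl":
        return {
            "F2": 1.0 / (2.0 * g**2),
            "F2_lam2": 2.0 * (1.0 + g**2) / g**4,
            "F2_over_lam2": math.log(g) / (4.0 * (g**2 - 1.0)),
            "F2_over_lam4": 1.0 / 32.0,
        }
    return {
        "F2": 4.0 / (5.0 * g**3),
        "F2_lam2": 36.0 / (5.0 * g**5) * (g**5 - 1.0) / (g**3 - 1.0),
        "F2_over_lam2": 2.0 / 5.0 / (g**3 - 1.0) * (
            1.0 - 1.0 / g
            + (4.0 * (g**3 - 1.0) ** 2 + 9.0 * g * (2.0 * g**2 - 1.0 - g**4))
            / (36.0 * g * (1.0 - g**5))
        ),
    }


def partial_sums(expansion: DipoleExpansion) -> Dict[str, float]:
    """Truncated mode sums matching the keys of :func:`sum_rules`."""
    lam2 = expansion.lams**2
    out = {
        "F2": float(expansion.F2.sum()),
        "F2_lam2": float((expansion.F2 * lam2).sum()),
        "F2_over_lam2": float((expansion.F2 / lam2).sum()),
    }
    if expansion.dim == "cyl":
        out["F2_over_lam4"] = float((expansion.F2 / lam2**2).sum())
    return out


def mode_sum(expansion: DipoleExpansion, exponent: int,
             fit_window: int = 160, extend_to: int = 2_000_000) -> float:
    """sum_n F_n^2 lambda_n^exponent, completed with an asymptotic tail.

    Asymptotically F_n^2 lambda_n^4 approaches two interleaved constants (the
    cross-product zeros alternate between the two branches of the large-order
    Bessel phase), so the dropped tail is summed by fitting, per parity of n,
    ``F^2 lam^4 ~ a + b/lam + c/lam^2`` over the last ``fit_window`` computed
    modes and extending lambda with the McMahon approximation.  This matters
    only for the lambda^2-weighted sum, whose direct partial sums converge
    like 1/n; the other weights converge fast and the correction is tiny.
    """
    if exponent not in (-4, -2, 0, 2):
        raise ValueError("exponent must be one of -4, -2, 0, 2")
    lam, F2 = expansion.lams, expansion.F2
    direct = float(np.sum(F2 * lam**float(exponent)))
    N = len(lam)
    if N < 2 * fit_window // 2 + 20:
        return direct
    g = expansion.gamma
    decay = 4 - exponent  # tail terms behave like 1/lam^decay
    nn = np.arange(N + 1, extend_to + 1, dtype=float)
    lam_ext = np.asarray(
        [approx_higher_vec(expansion.dim, g, nn)], dtype=float
    ).ravel()
    tail = 0.0
    v = F2 * lam**4
    for par in (0, 1):
        idx = np.arange(N - fit_window, N)
        idx = idx[idx % 2 == par]
        x = lam[idx]
        A = np.vstack([np.ones_like(x), 1 / x, 1 / x**2]).T
        coef, *_ = np.linalg.lstsq(A, v[idx], rcond=None)
        sel = (nn.astype(int) - 1) % 2 == par
        xe = lam_ext[sel]
        tail += float(np.sum((coef[0] + coef[1] / xe + coef[2] / xe**2) / xe**decay))
        if decay == 2:  # analytic remainder of the leading 1/lam^2 piece
            tail += coef[0] * (g - 1.0) ** 2 / math.pi**2 / 2.0 / extend_to
    return direct + tail


def approx_higher_vec(dim: str, gamma: float, n: np.ndarray) -> np.ndarray:
    """Vectorized McMahon zeros of the order-2 cross product (n >= 2)."""
    q = (gamma - 1.0) / (n - 1.0)
    if dim == "cyl":
        return np.pi / q + 19.0 / (8.0 * np.pi * gamma) * q
    return np.pi / q + 8.0 / (2.0 * np.pi * gamma) * q


def sum_rule_report(expansion: DipoleExpansion) -> List[dict]:
    """Compare truncated and tail-completed mode sums with the closed forms."""
    rules = sum_rules(expansion.dim, expansion.gamma)
    direct = partial_sums(expansion)
    exponents = {"F2": 0, "F2_lam2": 2, "F2_over_lam2": -2, "F2_over_lam4": -4}
    out = []
    for key, closed in rules.items():
        completed = mode_sum(expansion, exponents[key])
        out.append(
            {
                "rule": key,
                "partial_sum": direct[key],
                "tail_completed": completed,
                "closed_form": closed,
                "rel_error": abs(completed - closed) / abs(closed),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Correlation function
# ---------------------------------------------------------------------------

def correlation_function(spec: DiffusionSpec, expansion: DipoleExpansion,
                         times: Sequence[float], rel_tol: float = 1e-6) -> np.ndarray:
    """Frequency autocorrelation K(t) = delta_omega^2 sum F^2 exp(-lam^2 Dt/R^2).

    Monotone nonincreasing on t >= 0; K(0) approaches delta_omega^2 times the
    first sum rule as the truncation deepens.  A warning is raised when the
    estimated dropped tail of sum F^2 exceeds ``rel_tol`` of the total.
    """
    if spec.dim != expansion.dim:
        raise ValueError("spec and expansion dimensions differ")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    total = sum_rules(spec.dim, expansion.gamma)["F2"]
    tail = total - expansion.F2.sum()
    if tail > rel_tol * total:
        warnings.warn(
            f"truncation keeps only {expansion.F2.sum()/total:.6f} of sum F^2 "
            f"(dropped tail {tail:.3g}); increase n_max",
            RuntimeWarning,
            stacklevel=2,
        )
    tau = spec.tau(times)
    K = spec.delta_omega**2 * np.sum(
        expansion.F2[None, :] * np.exp(-np.outer(tau, expansion.lams**2)), axis=1
    )
    return K


# ---------------------------------------------------------------------------
# Propagator
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=100_000)
def _norm_cached(dim: str, nu: int, lam: float, gamma: float) -> float:
    return float(np.real(normalization(dim, nu, lam, gamma)))


def propagator_grid(spec: DiffusionSpec, modes: Dict[int, ModeTable],
                    r: np.ndarray, angle: np.ndarray, r0: float, t: float,
                    trunc_tol: float = 1e-12) -> np.ndarray:
    """Transition density on an (r x angle) tensor grid, vectorized per mode.

    Returns an array of shape (len(r), len(angle)); same series as
    :func:`propagator` but each radial eigenfunction is evaluated on the whole
    r-grid at once.
    """
    dim, geo = spec.dim, spec.geometry
    R, gamma = geo.R, geo.gamma
    r = np.asarray(r, dtype=float)
    angle = np.asarray(angle, dtype=float)
    rho = r / R
    rho0 = r0 / R
    tau = float(spec.tau(t))
    out = np.full((r.size, angle.size), 1.0 / spec.volume)
    for nu in sorted(modes.keys()):
        lams = np.real(modes[nu].lams)
        if dim == "cyl":
            ang = (2.0 - (1.0 if nu == 0 else 0.0)) * np.cos(nu * angle) / (2.0 * math.pi * R**2)
        else:
            ang = (2 * nu + 1) * eval_legendre(nu, np.cos(angle)) / (4.0 * math.pi * R**3)
        rad = np.zeros(r.size)
        for lam in lams:
            damp = math.exp(-(lam**2) * tau)
            if damp < trunc_tol:
                break
            N = _norm_cached(dim, nu, float(lam), gamma)
            pr = np.real(radial_eigenfunction(dim, nu, lam, rho))
            pr0 = float(np.real(radial_eigenfunction(dim, nu, lam, rho0)))
            rad += damp / N * pr * pr0
        out += np.outer(rad, ang)
    return out


def propagator(spec: DiffusionSpec, modes: Dict[int, ModeTable], q: PropagatorQuery,
               nu_max: Optional[int] = None, n_max: Optional[int] = None,
               trunc_tol: float = 1e-12) -> float:
    """Transition density p(r, r0, angle, t) by eigenfunction expansion.

    2D uses the (2 - delta_{nu,0}) cos(nu (phi - phi0)) angular factors, 3D the
    (2 nu + 1) P_nu(cos Omega)/(4 pi) Legendre factors (physical integer
    angular orders).  The long-time limit is 1/V.  A warning flags truncation
    when exp(-lam^2 Dt/R^2) at the cutoff modes still exceeds ``trunc_tol``.
    """
    dim, geo = spec.dim, spec.geometry
    R, gamma = geo.R, geo.gamma
    for r in (q.r, q.r0):
        if not (R - 1e-12 <= r <= gamma * R + 1e-12):
            raise ValueError(f"position {r} outside the shell")
    tau = float(spec.tau(q.t))
    V = spec.volume
    rho, rho0 = q.r / R, q.r0 / R
    total = 1.0 / V
    worst_damp = 0.0
    nus = sorted(modes.keys()) if nu_max is None else [n for n in sorted(modes.keys()) if n <= nu_max]
    for nu in nus:
        table = modes[nu]
        lams = np.real(table.lams)
        if n_max is not None:
            lams = lams[:n_max]
        if len(lams) == 0:
            continue
        worst_damp = max(worst_damp, float(np.exp(-lams[-1] ** 2 * tau)))
        term_sum = 0.0
        for lam in lams:
            N = _norm_cached(dim, nu, float(lam), gamma)
            damp = math.exp(-(lam**2) * tau)
            if damp < trunc_tol:
                break
            pr = float(np.real(radial_eigenfunction(dim, nu, lam, rho)))
            pr0 = float(np.real(radial_eigenfunction(dim, nu, lam, rho0)))
            term_sum += damp / N * pr * pr0
        if dim == "cyl":
            ang = (2.0 - (1.0 if nu == 0 else 0.0)) * math.cos(nu * q.angle)
            total += term_sum * ang / (2.0 * math.pi * R**2)
        else:
            ang = (2 * nu + 1) * float(eval_legendre(nu, math.cos(q.angle)))
            total += term_sum * ang / (4.0 * math.pi * R**3)
    if worst_damp > trunc_tol:
        warnings.warn(
            f"series truncation: slowest dropped damping factor {worst_damp:.3g} "
            f"exceeds {trunc_tol:g} (short-time evaluation needs more modes)",
            RuntimeWarning,
            stacklevel=2,
        )
    return total


def build_mode_basis(dim: str, gamma: float, nu_max: int, n_max: int) -> Dict[int, ModeTable]:
    """Mode tables for angular orders nu = 0..nu_max (propagator input)."""
    return {nu: find_zeros(dim, nu, gamma, n_max) for nu in range(nu_max + 1)}


# ---------------------------------------------------------------------------
# Spherical secular equation
# ---------------------------------------------------------------------------

def sph_secular_residual(lam: float, gamma: float, pole_tol: float = 1e-8) -> float:
    """Residual of the trigonometric secular equation equivalent to g_2(lam)=0,

    tan(lam(gamma-1))/(lam(gamma-1)) - rational(lam, gamma),

    which vanishes exactly at the order-2 spherical Neumann eigenvalues.
    """
    x = lam * (gamma - 1.0)
    if abs(math.cos(x)) < pole_tol:
        raise ValueError(f"lam(gamma-1)={x} is within {pole_tol} of a tan pole")
    l2 = lam**2
    num = 81.0 - 9.0 * l2 * (gamma**2 - 3.0 * gamma + 1.0) + 4.0 * gamma**2 * l2**2
    den = (
        81.0
        - 9.0 * l2 * (4.0 * gamma**2 - 9.0 * gamma + 4.0)
        + gamma * l2**2 * (16.0 * gamma - 9.0 * gamma**2 - 9.0)
        + gamma**3 * l2**3
    )
    return math.tan(x) / x - num / den
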