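"""Location of the cross-product zeros lambda_{n,nu}.

The primary algorithm discretizes the radial Laplacian on the shell as a
tridiagonal matrix with Neumann closure, solves the resulting matrix
eigenvalue problem for seeds, and polishes every seed on the analytic cross
product.  Printed closed-form approximations (small-lambda Taylor, small-nu,
Gottlieb, Grebenkov, Buchholz, McMahon) are exposed alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .geometry import ShellGeometry, check_dim
from .special import bessel_cross

Complex = Union[float, complex]

__all__ = [
    "DiscreteOperator",
    "ModeEntry",
    "ModeTable",
    "RadialGrid",
    "approx_first",
    "approx_higher",
    "build_discrete_laplacian",
    "build_grid",
    "find_zeros",
    "matrix_modes",
    "polish_zero",
]

#: default number of grid points for matrix seeding
DEFAULT_P = 2000
#: residual threshold declaring a polished zero converged
POLISH_TOL = 1e-12
#: two polished zeros closer than this are considered duplicates
DUPLICATE_TOL = 1e-8


# ---------------------------------------------------------------------------
# Grid and discrete operator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid r_j = R + (j-1) h, j = 1..p, with h = R(gamma-1)/(p-1)."""

    p: int
    h: float
    nodes: np.ndarray
    geometry: ShellGeometry


def build_grid(p: int, geometry: ShellGeometry) -> RadialGrid:
    if p < 2:
        raise ValueError(f"need at least 2 grid points, got p={p}")
    R, gamma = geometry.R, geometry.gamma
    h = R * (gamma - 1.0) / (p - 1)
    nodes = R + (np.arange(1, p + 1) - 1) * h
    return RadialGrid(p=p, h=h, nodes=nodes, geometry=geometry)


@dataclass(frozen=True)
class DiscreteOperator:
    """Tridiagonal finite-difference radial Laplacian with Neumann closure.

    Stored as the three diagonals of the (generally nonsymmetric) matrix;
    every row sums to zero, interior main-diagonal entries are -2/h^2 in 2D,
    and the first/last rows carry the reflecting-boundary factor 2.
    """

    dim: str
    grid: RadialGrid
    lower: np.ndarray  # entries (j+1, j), length p-1
    diag: np.ndarray   # length p
    upper: np.ndarray  # entries (j, j+1), length p-1

    def dense(self) -> np.ndarray:
        return (
            np.diag(self.diag)
            + np.diag(self.upper, 1)
            + np.diag(self.lower, -1)
        )


def build_discrete_laplacian(dim: str, grid: RadialGrid) -> DiscreteOperator:
    """Second-order stencil of the radial part of the 2D/3D Laplace operator.

    2D rows use half-index radii r_{j +/- 1/2} over r_j; 3D rows use their
    squares.  The stencil is conservative: row sums vanish identically, so the
    constant vector is annihilated (the Neumann zero mode).
    """
    check_dim(dim)
    p, h, r = grid.p, grid.h, grid.nodes
    half = r[:-1] + 0.5 * h  # r_{j+1/2}, j = 1..p-1
    w = half / r[:-1] if dim == "cyl" else (half / r[:-1]) ** 2  # coupling to the right
    v = half / r[1:] if dim == "cyl" else (half / r[1:]) ** 2    # coupling to the left
    upper = w.copy()
    lower = v.copy()
    upper[0] *= 2.0
    lower[-1] *= 2.0
    diag = np.zeros(p)
    diag[0] = -upper[0]
    diag[-1] = -lower[-1]
    diag[1:-1] = -(lower[:-1][: p - 2] + upper[1:][: p - 2])
    return DiscreteOperator(dim=dim, grid=grid, lower=lower / h**2,
                            diag=diag / h**2, upper=upper / h**2)


def matrix_modes(dim: str, nu: Complex, geometry: ShellGeometry, p: int = DEFAULT_P,
                 k: int = 10) -> np.ndarray:
    """k smallest eigenvalues lambda of the discretized radial problem.

    Solves ``[c_nu diag(1/r_j^2) - L] u = (lambda/R)^2 u`` with
    ``c_nu = nu^2`` (2D) or ``nu(nu+1)`` (3D) and returns
    ``lambda = R sqrt(eig)`` (principal square root).  For real nu the
    nonsymmetric tridiagonal matrix is similarity-transformed to a symmetric
    one and solved with a banded eigensolver; complex nu uses a dense solver
    with (Re, Im)-lexicographic ordering.
    """
    check_dim(dim)
    if k > p:
        raise ValueError(f"cannot request k={k} modes from a p={p} grid")
    grid = build_grid(p, geometry)
    op = build_discrete_laplacian(dim, grid)
    R = geometry.R
    cnu = nu**2 if dim == "cyl" else nu * (nu + 1)
    shift = np.asarray(cnu / grid.nodes**2)
    if np.all(np.isreal(np.atleast_1d(shift))) and abs(complex(cnu).imag) == 0:
        d = np.real(shift) - op.diag
        # the similarity weight sqrt(r_j) (sqrt(r_j/2) at the two Neumann rows)
        # makes the tridiagonal symmetric with off-diagonal -sqrt(upper*lower)
        e = -np.sqrt(op.upper * op.lower)
        try:
            vals = sla.eigh_tridiagonal(d, e, select="i",
                                        select_range=(0, k - 1), eigvals_only=True)
        except sla.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(
                f"banded eigensolver failed for dim={dim}, nu={nu}, p={p}"
            ) from exc
        vals = np.where(np.abs(vals) < 1e-14, 0.0, vals)
        return R * np.sqrt(np.maximum(vals, 0.0))
    M = np.diag(shift.astype(complex)) - op.dense().astype(complex)
    try:
        vals = sla.eigvals(M)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(
            f"dense eigensolver failed for dim={dim}, nu={nu}, p={p}"
        ) from exc
    order = np.lexsort((vals.imag, vals.real))
    lam = np.sqrt(vals[order][:k].astype(complex))
    return R * lam


# ---------------------------------------------------------------------------
# Root polishing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolishResult:
    lam: Complex
    residual: float
    iterations: int


def _objective(dim: str, nu: Complex, gamma: float):
    """Polish objective; the spherical cross product is scaled by lam^3 to
    remove its pole-like small-lambda behavior (scale-free near zero, no new
    zeros on the positive axis)."""
    if dim == "cyl":
        return lambda lam: bessel_cross(dim, nu, gamma, lam)
    return lambda lam: np.asarray(lam) ** 3 * bessel_cross(dim, nu, gamma, lam)


def _residual(dim: str, nu: Complex, gamma: float, lam: Complex) -> float:
    return float(abs(bessel_cross(dim, nu, gamma, lam)))


def polish_zero(dim: str, nu: Complex, gamma: float, seed: Complex,
                spacing: Optional[float] = None, max_iter: int = 50) -> PolishResult:
    """Refine a seed to a cross-product zero.

    Real nu with a real seed uses a sign-preserving bracket plus Brent's
    method (no root-jumping possible); complex nu uses an unconstrained
    secant iteration in the complex plane.  A root-collapse guard rejects a
    polished value that moved by more than half the local root spacing.
    """
    check_dim(dim)
    if spacing is None:
        spacing = math.pi / (gamma - 1.0) if gamma > 1 else 1.0
    fobj = _objective(dim, nu, gamma)
    real_path = abs(complex(nu).imag) == 0 and abs(complex(seed).imag) == 0
    seed_res = abs(fobj(seed))
    if seed_res == 0.0:
        return PolishResult(lam=seed, residual=_residual(dim, nu, gamma, seed),
                            iterations=0)
    if real_path:
        s = float(np.real(seed))
        lam = _polish_bracketed(fobj, s, spacing)
        iters = 1
        # local scale = oscillation amplitude of the objective over the
        # half-spacing window; the converged residual is judged against it
        probe = np.linspace(max(lam - 0.45 * spacing, 1e-12), lam + 0.45 * spacing, 15)
        fscale = float(np.max(np.abs(fobj(probe))))
    else:
        lam, iters = _polish_secant(fobj, complex(seed), max_iter)
        fscale = max(seed_res, 1.0)
    if abs(lam - seed) > 0.5 * spacing:
        raise RuntimeError(
            f"root collapse: polished zero {lam} moved more than half the "
            f"local spacing from seed {seed}"
        )
    res = _residual(dim, nu, gamma, lam)
    # convergence is judged against the local scale of the objective (its
    # magnitude on the bracketing grid), not an absolute number
    if abs(fobj(lam)) > POLISH_TOL * max(1e-300, fscale):
        raise RuntimeError(
            f"polishing did not converge at seed {seed}: residual {res}"
        )
    return PolishResult(lam=lam, residual=res, iterations=iters)


def _polish_bracketed(fobj, seed: float, spacing: float) -> float:
    """Expand a bracket around the seed until the objective changes sign, then Brent."""
    for frac in (0.02, 0.05, 0.1, 0.2, 0.35, 0.5):
        delta = frac * spacing
        lo = max(seed - delta, 1e-12)
        hi = seed + delta
        grid = np.linspace(lo, hi, 25)
        vals = np.asarray(fobj(grid), dtype=float)
        sign = np.sign(vals)
        flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if flips.size:
            # take the sign change nearest the seed
            mid = 0.5 * (grid[flips] + grid[flips + 1])
            i = flips[np.argmin(np.abs(mid - seed))]
            return optimize.brentq(lambda x: float(fobj(x)), grid[i], grid[i + 1],
                                   xtol=1e-15, rtol=8.9e-16, maxiter=100)
    raise RuntimeError(f"no sign change of the cross product near seed {seed}")


def _polish_secant(fobj, seed: complex, max_iter: int):
    x0 = seed
    x1 = seed * (1.0 + 1e-6) + 1e-8
    f0, f1 = complex(fobj(x0)), complex(fobj(x1))
    for it in range(1, max_iter + 1):
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        x0, f0, x1 = x1, f1, x2
        f1 = complex(fobj(x1))
        if abs(x1 - x0) < 1e-15 * max(1.0, abs(x1)) or abs(f1) == 0.0:
            return x1, it
    if abs(f1) < abs(f0):
        return x1, max_iter
    raise RuntimeError(f"secant iteration failed to converge from seed {seed}")


# ---------------------------------------------------------------------------
# Printed closed-form approximations
# ---------------------------------------------------------------------------

def approx_first(dim: str, nu: Complex, gamma: float, method: str) -> Complex:
    """Closed-form approximations of the exceptional (first) zero lambda_{1,nu}.

    Methods: ``small_lambda`` (Taylor expansion of the cross product),
    ``small_nu``, ``gottlieb``, ``grebenkov``, and (2D only) ``buchholz``.
    The small-lambda 2D form has a pole at nu = +/-1; its validity window in
    gamma is not sharply known, it is exposed as printed.
    """
    check_dim(dim)
    g = gamma
    if dim == "cyl":
        if method == "small_lambda":
            if abs(nu**2 - 1) < 1e-12:
                raise ZeroDivisionError("small-lambda 2D approximation has a pole at nu=+/-1")
            num = 4 * nu * (1 - nu**2) * (g ** (2 * nu) - 1)
            den = (nu**2 + nu - 2) * (1 - g**2) * (1 + g ** (2 * nu)) - 2 * nu * (
                g ** (2 * nu) - g**2
            )
            return _csqrt(num / den)
        if method == "small_nu":
            return nu * _csqrt(2.0 * math.log(g) / (g**2 - 1.0))
        if method == "gottlieb":
            return nu * (1 - 0.5 * (g - 1) + 7.0 / 24.0 * (g - 1) ** 2)
        if method == "grebenkov":
            return nu * _csqrt(
                2 - g + 5.0 / 6.0 * (1 - g) ** 2 + 2.0 / 3.0 * (1 - g) ** 3
                - (nu**2 - 16) / 30.0 * (1 - g) ** 4
            )
        if method == "buchholz":
            return nu / (
                _csqrt(g)
                * (
                    1
                    + (g - 1) ** 2 / (12 * g)
                    + (8 * nu**2 - 3) * (g - 1) ** 4 / (480 * g**2)
                    - (144 * nu**2 - 103) * (g - 1) ** 6 / (120960 * g**3)
                )
            )
        raise ValueError(f"unknown 2D method {method!r}")
    if method == "small_lambda":
        num = 2 * nu * (nu + 1) * (4 * nu**2 + 4 * nu - 3) * (1 - g ** (2 * nu + 1))
        den = (2 * nu**3 + 5 * nu**2 + nu - 2) * (1 - g ** (2 * nu + 3)) + nu * g**2 * (
            2 * nu**2 + nu - 3
        ) * (g ** (2 * nu - 1) - 1)
        return _csqrt(num / den)
    if method == "small_nu":
        return _csqrt(3 * nu / (1 + g + g**2))
    if method == "grebenkov":
        return _csqrt(nu * (1 + nu)) * _csqrt(
            2 - g + 2.0 / 3.0 * (1 - g) ** 2 + 1.0 / 3.0 * (1 - g) ** 3
            - (3 * nu * (1 + nu) - 10) / 90.0 * (1 - g) ** 4
        )
    if method == "gottlieb":
        return _csqrt(nu * (1 + nu)) * (
            1
            - 0.5 * (g - 1)
            + 5.0 / 24.0 * (g - 1) ** 2
            - 1.0 / 16.0 * (g - 1) ** 3
            + (5 - 32 * nu * (nu + 1)) / 1920.0 * (g - 1) ** 4
        )
    raise ValueError(f"unknown 3D method {method!r} (buchholz is 2D only)")


def approx_higher(dim: str, nu: Complex, gamma: float, n: int, method: str = "mcmahon") -> Complex:
    """McMahon / Buchholz asymptotics of the n-th zero (n >= 2); the leading
    term is pi (n-1)/(gamma-1) in the labeling where n=1 is the exceptional zero."""
    check_dim(dim)
    if n < 2:
        raise ValueError("asymptotic formulas apply for n >= 2")
    g = gamma
    q = (g - 1.0) / (n - 1.0)
    if method == "mcmahon":
        if dim == "cyl":
            lead = math.pi / q
            c1 = (4 * nu**2 + 3) / (8 * math.pi * g)
            c3 = (
                (g**2 + g + 1) * (16 * nu**4 + 184 * nu**2 - 63)
                - 6 * g * (4 * nu**2 + 3) ** 2
            ) / (384 * math.pi**3 * g**3)
            return lead + c1 * q + c3 * q**3
        return math.pi / q + (nu**2 + nu + 2) / (2 * math.pi * g) * q
    if method == "buchholz":
        if dim != "cyl":
            raise ValueError("the Buchholz higher-zero formula is 2D only")
        den = (
            1
            - (4 * nu**2 + 3) / (8 * g * math.pi**2) * q**2
            + (96 * nu**4 - 176 * nu**2 + 198) / (256 * g**2 * math.pi**4) * q**4
        )
        return math.pi / q / den
    raise ValueError(f"unknown method {method!r}")


def _csqrt(x: Complex) -> Complex:
    if isinstance(x, complex) or (isinstance(x, (int, float)) and x < 0):
        return complex(x) ** 0.5
    return math.sqrt(x)


# ---------------------------------------------------------------------------
# Mode tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeEntry:
    n: int
    lam: Complex
    residual: float
    source: str  # matrix | polished | approximation


@dataclass
class ModeTable:
    """Ordered cross-product zeros for one (dimension, order, shell ratio)."""

    dim: str
    nu: Complex
    gamma: float
    entries: List[ModeEntry]
    p: int
    metadata: dict = field(default_factory=dict)

    @property
    def lams(self) -> np.ndarray:
        vals = np.array([e.lam for e in self.entries])
        return vals.real if np.all(vals.imag == 0) else vals

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": [e.n for e in self.entries],
                "re_lambda": [complex(e.lam).real for e in self.entries],
                "im_lambda": [complex(e.lam).imag for e in self.entries],
                "residual": [e.residual for e in self.entries],
                "source": [e.source for e in self.entries],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "dim": self.dim,
            "nu": [complex(self.nu).real, complex(self.nu).imag],
            "gamma": self.gamma,
            "p": self.p,
            "polish_tol": POLISH_TOL,
            "metadata": self.metadata,
            "modes": [
                {
                    "n": e.n,
                    "re_lambda": complex(e.lam).real,
                    "im_lambda": complex(e.lam).imag,
                    "residual": e.residual,
                    "source": e.source,
                }
                for e in self.entries
            ],
        }


def _auto_p(n_max: int, gamma: float, p: Optional[int]) -> int:
    lam_est = math.pi * max(n_max, 1) / max(gamma - 1.0, 1e-3) + 2.0
    p_needed = int(math.ceil(10.0 * lam_est * (gamma - 1.0))) + 50
    return max(p or DEFAULT_P, p_needed)


def find_zeros(dim: str, nu: Complex, gamma: float, n_max: int,
               p: Optional[int] = None) -> ModeTable:
    """Locate the first ``n_max`` cross-product zeros: matrix seeds + polish.

    Indexing convention: n=1 is the smallest zero with Re(lambda) above the
    zero-mode threshold (the exceptional zero); the lambda=0 constant Neumann
    mode at nu=0 is excluded and reported in the table metadata.  For real nu
    a McMahon spacing check flags holes in the sequence.
    """
    check_dim(dim)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    real_nu = abs(complex(nu).imag) == 0
    if real_nu:
        nu = complex(nu).real
        p_eff = _auto_p(n_max, gamma, p)
    else:
        p_eff = min(p or 800, DEFAULT_P)
    geometry = ShellGeometry(R=1.0, gamma=gamma)
    seeds = matrix_modes(dim, nu, geometry, p=p_eff, k=n_max + 4)
    seeds = np.atleast_1d(seeds)

    metadata: dict = {}
    cnu = nu**2 if dim == "cyl" else nu * (nu + 1)
    spacing_est = math.pi / (gamma - 1.0) if gamma > 1 else 1.0
    seeds = list(seeds)
    if abs(cnu) < 1e-14:
        # the Neumann operator annihilates constants: the smallest eigenvalue
        # is the lambda=0 mode (contaminated only by rounding); exclude it
        zero_seed = seeds.pop(0)
        if abs(zero_seed) > 1e-3 * spacing_est:
            raise RuntimeError(
                f"expected a numerical zero mode for nu={nu}, found {zero_seed}"
            )
        metadata["excluded_zero_mode"] = {
            "lam": 0.0,
            "numerical_value": abs(complex(zero_seed)),
            "reason": "constant Neumann mode (row sums of the discrete "
                      "Laplacian vanish)",
        }
    kept = [complex(s) if not real_nu else float(np.real(s)) for s in seeds]

    spacing = math.pi / (gamma - 1.0) if gamma > 1 else 1.0
    entries: List[ModeEntry] = []
    lams: List[Complex] = []
    for s in kept:
        if len(entries) >= n_max:
            break
        local = spacing
        if lams:
            local = min(spacing, abs(s - lams[-1]))
        res = polish_zero(dim, nu, gamma, s, spacing=local)
        if any(abs(res.lam - prev) < DUPLICATE_TOL for prev in lams):
            raise RuntimeError(
                f"duplicate zero {res.lam} (matrix seed {s} collapsed onto an "
                "already-polished root)"
            )
        lams.append(res.lam)
        entries.append(ModeEntry(n=len(entries) + 1, lam=res.lam,
                                 residual=res.residual, source="polished"))
    if len(entries) < n_max:
        raise RuntimeError(
            f"matrix seeding produced only {len(entries)} distinct zeros, "
            f"requested {n_max}; increase p"
        )
    if real_nu:
        order = np.argsort([e.lam for e in entries])
        entries = [
            ModeEntry(n=i + 1, lam=entries[j].lam, residual=entries[j].residual,
                      source=entries[j].source)
            for i, j in enumerate(order)
        ]
        vals = [float(np.real(e.lam)) for e in entries]
        gaps = np.diff(vals)
        if np.any(gaps[1:] > 1.6 * spacing):
            raise RuntimeError(
                "missed-root check failed: a gap between consecutive zeros "
                f"exceeds 1.6x the McMahon spacing {spacing:.4g}"
            )
    else:
        vals_c = np.array([e.lam for e in entries])
        order = np.lexsort((vals_c.imag, vals_c.real))
        entries = [
            ModeEntry(n=i + 1, lam=entries[j].lam, residual=entries[j].residual,
                      source=entries[j].source)
            for i, j in enumerate(order)
        ]
    return ModeTable(dim=dim, nu=nu, gamma=gamma, entries=entries, p=p_eff,
                     metadata=metadata)
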