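"""Reflected Brownian motion in the shell — an independent validation oracle.

Simulates spins performing Gaussian steps between two reflecting circles
(2D) or spheres (3D) and accumulates the dipole-field correlation
<f(x_0) f(x_t)> along the paths.  Nothing here touches the eigenfunction
machinery, so agreement with the mode-sum K(t) validates the propagator
expansion end to end.  Used by the test suite; not a production estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["correlation_random_walk", "WalkResult"]


@dataclass(frozen=True)
class WalkResult:
    taus: np.ndarray      # nondimensional times Dt/R^2
    K: np.ndarray         # correlation estimate, in units of delta_omega^2
    stderr: np.ndarray    # standard error of the mean
    n_walkers: int
    step_sigma: float
    seed: int


def _reflect_radial(x: np.ndarray, gamma: float) -> None:
    """Specular reflection in the radius at both shells (in place).

    A point at radius r < 1 maps to 2 - r along the same ray, r > gamma maps
    to 2*gamma - r; repeated until inside (multiple reflections are rare for
    small steps).
    """
    for _ in range(10):
        r = np.sqrt(np.sum(x**2, axis=1))
        inner = r < 1.0
        outer = r > gamma
        if not (inner.any() or outer.any()):
            return
        scale = np.ones_like(r)
        scale[inner] = (2.0 - r[inner]) / r[inner]
        scale[outer] = (2.0 * gamma - r[outer]) / r[outer]
        x *= scale[:, None]
    raise RuntimeError("reflection did not settle; step size too large?")


def correlation_random_walk(dim: str, gamma: float, taus: Sequence[float],
                            n_walkers: int = 100_000,
                            step_sigma: float | None = None,
                            seed: int = 0) -> WalkResult:
    """Monte Carlo estimate of K(tau)/delta_omega^2 at nondimensional times.

    Works in units R = 1, D = 1.  Each coordinate advances by a Gaussian step
    of standard deviation ``step_sigma`` (default 0.01 * (gamma - 1)), which
    corresponds to a time increment sigma^2 / 2 per step; initial positions
    are uniform in the shell volume.
    """
    if dim not in ("cyl", "sph"):
        raise ValueError(f"dim must be 'cyl' or 'sph', got {dim!r}")
    taus = np.asarray(sorted(taus), dtype=float)
    if np.any(taus < 0):
        raise ValueError("times must be >= 0")
    if step_sigma is None:
        step_sigma = 0.01 * (gamma - 1.0)
    rng = np.random.default_rng(seed)
    d = 2 if dim == "cyl" else 3
    dt = step_sigma**2 / 2.0

    # uniform start in the shell: radius from the volume-weighted inverse CDF
    u = rng.uniform(0.0, 1.0, n_walkers)
    if dim == "cyl":
        r0 = np.sqrt(1.0 + u * (gamma**2 - 1.0))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_walkers)
        x = np.column_stack([r0 * np.cos(phi), r0 * np.sin(phi)])
    else:
        r0 = np.cbrt(1.0 + u * (gamma**3 - 1.0))
        vec = rng.standard_normal((n_walkers, 3))
        vec /= np.linalg.norm(vec, axis=1)[:, None]
        x = r0[:, None] * vec

    def dipole(pos: np.ndarray) -> np.ndarray:
        r2 = np.sum(pos**2, axis=1)
        if dim == "cyl":
            # cos(2 phi)/rho^2 = (x^2 - y^2)/r^2 / r^2
            return (pos[:, 0] ** 2 - pos[:, 1] ** 2) / r2**2
        r = np.sqrt(r2)
        return (3.0 * pos[:, 2] ** 2 / r2 - 1.0) / r**3

    f0 = dipole(x)
    K = np.empty_like(taus)
    err = np.empty_like(taus)
    steps_done = 0
    for i, tau in enumerate(taus):
        target = int(round(tau / dt))
        for _ in range(target - steps_done):
            x += rng.standard_normal((n_walkers, d)) * step_sigma
            _reflect_radial(x, gamma)
        steps_done = target
        prod = f0 * dipole(x)
        K[i] = prod.mean()
        err[i] = prod.std(ddof=1) / np.sqrt(n_walkers)
    return WalkResult(taus=taus, K=K, stderr=err, n_walkers=n_walkers,
                      step_sigma=float(step_sigma), seed=seed)
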