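"""Shell geometry shared by every layer of the package."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ShellGeometry:
    """Annulus (2D) or spherical shell (3D) ``R <= r <= gamma*R``.

    Parameters
    ----------
    R : float
        Inner radius (any length unit; all internal computations are done in
        the nondimensional radial coordinate ``rho = r/R``).
    gamma : float
        Outer-to-inner radius ratio, ``gamma >= 1``.
    """

    R: float = 1.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"inner radius must be positive, got R={self.R}")
        if not self.gamma >= 1:
            raise ValueError(f"shell ratio must satisfy gamma >= 1, got {self.gamma}")

    @property
    def outer(self) -> float:
        return self.gamma * self.R

    def volume(self, dim: str) -> float:
        """Shell volume: pi R^2 (gamma^2-1) for 'cyl', 4/3 pi R^3 (gamma^3-1) for 'sph'."""
        import math

        if dim == "cyl":
            return math.pi * self.R**2 * (self.gamma**2 - 1.0)
        if dim == "sph":
            return 4.0 / 3.0 * math.pi * self.R**3 * (self.gamma**3 - 1.0)
        raise ValueError(f"dim must be 'cyl' or 'sph', got {dim!r}")


def check_dim(dim: str) -> str:
    if dim not in ("cyl", "sph"):
        raise ValueError(f"dim must be 'cyl' or 'sph', got {dim!r}")
    return dim
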