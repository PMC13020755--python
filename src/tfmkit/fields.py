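"""Core containers shared by every pipeline stage.

Coordinate convention (used throughout the package): images and fields are
row-major 2D arrays; ``x`` is the column index, ``y`` the row index, the
origin is the top-left sample and ``y`` displacement is positive downward.
Fields are sampled at pixel/grid-cell centers, with physical position
``(x * spacing, y * spacing)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["VectorField2D", "ElasticSubstrate"]


@dataclass
class VectorField2D:
    """Regular-grid two-component vector field.

    The common currency between pipeline stages: displacement fields
    (``units`` of ``"px"`` or ``"um"``) and traction fields (``"Pa"``).

    Parameters
    ----------
    u, v : ndarray
        x- (column) and y- (row, positive down) components, same shape.
    spacing : float
        Physical distance between neighbouring samples, in micrometres.
    units : str
        Units of the components (``"px"``, ``"um"`` or ``"Pa"``).
    meta : dict
        Free-form provenance (parameters that produced the field).
    """

    u: np.ndarray
    v: np.ndarray
    spacing: float
    units: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError(
                f"component shapes differ: {self.u.shape} vs {self.v.shape}"
            )
        if self.u.ndim != 2:
            raise ValueError("VectorField2D components must be 2D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def copy(self) -> "VectorField2D":
        return VectorField2D(
            self.u.copy(), self.v.copy(), self.spacing, self.units, dict(self.meta)
        )

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical sample positions ``(x, y)`` in µm, each of field shape."""
        ny, nx = self.shape
        x = np.arange(nx) * self.spacing
        y = np.arange(ny) * self.spacing
        return np.meshgrid(x, y)

    def to_um(self, pixel_size: float) -> "VectorField2D":
        """Convert a pixel-valued displacement field to micrometres."""
        if self.units == "um":
            return self.copy()
        if self.units != "px":
            raise ValueError(f"cannot convert units {self.units!r} to um")
        out = VectorField2D(
            self.u * pixel_size, self.v * pixel_size, self.spacing, "um", dict(self.meta)
        )
        return out

    def scaled(self, factor: float) -> "VectorField2D":
        return VectorField2D(
            self.u * factor, self.v * factor, self.spacing, self.units, dict(self.meta)
        )


@dataclass(frozen=True)
class ElasticSubstrate:
    """Linear elastic substrate: Young's modulus ``E`` (Pa), Poisson ratio
    ``nu`` and optional finite ``thickness`` (µm; ``None`` means a
    semi-infinite half-space)."""

    E: float = 20_000.0
    nu: float = 0.5
    thickness: float | None = None

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.thickness is not None and not self.thickness > 0:
            raise ValueError("thickness must be positive (or None for half-space)")
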