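"""Parametric synthetic palate geometry.

Generates a two-layer (resin plate over denture-supporting mucosa) model of
the palatal vault between the first and second molars.  The mucosa rests on
rigid bone (its top surface is fully constrained) and its thickness varies
over 14 segments, mirroring the clinical practice of measuring mucosal
thickness at 14 sites and building those measurements into the model.

Coordinate convention (mm-N-MPa unit system throughout the package):

* ``x`` runs left-right with the midline at ``x = 0``,
* ``y`` runs anterior to posterior over ``[0, arch_length]``,
* ``z`` increases from the bone surface (top, fixed) toward the oral
  cavity, so the bite load compresses the mucosa in the ``-z`` sense.

The vault is a cosine arch of configurable rise; ``dome_height = 0``
degenerates to a flat bilayer slab, which the solver verification fixtures
rely on because it has closed-form volumes and stress states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PalateConfig",
    "ThicknessMap",
    "LayeredGeometry",
    "sample_thickness_map",
    "build_geometry",
    "N_SEGMENTS",
]

#: Number of mucosal thickness segments (measurement sites).
N_SEGMENTS = 14

#: Rows along the arch (anterior -> posterior) x left/right columns.
SEGMENT_ROWS = 7
SEGMENT_COLS = 2


def _default_thickness_bounds() -> list[tuple[float, float]]:
    """Per-segment (min, max) thickness in mm.

    Palatal mucosa is thin anteriorly and thickens toward the posterior
    lateral slopes; literature ranges span roughly 1-6 mm.  Bounds grow
    with the row index (anterior row 0 to posterior row 6), identical for
    the left and right column of each row.
    """
    bounds = []
    for row in range(SEGMENT_ROWS):
        lo = 1.0 + 0.3 * row
        hi = 2.5 + 0.5 * row
        bounds.extend([(lo, hi), (lo, hi)])
    return bounds


@dataclass(frozen=True)
class PalateConfig:
    """Parameters of the synthetic palate model.

    All lengths in mm.  ``mesh_edge`` is the target element size; the
    clinical reference resolution is 0.5 mm, but studies on the synthetic
    geometry are routinely run coarser.
    """

    arch_length: float = 25.0
    arch_half_width: float = 15.0
    dome_height: float = 8.0
    plate_thickness: float = 1.5
    thickness_bounds: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(_default_thickness_bounds())
    )
    mesh_edge: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arch_length", "arch_half_width", "plate_thickness", "mesh_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.dome_height < 0:
            raise ValueError(f"dome_height must be >= 0, got {self.dome_height}")
        if len(self.thickness_bounds) != N_SEGMENTS:
            raise ValueError(
                f"thickness_bounds must have exactly {N_SEGMENTS} entries, "
                f"got {len(self.thickness_bounds)}"
            )
        for i, (lo, hi) in enumerate(self.thickness_bounds):
            if lo <= 0 or hi <= 0:
                raise ValueError(f"segment {i + 1}: thickness bounds must be positive")
            if lo > hi:
                raise ValueError(f"segment {i + 1}: min thickness {lo} > max {hi}")

    def with_(self, **kwargs) -> "PalateConfig":
        return replace(self, **kwargs)

    @property
    def segment_centers(self) -> np.ndarray:
        """(14, 2) array of (x, y) segment-center footprint coordinates.

        Segments are numbered 1..14 row-major: row 0 anterior to row 6
        posterior, left column then right column within each row.
        """
        w, length = self.arch_half_width, self.arch_length
        xs = np.array([-w / 2.0, w / 2.0])
        ys = (np.arange(SEGMENT_ROWS) + 0.5) * length / SEGMENT_ROWS
        centers = np.empty((N_SEGMENTS, 2))
        for row in range(SEGMENT_ROWS):
            for col in range(SEGMENT_COLS):
                centers[row * SEGMENT_COLS + col] = (xs[col], ys[row])
        return centers


@dataclass(frozen=True)
class ThicknessMap:
    """Sampled mucosal thickness (mm) per segment, segment ids 1..14."""

    thickness: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thickness) != N_SEGMENTS:
            raise ValueError(
                f"expected {N_SEGMENTS} thickness values, got {len(self.thickness)}"
            )
        if any(t <= 0 for t in self.thickness):
            raise ValueError("all thickness values must be strictly positive")

    def __getitem__(self, segment_id: int) -> float:
        if not 1 <= segment_id <= N_SEGMENTS:
            raise KeyError(f"segment_id must be in 1..{N_SEGMENTS}")
        return self.thickness[segment_id - 1]

    def as_grid(self) -> np.ndarray:
        """Thickness as a (rows, cols) = (7, 2) grid."""
        return np.asarray(self.thickness, dtype=float).reshape(SEGMENT_ROWS, SEGMENT_COLS)

    def mirrored(self) -> "ThicknessMap":
        """Swap left and right columns."""
        grid = self.as_grid()[:, ::-1]
        return ThicknessMap(tuple(grid.ravel()))

    @property
    def max_thickness(self) -> float:
        return max(self.thickness)


def sample_thickness_map(config: PalateConfig, seed: int | None = None) -> ThicknessMap:
    """Draw one thickness per segment, uniformly within its configured bounds.

    Deterministic for a given ``(config, seed)``; ``seed`` defaults to
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo = np.array([b[0] for b in config.thickness_bounds])
    hi = np.array([b[1] for b in config.thickness_bounds])
    values = lo + rng.random(N_SEGMENTS) * (hi - lo)
    return ThicknessMap(tuple(float(v) for v in values))


class LayeredGeometry:
    """Continuous bilayer geometry built from a config and a thickness map.

    Exposes the three defining surfaces as functions of the footprint
    coordinate (x, y):

    * ``bone_z``: top of the mucosa (bonded to bone, fixed),
    * ``interface_z``: mucosa-plate interface (``bone_z + thickness``),
    * ``oral_z``: plate oral surface (``interface_z + plate_thickness``).

    The segment-center thicknesses are blended over the footprint by
    bilinear interpolation (clamped to the center lattice outside it), so
    evaluating ``thickness`` at a segment center returns exactly the
    sampled value while remaining C0 between segments.
    """

    def __init__(self, config: PalateConfig, thickness_map: ThicknessMap):
        self.config = config
        self.thickness_map = thickness_map
        w, length = config.arch_half_width, config.arch_length
        self._xc = np.array([-w / 2.0, w / 2.0])
        self._yc = (np.arange(SEGMENT_ROWS) + 0.5) * length / SEGMENT_ROWS
        self._grid = thickness_map.as_grid()  # (rows=y, cols=x)

    # -- footprint -----------------------------------------------------

    @property
    def footprint(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the modelled region."""
        c = self.config
        return (-c.arch_half_width, c.arch_half_width, 0.0, c.arch_length)

    @property
    def footprint_area(self) -> float:
        c = self.config
        return 2.0 * c.arch_half_width * c.arch_length

    def segment_at(self, x, y) -> np.ndarray:
        """Segment id (1..14) containing each footprint point."""
        c = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        row = np.clip(
            np.floor(y / c.arch_length * SEGMENT_ROWS).astype(int), 0, SEGMENT_ROWS - 1
        )
        col = (x >= 0).astype(int)
        return row * SEGMENT_COLS + col + 1

    # -- surfaces ------------------------------------------------------

    def thickness(self, x, y) -> np.ndarray:
        """Blended mucosal thickness (mm) at footprint points."""
        x = np.clip(np.asarray(x, dtype=float), self._xc[0], self._xc[-1])
        y = np.clip(np.asarray(y, dtype=float), self._yc[0], self._yc[-1])
        # bilinear on the 2 x 7 center lattice
        tx = (x - self._xc[0]) / (self._xc[1] - self._xc[0])
        iy = np.clip(np.searchsorted(self._yc, y) - 1, 0, SEGMENT_ROWS - 2)
        ty = (y - self._yc[iy]) / (self._yc[iy + 1] - self._yc[iy])
        g = self._grid
        left = g[iy, 0] * (1 - ty) + g[iy + 1, 0] * ty
        right = g[iy, 1] * (1 - ty) + g[iy + 1, 1] * ty
        return left * (1 - tx) + right * tx

    def bone_z(self, x, y=None) -> np.ndarray:
        """Bone-surface height; the vault rises (-z) toward the midline."""
        c = self.config
        x = np.asarray(x, dtype=float)
        out = -c.dome_height * np.cos(np.pi * x / (2.0 * c.arch_half_width))
        return out + np.zeros_like(np.asarray(y if y is not None else 0.0, dtype=float))

    def interface_z(self, x, y) -> np.ndarray:
        return self.bone_z(x, y) + self.thickness(x, y)

    def oral_z(self, x, y) -> np.ndarray:
        return self.interface_z(x, y) + self.config.plate_thickness


def build_geometry(config: PalateConfig, thickness_map: ThicknessMap) -> LayeredGeometry:
    """Assemble the layered geometry from a config and a thickness map."""
    return LayeredGeometry(config, thickness_map)
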