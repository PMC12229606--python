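"""Geometry of the detector array, the orbital scan and the sample-plane grid.

All lengths are in nanometers in sample space; the origin of every grid is the
center of the targeted coordinate pattern (TCP), x to the right, y up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectorGeometry", "OrbitGeometry", "GridSpec"]


@dataclass(frozen=True)
class DetectorGeometry:
    """A square SPAD array imaged into the sample plane (descanned).

    Parameters
    ----------
    n_rows, n_cols : int
        Array dimensions; the default 5x5 array has 25 elements indexed
        row-major 0..24 with element 12 in the center.
    pitch : float
        Element-to-element distance projected into the sample plane [nm].
    element_size : float
        Active-area side length projected into the sample plane [nm].
    excluded_elements : frozenset of int
        Hot elements dropped from both the MDFs and the photon counts.
    """

    n_rows: int = 5
    n_cols: int = 5
    pitch: float = 150.0
    element_size: float = 100.0
    excluded_elements: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one element")
        if self.element_size <= 0 or self.pitch <= 0:
            raise ValueError("pitch and element_size must be positive")
        if self.element_size > self.pitch:
            raise ValueError("element_size must not exceed pitch")
        bad = [j for j in self.excluded_elements
               if not 0 <= j < self.n_rows * self.n_cols]
        if bad:
            raise ValueError(f"excluded elements out of range: {bad}")
        object.__setattr__(self, "excluded_elements",
                           frozenset(self.excluded_elements))

    @property
    def n_elements(self) -> int:
        """Number of active elements N_d (hot pixels excluded)."""
        return self.n_rows * self.n_cols - len(self.excluded_elements)

    @property
    def active_elements(self) -> np.ndarray:
        """Sorted row-major indices of the active elements."""
        all_idx = np.arange(self.n_rows * self.n_cols)
        mask = ~np.isin(all_idx, sorted(self.excluded_elements))
        return all_idx[mask]

    def element_centers(self) -> np.ndarray:
        """(N_d, 2) sample-plane centers (x, y) of the active elements [nm].

        Row 0 is the top row (largest y), matching image convention.
        """
        idx = self.active_elements
        rows, cols = np.divmod(idx, self.n_cols)
        x = (cols - (self.n_cols - 1) / 2.0) * self.pitch
        y = ((self.n_rows - 1) / 2.0 - rows) * self.pitch
        return np.column_stack([x, y]).astype(float)

    @property
    def fov_halfwidth(self) -> float:
        """Half-width of the detector footprint in the sample plane [nm]."""
        half_cols = (self.n_cols - 1) / 2.0 * self.pitch + self.element_size / 2
        half_rows = (self.n_rows - 1) / 2.0 * self.pitch + self.element_size / 2
        return max(half_cols, half_rows)


@dataclass(frozen=True)
class OrbitGeometry:
    """The circular targeted coordinate pattern (TCP).

    The beam visits ``n_positions`` points on a circle of diameter ``L``;
    position i sits at delta_i = (L/2) (cos theta_i, sin theta_i) with
    theta_i = alpha0 + direction * 2 pi i / n_positions.
    """

    L: float = 90.0                 # TCP circle diameter [nm]
    alpha0: float = 0.0             # starting phase [rad]
    direction: int = +1             # +1 counter-clockwise, -1 clockwise
    n_positions: int = 32           # N_c probed points per orbit
    period: float = 1.92            # orbit period [ms]

    def __post_init__(self):
        if self.L < 0:
            raise ValueError("L must be non-negative")
        if self.n_positions < 3:
            raise ValueError("need at least 3 orbit positions")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def radius(self) -> float:
        return self.L / 2.0

    @property
    def dwell_time(self) -> float:
        """Dwell per angular position [ms]."""
        return self.period / self.n_positions

    def angles(self) -> np.ndarray:
        i = np.arange(self.n_positions)
        return self.alpha0 + self.direction * 2.0 * np.pi * i / self.n_positions

    def offsets(self) -> np.ndarray:
        """(N_c, 2) beam offsets delta_i from the TCP center [nm]."""
        th = self.angles()
        return self.radius * np.column_stack([np.cos(th), np.sin(th)])


@dataclass(frozen=True)
class GridSpec:
    """Sample-plane pixel grid for MDF maps.

    Pixel (row, col) = (iy, ix) has its center at
    x = x0 + (ix + 0.5) * pixel_size, y = y0 + (iy + 0.5) * pixel_size
    (pixels are half-open [k*s, (k+1)*s) boxes). By default the grid is
    centered on the TCP center. Row index increases with y.
    """

    pixel_size: float = 2.5         # [nm]
    n_pixels: int = 1000            # square grid side [px]

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_pixels < 2:
            raise ValueError("grid needs at least 2 pixels per side")

    @property
    def extent(self) -> float:
        """Full grid side length [nm]."""
        return self.pixel_size * self.n_pixels

    @property
    def halfwidth(self) -> float:
        return self.extent / 2.0

    def axis(self) -> np.ndarray:
        """Pixel-center coordinates along one axis [nm]."""
        k = np.arange(self.n_pixels)
        return -self.halfwidth + (k + 0.5) * self.pixel_size

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        ax = self.axis()
        return np.meshgrid(ax, ax, indexing="xy")

    def to_index(self, xy: np.ndarray) -> np.ndarray:
        """Fractional (col, row) pixel coordinates of sample points (x, y)."""
        xy = np.asarray(xy, dtype=float)
        return (xy + self.halfwidth) / self.pixel_size - 0.5

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        h = self.halfwidth - margin
        return np.all(np.abs(xy) <= h, axis=-1)
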