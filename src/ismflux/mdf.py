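"""Molecule detection functions (MDFs) for an orbital doughnut scan.

The MDF p_ij(r) is the probability that a photon emitted by a molecule at
sample position r is detected while the beam sits at orbit position i, in
detector element j. In descanned mode the whole set derives from the base
stack I_0j recorded (or simulated) with the beam at the TCP center:

    values[i][j](r) = I_0j(r - delta_i)

with delta_i the beam offset of orbit position i. MDFSet therefore stores the
base stack once and applies the orbit shift on the fly during interpolation,
which is exact rather than an approximation of a materialized stack.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._interp import bilinear_sample
from .geometry import DetectorGeometry, GridSpec, OrbitGeometry
from .optics import OpticsModel

__all__ = [
    "MDFSet", "SmoothingSpec", "simulate_base_mdf", "simulate_mdf",
    "expand_orbit", "prepare_measured_mdf", "reduce_to_single_element",
]


@dataclass(frozen=True)
class SmoothingSpec:
    """Uniform-then-Gaussian smoothing applied to measured MDF images.

    The kernel sizes are free parameters (the criterion in practice is
    "visually smooth"); defaults are a 5 px uniform filter followed by a
    2 px Gaussian blur.
    """

    uniform_size: int = 5
    gaussian_sigma: float = 2.0
    enabled: bool = True


@dataclass(frozen=True)
class MDFSet:
    """A full set of molecule detection functions.

    Attributes
    ----------
    base : ndarray, shape (N_d, H, W)
        Unshifted maps I_0j on the sample-plane grid, indexed [iy, ix]
        (y increases with the row index). Non-negative.
    grid : GridSpec
    detector : DetectorGeometry
    orbit : OrbitGeometry
    provenance : {"simulated", "measured"}
    """

    base: np.ndarray
    grid: GridSpec
    detector: DetectorGeometry
    orbit: OrbitGeometry
    provenance: str = "simulated"

    def __post_init__(self):
        base = np.asarray(self.base, dtype=float)
        if base.ndim != 3:
            raise ValueError("base must be a (N_d, H, W) stack")
        if base.shape[1] != self.grid.n_pixels or \
                base.shape[2] != self.grid.n_pixels:
            raise ValueError("base maps do not match the grid")
        if base.shape[0] != self.detector.n_elements:
            raise ValueError(
                f"expected {self.detector.n_elements} maps, got {base.shape[0]}")
        if np.any(base < 0):
            raise ValueError("MDF values must be non-negative")
        if self.provenance not in ("simulated", "measured"):
            raise ValueError("provenance must be 'simulated' or 'measured'")
        margin = self.orbit.radius + self.grid.pixel_size
        if margin >= self.grid.halfwidth:
            raise ValueError("orbit offsets exceed the grid margin")
        object.__setattr__(self, "base", base)

    # -- basic shape info ---------------------------------------------------

    @property
    def n_positions(self) -> int:
        return self.orbit.n_positions

    @property
    def n_elements(self) -> int:
        return self.base.shape[0]

    @property
    def offsets(self) -> np.ndarray:
        return self.orbit.offsets()

    def sampling_halfwidth(self, extra_margin: float = 0.0) -> float:
        """Largest |x|,|y| at which the full set can be interpolated [nm]."""
        return (self.grid.halfwidth - self.orbit.radius
                - self.grid.pixel_size - extra_margin)

    # -- evaluation ---------------------------------------------------------

    def sample(self, xy: np.ndarray, rows: np.ndarray | None = None
               ) -> np.ndarray:
        """Interpolated m_ij at emitter positions.

        Parameters
        ----------
        xy : (..., 2) positions in nm.
        rows : optional subset of orbit-position indices.

        Returns
        -------
        ndarray of shape (..., N_c_sel, N_d), clipped at zero.
        """
        xy = np.asarray(xy, dtype=float)
        offs = self.offsets if rows is None else self.offsets[np.asarray(rows)]
        query = xy[..., None, :] - offs                 # (..., Nc, 2)
        vals = bilinear_sample(self.base, self.grid, query)
        return np.clip(vals, 0.0, None)

    def sum_signal(self, xy: np.ndarray) -> np.ndarray:
        """Sum over all (i, j) of m_ij at positions xy (expected-rate shape)."""
        return self.sample(xy).sum(axis=(-2, -1))

    def page(self, i: int, j: int) -> np.ndarray:
        """Materialize the map for orbit position i, element j (bilinear)."""
        dx, dy = self.offsets[i]
        s = self.grid.pixel_size
        # shift in (row, col) = (y, x) pixel units; content moves by +delta.
        # snap near-integer shifts: a 1e-16 residue would zero a border row
        shift = np.array([dy / s, dx / s])
        near = np.abs(shift - np.round(shift)) < 1e-9
        shift[near] = np.round(shift[near])
        shifted = ndimage.shift(self.base[j], tuple(shift), order=1,
                                mode="constant", cval=0.0)
        return np.clip(shifted, 0.0, None)

    @property
    def values(self) -> np.ndarray:
        """Full (N_c, N_d, H, W) stack. Large; prefer `sample` for points."""
        return np.stack([
            np.stack([self.page(i, j) for j in range(self.n_elements)])
            for i in range(self.n_positions)])

    # -- derived sets -------------------------------------------------------

    def with_orbit(self, orbit: OrbitGeometry) -> "MDFSet":
        return replace(self, orbit=orbit)


def simulate_base_mdf(optics: OpticsModel, det: DetectorGeometry,
                      grid: GridSpec) -> np.ndarray:
    """Simulate the unshifted MDF stack I_0j (beam at the TCP center).

    I_0j(r) = Exc(r) * Det_j(r): the doughnut excitation profile times the
    detection PSF integrated over element j's square active area (element
    offsets are fixed in sample space, descanned detection). The stack is
    normalized so that the sum over elements at the doughnut intensity
    maximum equals 1.
    """
    if grid.halfwidth < det.fov_halfwidth:
        raise ValueError(
            f"grid halfwidth {grid.halfwidth:.0f} nm smaller than the "
            f"detector footprint {det.fov_halfwidth:.0f} nm")
    ax = grid.axis()
    X, Y = grid.meshgrid()                      # (H, W), y up along rows
    exc = optics.excitation(X, Y)
    centers = det.element_centers()
    maps = np.empty((len(centers), grid.n_pixels, grid.n_pixels))
    for k, (cx, cy) in enumerate(centers):
        dx = optics.element_detection_1d(ax, cx, det.element_size)
        dy = optics.element_detection_1d(ax, cy, det.element_size)
        maps[k] = exc * (dy[:, None] * dx[None, :])
    # normalization point: the doughnut maximum on the +x axis
    rmax = optics.doughnut_peak_radius
    exc_max = optics.excitation(rmax, 0.0)
    det_sum = sum(
        optics.element_detection_1d(rmax, cx, det.element_size)
        * optics.element_detection_1d(0.0, cy, det.element_size)
        for cx, cy in centers)
    norm = exc_max * det_sum
    if norm <= 0:
        raise ValueError("degenerate optics: zero detection at doughnut peak")
    maps /= norm
    return maps


def expand_orbit(base: np.ndarray, orbit: OrbitGeometry, grid: GridSpec,
                 detector: DetectorGeometry,
                 provenance: str = "simulated") -> MDFSet:
    """Attach an orbit to a base stack, giving the full shifted MDF set.

    The shifts are applied lazily during interpolation; the constructor
    checks that every orbit offset stays inside the grid margin.
    """
    return MDFSet(base=np.asarray(base, dtype=float), grid=grid,
                  detector=detector, orbit=orbit, provenance=provenance)


def simulate_mdf(optics: OpticsModel, det: DetectorGeometry,
                 orbit: OrbitGeometry,
                 grid: GridSpec | None = None) -> MDFSet:
    """Convenience: simulate the base stack and expand it over the orbit."""
    grid = grid or GridSpec()
    base = simulate_base_mdf(optics, det, grid)
    return expand_orbit(base, orbit, grid, det, provenance="simulated")


def prepare_measured_mdf(scan_images: np.ndarray, x_rescale: float,
                         smoothing: SmoothingSpec | None,
                         orbit: OrbitGeometry, grid: GridSpec,
                         detector: DetectorGeometry) -> MDFSet:
    """Turn raster-scanned single-emitter images into a measured MDF set.

    Applies (1) an anisotropic rescale along x about the grid center,
    correcting fast-axis stretch of the galvo scan, (2) uniform + Gaussian
    smoothing, then (3) the orbit expansion. Output provenance is "measured".
    """
    imgs = np.asarray(scan_images, dtype=float)
    if imgs.ndim != 3:
        raise ValueError("scan_images must be a (N_d, H, W) stack")
    if len({im.shape for im in imgs}) != 1:
        raise ValueError("scan images must share one shape")
    if not 0 < x_rescale <= 1.5:
        raise ValueError("x_rescale must be a positive fraction")

    out = imgs
    if x_rescale != 1.0:
        # squeeze content by x_rescale about the image center:
        # out(y, x) = in(y, xc + (x - xc) / x_rescale)
        n = imgs.shape[2]
        xc = (n - 1) / 2.0
        matrix = np.array([[1.0, 0.0], [0.0, 1.0 / x_rescale]])
        offset = np.array([0.0, xc - xc / x_rescale])
        out = np.stack([
            ndimage.affine_transform(im, matrix, offset=offset, order=1,
                                     mode="constant", cval=0.0)
            for im in out])
    if smoothing is not None and smoothing.enabled:
        out = np.stack([
            ndimage.gaussian_filter(
                ndimage.uniform_filter(im, size=smoothing.uniform_size,
                                       mode="constant"),
                sigma=smoothing.gaussian_sigma, mode="constant")
            for im in out])
    out = np.clip(out, 0.0, None)
    return expand_orbit(out, orbit, grid, detector, provenance="measured")


def reduce_to_single_element(mdf: MDFSet) -> MDFSet:
    """Collapse the detector dimension: a virtual single-element detector.

    Sums the maps over all elements, mimicking analysis of the same photons
    recorded without spatial information on the detection side. Idempotent.
    """
    summed = mdf.base.sum(axis=0, keepdims=True)
    side = max(mdf.detector.n_rows, mdf.detector.n_cols) * mdf.detector.pitch
    det = DetectorGeometry(n_rows=1, n_cols=1, pitch=side, element_size=side)
    return MDFSet(base=summed, grid=mdf.grid, detector=det, orbit=mdf.orbit,
                  provenance=mdf.provenance)
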