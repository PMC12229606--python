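"""Fisher information and Cramér-Rao bound maps for MDF sets.

For multinomial counts with cell probabilities p_ij(r) and N total photons,
the Fisher information about the emitter position r = (x, y) is

    F(r) = N * sum_ij  (grad p_ij)(grad p_ij)^T / p_ij,

and the position-uncertainty bound is reported as the rms of the two
per-axis bounds, sigma_CRB = sqrt(tr(F^-1) / 2), matching the
sigma = sqrt((sigma_x^2 + sigma_y^2)/2) convention used for measured
localization spreads. Gradients are central finite differences of the
interpolated p_ij with a step of one MDF pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimator import BackgroundModel, _probabilities_from_m
from .mdf import MDFSet

__all__ = [
    "CRBMap", "fisher_information", "sigma_crb", "crb_map",
    "crb_fov_average", "effective_uncertainty_map",
]


@dataclass(frozen=True)
class CRBMap:
    """sigma_CRB (and per-axis variances) on a decimated sample-plane grid."""

    sigma: np.ndarray           # (ny, nx) rms bound [nm]
    var_x: np.ndarray           # (ny, nx) inverse-Fisher diagonal [nm^2]
    var_y: np.ndarray
    xs: np.ndarray              # (nx,) pixel-center x [nm]
    ys: np.ndarray              # (ny,) pixel-center y [nm]
    N_ref: float                # photon count the map assumes
    sbr: float

    def rescaled(self, N_new: float) -> "CRBMap":
        """The same map at a different photon count (1/sqrt(N) scaling)."""
        f = self.N_ref / N_new
        return replace(self, sigma=self.sigma * np.sqrt(f),
                       var_x=self.var_x * f, var_y=self.var_y * f,
                       N_ref=N_new)

    def at_center(self) -> float:
        """Map value nearest the TCP center."""
        iy = int(np.argmin(np.abs(self.ys)))
        ix = int(np.argmin(np.abs(self.xs)))
        return float(self.sigma[iy, ix])

    def radius_grid(self) -> np.ndarray:
        X, Y = np.meshgrid(self.xs, self.ys)
        return np.hypot(X, Y)


def _fisher_batch(mdf: MDFSet, bkg: BackgroundModel, pts: np.ndarray,
                  N: float, step: float | None = None) -> np.ndarray:
    """Fisher matrices, shape (P, 2, 2), at positions pts (P, 2)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    h = step if step is not None else mdf.grid.pixel_size
    offsets = np.array([[0.0, 0.0], [h, 0], [-h, 0], [0, h], [0, -h]])
    stencil = pts[:, None, :] + offsets             # (P, 5, 2)
    m = mdf.sample(stencil)                         # (P, 5, Nc, Nd)
    p = _probabilities_from_m(m, bkg)
    p0 = p[:, 0]
    gx = (p[:, 1] - p[:, 2]) / (2 * h)
    gy = (p[:, 3] - p[:, 4]) / (2 * h)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_p = np.where(p0 > 0, 1.0 / p0, 0.0)
    F = np.empty((pts.shape[0], 2, 2))
    F[:, 0, 0] = N * (gx * gx * inv_p).sum(axis=(-2, -1))
    F[:, 0, 1] = F[:, 1, 0] = N * (gx * gy * inv_p).sum(axis=(-2, -1))
    F[:, 1, 1] = N * (gy * gy * inv_p).sum(axis=(-2, -1))
    return F


def fisher_information(mdf: MDFSet, bkg: BackgroundModel, r_E: np.ndarray,
                       N: float, step: float | None = None) -> np.ndarray:
    """2x2 Fisher information matrix at emitter position r_E.

    Linear in N. The finite-difference step defaults to one MDF pixel.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    return _fisher_batch(mdf, bkg, np.asarray(r_E, float), N, step=step)[0]


def _sigma_from_F(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sigma_rms, var_x, var_y) from batched 2x2 Fisher matrices."""
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    tr = F[..., 0, 0] + F[..., 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_x = np.where(det > 0, F[..., 1, 1] / det, np.inf)
        var_y = np.where(det > 0, F[..., 0, 0] / det, np.inf)
        sigma = np.where(det > 0, np.sqrt(tr / (2 * det)), np.inf)
    return sigma, var_x, var_y


def sigma_crb(mdf: MDFSet, bkg: BackgroundModel, r_E: np.ndarray,
              N: float) -> float:
    """Cramér-Rao bound sqrt(tr(F^-1)/2) at r_E, in nm (inf if singular)."""
    F = fisher_information(mdf, bkg, r_E, N)
    return float(_sigma_from_F(F)[0])


def crb_map(mdf: MDFSet, bkg: BackgroundModel, N: float,
            decimation: int = 8,
            halfwidth: float | None = None) -> CRBMap:
    """sigma_CRB evaluated on a decimated grid over the map region.

    The region defaults to the detector field of view, clipped to where the
    full MDF set (including the finite-difference stencil) stays
    interpolatable.
    """
    h = mdf.grid.pixel_size
    max_half = mdf.sampling_halfwidth(extra_margin=h)
    half = min(halfwidth if halfwidth is not None else
               mdf.detector.fov_halfwidth, max_half)
    ax = mdf.grid.axis()
    keep = np.abs(ax) <= half
    xs = ax[keep][::decimation]
    ys = ax[keep][::decimation]
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    F = np.empty((pts.shape[0], 2, 2))
    chunk = 4096
    for k in range(0, pts.shape[0], chunk):
        F[k:k + chunk] = _fisher_batch(mdf, bkg, pts[k:k + chunk], N)
    sigma, var_x, var_y = _sigma_from_F(F)
    shape = X.shape
    return CRBMap(sigma=sigma.reshape(shape), var_x=var_x.reshape(shape),
                  var_y=var_y.reshape(shape), xs=xs, ys=ys, N_ref=N,
                  sbr=bkg.sbr)


def crb_fov_average(cmap: CRBMap, fov_diameter: float) -> float:
    """Mean sigma_CRB over the centered disk of the given diameter [nm].

    A degenerate (empty) disk returns the value at the TCP center.
    """
    if fov_diameter < 0:
        raise ValueError("fov_diameter must be non-negative")
    r = cmap.radius_grid()
    inside = r <= fov_diameter / 2.0
    if not inside.any():
        return cmap.at_center()
    return float(cmap.sigma[inside].mean())


def effective_uncertainty_map(mdf: MDFSet, bkg: BackgroundModel,
                              N_center: float, decimation: int = 8,
                              halfwidth: float | None = None) -> CRBMap:
    """CRB scaled by the position-dependent expected photon count.

    At constant laser power the photon yield varies with the emitter's
    position in the doughnut orbit: N(x, y) = N_center * S(x, y)/S(0) with
    S the sum of all MDFs. The effective bound is
    sigma_CRB(x, y; N_ref) * sqrt(N_ref / N(x, y)); points with zero yield
    map to +inf.
    """
    if N_center <= 0:
        raise ValueError("N_center must be positive")
    cmap = crb_map(mdf, bkg, N_center, decimation=decimation,
                   halfwidth=halfwidth)
    X, Y = np.meshgrid(cmap.xs, cmap.ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    S = mdf.sum_signal(pts).reshape(X.shape)
    S0 = float(mdf.sum_signal(np.zeros(2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(S > 0, np.sqrt(S0 / S), np.inf)
    return replace(cmap, sigma=cmap.sigma * scale,
                   var_x=cmap.var_x * scale ** 2,
                   var_y=cmap.var_y * scale ** 2)
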