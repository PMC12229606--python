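"""Vectorized bilinear point-sampling of map stacks.

scipy.ndimage.map_coordinates cannot batch one set of sample points across a
stack of maps without replicating the coordinate arrays per map, which is the
hot path of both the likelihood search and the Fisher-information maps. The
gather below does the same order-1 interpolation for all maps at once and is
cross-checked against map_coordinates in the test suite.
"""

from __future__ import annotations

import numpy as np

from .geometry import GridSpec


def bilinear_sample(stack: np.ndarray, grid: GridSpec,
                    xy: np.ndarray) -> np.ndarray:
    """Sample a (..., H, W) stack of maps at sample-plane points.

    Parameters
    ----------
    stack : ndarray, shape (n_maps, H, W)
        Maps indexed [iy, ix] with y increasing along axis -2.
    grid : GridSpec
        Grid on which the maps live.
    xy : ndarray, shape (..., 2)
        Sample-plane points (x, y) in nm. Points must lie inside the hull of
        pixel centers (half a pixel inside the physical grid edge).

    Returns
    -------
    ndarray, shape xy.shape[:-1] + (n_maps,)
    """
    xy = np.asarray(xy, dtype=float)
    pts = xy.reshape(-1, 2)
    f = grid.to_index(pts)                      # fractional (col, row)
    n = grid.n_pixels
    eps = 1e-9
    if np.any(f < -eps) or np.any(f > n - 1 + eps):
        bad = pts[np.any((f < -eps) | (f > n - 1 + eps), axis=1)][0]
        raise ValueError(
            f"sample point ({bad[0]:.1f}, {bad[1]:.1f}) nm outside the "
            f"interpolation domain of the {n}x{n} px grid")
    f = np.clip(f, 0.0, n - 1 - eps)
    fx, fy = f[:, 0], f[:, 1]
    ix = fx.astype(np.intp)
    iy = fy.astype(np.intp)
    np.minimum(ix, n - 2, out=ix)
    np.minimum(iy, n - 2, out=iy)
    wx = fx - ix
    wy = fy - iy

    v00 = stack[:, iy, ix]
    v01 = stack[:, iy, ix + 1]
    v10 = stack[:, iy + 1, ix]
    v11 = stack[:, iy + 1, ix + 1]
    out = ((1 - wy) * ((1 - wx) * v00 + wx * v01)
           + wy * ((1 - wx) * v10 + wx * v11))    # (n_maps, P)
    return np.moveaxis(out, 0, -1).reshape(xy.shape[:-1] + (stack.shape[0],))
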