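"""Orbit-parameter calibration: reference-bead fits and self-calibration.

The orbital scan is described by three parameters: diameter L, starting
phase alpha_0, and rotation direction. Galvo inertia makes the executed
orbit differ from the commanded one, so both must be measured. Two routes:

* reference_calibration: localize a bright bead per orbit angle against the
  unshifted MDFs; in descanned detection the bead's apparent position
  traces the orbit mirrored through the bead, so a circle fit recovers
  (L, alpha_0, direction).
* self_calibrate_L: exploit the same effect on single-molecule events by
  localizing 4 quadrants of 8 consecutive orbit angles with MDF sets built
  for candidate L values; the quadrant positions agree only at the true L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .estimator import (BackgroundModel, EventMatrix, SearchSpec,
                        localize_mle, localize_per_subset, quadrant_subsets)
from .geometry import OrbitGeometry
from .mdf import MDFSet
from .simulate import CountTensor

__all__ = ["OrbitFit", "reference_calibration", "self_calibrate_L",
           "fit_circle"]


@dataclass(frozen=True)
class OrbitFit:
    """Recovered orbit parameters."""

    radius: float               # nm (L = 2 * radius)
    alpha0: float               # rad, phase of orbit position 0
    direction: int              # +1 or -1
    center: tuple               # (x, y) nm, bead position for reference fits
    residual_rms: float         # nm, circle-fit residual

    @property
    def L(self) -> float:
        return 2.0 * self.radius


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle fit: algebraic (Kåsa) then geometric refinement.

    Returns (center (2,), radius, residual_rms). Deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.all(np.isfinite(sol)):
        raise ValueError("rank-deficient circle fit")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx ** 2 + cy ** 2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    r = float(np.sqrt(r2))

    def residual(params):
        px, py, pr = params
        return np.hypot(x - px, y - py) - pr

    res = least_squares(residual, x0=[cx, cy, r], method="lm")
    cx, cy, r = res.x
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return np.array([cx, cy]), float(abs(r)), rms


def _direction_from_angles(theta: np.ndarray) -> int:
    """Sign of the consistent angular ordering of consecutive points."""
    d = np.diff(theta)
    d = (d + np.pi) % (2 * np.pi) - np.pi       # wrap to (-pi, pi]
    return 1 if np.median(d) >= 0 else -1


def reference_calibration(tensor: CountTensor, mdf_base: MDFSet,
                          bkg: BackgroundModel,
                          orbits_per_block: int = 100,
                          search: SearchSpec | None = None) -> OrbitFit:
    """Recover the executed orbit from a bright-bead reference measurement.

    Per block of ``orbits_per_block`` orbits, the counts of each orbit angle
    are localized against the unshifted base MDF (an MDF set with a zero-
    diameter orbit). Because the detection is descanned, the apparent bead
    position at angle i is r_bead - delta_i; a circle fit over all blocks'
    points then gives the radius, the starting phase (from the phase of
    point 0) and the rotation direction (from the angular ordering).
    """
    if mdf_base.orbit.L != 0:
        static = OrbitGeometry(L=0.0, alpha0=0.0, direction=1,
                               n_positions=mdf_base.orbit.n_positions,
                               period=mdf_base.orbit.period)
        mdf_base = mdf_base.with_orbit(static)
    n_c = tensor.orbit.n_positions
    n_blocks = tensor.n_orbits // orbits_per_block
    if n_blocks < 1:
        raise ValueError("tensor shorter than one calibration block")
    pts = np.empty((n_blocks, n_c, 2))
    for b in range(n_blocks):
        block = tensor.counts[b * orbits_per_block:
                              (b + 1) * orbits_per_block].sum(axis=0)
        for i in range(n_c):
            ev = EventMatrix(block[i][None, :], n_orbits=orbits_per_block)
            loc = localize_mle(ev, mdf_base, bkg, search=search,
                               rows=np.array([0]))
            pts[b, i] = loc.r_hat
    center, radius, rms = fit_circle(pts.reshape(-1, 2))
    # apparent position q_i = center - delta_i  =>  delta_i = center - q_i
    delta = center[None, None, :] - pts
    mean_delta = delta.mean(axis=0)             # average over blocks
    theta = np.unwrap(np.arctan2(mean_delta[:, 1], mean_delta[:, 0]))
    direction = _direction_from_angles(theta)
    # starting phase: every angle i carries alpha0 = theta_i - dir*2*pi*i/Nc;
    # the circular mean over all i averages out localization quantization
    i = np.arange(n_c)
    phase = theta - direction * 2 * np.pi * i / n_c
    alpha0 = float(np.angle(np.exp(1j * phase).mean()) % (2 * np.pi))
    return OrbitFit(radius=radius, alpha0=alpha0,
                    direction=direction,
                    center=(float(center[0]), float(center[1])),
                    residual_rms=rms)


def self_calibrate_L(event: EventMatrix, mdf_family: dict[float, MDFSet],
                     bkg: BackgroundModel, n_quadrants: int = 4,
                     search: SearchSpec | None = None
                     ) -> tuple[float, np.ndarray, np.ndarray]:
    """Recover the orbit diameter from the event data itself.

    For each candidate-L MDF set, the event's counts are localized in
    ``n_quadrants`` blocks of consecutive orbit angles; the spread metric is
    the rms distance of the quadrant positions from their centroid. Returns
    (L_best, candidate Ls, spread curve). Wrong L values displace the
    quadrant localizations in different directions, so the spread is
    minimized at the true L.
    """
    Ls = np.array(sorted(mdf_family))
    spreads = np.full(Ls.shape, np.nan)
    for k, L in enumerate(Ls):
        mdf = mdf_family[L]
        subsets = quadrant_subsets(mdf.n_positions, n_quadrants)
        locs = localize_per_subset(event, mdf, bkg, subsets, search=search)
        pts = np.array([l.r_hat for l in locs if l is not None])
        if len(pts) < 2:
            continue
        centroid = pts.mean(axis=0)
        spreads[k] = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if np.all(np.isnan(spreads)):
        raise ValueError("all candidate L values were degenerate")
    best = int(np.nanargmin(spreads))
    return float(Ls[best]), Ls, spreads
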