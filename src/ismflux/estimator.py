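"""Multinomial maximum-likelihood position estimation.

An event reduces to the count matrix n_ij (orbit position i, detector element
j). Conditional on the total photon number N, the counts are multinomial with
probabilities

    p_ij(r_E) = sbr/(sbr+1) * m_ij(r_E)/sum(m) + 1/(sbr+1) * 1/(N_c N_d),

the MDF values mixed with a uniform background at signal-to-background ratio
`sbr`. The log-likelihood is evaluated up to the count-only multinomial
constant (the constant cancels in likelihood ratios between candidate
positions and is omitted from reported values). The maximizer is found by a
deterministic brute-force grid search: a coarse lattice pass followed by
local refinements that shrink the step down to the MDF pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mdf import MDFSet

__all__ = [
    "EventMatrix", "BackgroundModel", "LocalizationResult", "SearchSpec",
    "detection_probabilities", "log_likelihood", "localize_mle",
    "localize_per_subset",
]

_LOGLIK_FLOOR = np.finfo(float).min


@dataclass(frozen=True)
class EventMatrix:
    """Reduced photon counts n_ij of one event (orbits summed)."""

    n_ij: np.ndarray
    n_orbits: int = 1

    def __post_init__(self):
        n = np.asarray(self.n_ij)
        if n.ndim != 2:
            raise ValueError("n_ij must be a 2D (N_c, N_d) array")
        if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
            n = np.asarray(n)
            if np.any(n < 0) or np.any(n != np.round(n)):
                raise ValueError("n_ij must hold non-negative integers")
            n = n.astype(np.int64)
        object.__setattr__(self, "n_ij", n.astype(np.int64))

    @property
    def N(self) -> int:
        """Total photon count."""
        return int(self.n_ij.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_ij.shape


@dataclass(frozen=True)
class BackgroundModel:
    """Uniform background at a fixed signal-to-background ratio.

    sbr is the expected signal/background photon ratio; np.inf means no
    background. The background is uniform over orbit positions and elements.
    """

    sbr: float = 10.0

    def __post_init__(self):
        if not self.sbr > 0:
            raise ValueError("sbr must be positive (np.inf for no background)")

    @property
    def signal_fraction(self) -> float:
        return 1.0 if np.isinf(self.sbr) else self.sbr / (self.sbr + 1.0)


@dataclass(frozen=True)
class LocalizationResult:
    """A maximum-likelihood position estimate."""

    x: float
    y: float
    log_likelihood: float
    n_photons: int
    grid_level: int = 0
    on_border: bool = False
    degenerate: bool = False

    @property
    def r_hat(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SearchSpec:
    """Brute-force search region and refinement schedule.

    The search runs on a lattice of step coarse_step_px MDF pixels over the
    square region |x - cx|, |y - cy| <= halfwidth, then refines around the
    best point with refine_levels passes of step halved each time. Ties are
    broken deterministically toward the lowest x, then lowest y.
    """

    center: tuple[float, float] = (0.0, 0.0)
    halfwidth: float | None = None      # default: detector FOV, grid-limited
    coarse_step_px: int = 8
    refine_levels: int = 3


def _probabilities_from_m(m: np.ndarray, bkg: BackgroundModel) -> np.ndarray:
    """Mix MDF values with the uniform background; normalize over (i, j)."""
    tot = m.sum(axis=(-2, -1), keepdims=True)
    n_cells = m.shape[-2] * m.shape[-1]
    if np.isinf(bkg.sbr):
        if np.any(tot <= 0):
            raise ValueError(
                "all-zero MDF at the requested position with infinite SBR")
        return m / tot
    f = bkg.signal_fraction
    signal = np.divide(m, tot, out=np.zeros_like(m), where=tot > 0)
    return f * signal + (1.0 - f) / n_cells


def detection_probabilities(mdf: MDFSet, bkg: BackgroundModel,
                            r_E: np.ndarray,
                            rows: np.ndarray | None = None) -> np.ndarray:
    """Photon-detection probabilities p_ij(r_E); sums to 1 over (i, j).

    `rows` restricts (and renormalizes over) a subset of orbit positions,
    as used for quadrant localizations.
    """
    m = mdf.sample(r_E, rows=rows)
    return _probabilities_from_m(m, bkg)


def log_likelihood(event: EventMatrix, mdf: MDFSet, bkg: BackgroundModel,
                   r_E: np.ndarray,
                   rows: np.ndarray | None = None) -> float:
    """Multinomial log-likelihood at r_E, constant term omitted.

    Returns the representable minimum if any cell with counts has zero
    probability (only possible at infinite SBR).
    """
    p = detection_probabilities(mdf, bkg, r_E, rows=rows)
    n = event.n_ij if rows is None else event.n_ij[np.asarray(rows)]
    return _loglik_from_p(n, p[None])[0]


def _loglik_from_p(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Batched sum n_ij log p_ij for p of shape (P, Nc, Nd)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        occupied = n > 0
        bad = (p <= 0) & occupied
        terms = np.where(occupied, n * logp, 0.0)
    ll = terms.sum(axis=(-2, -1))
    ll[bad.any(axis=(-2, -1))] = _LOGLIK_FLOOR
    return ll


def _lattice(cx: float, cy: float, half: float, step: float,
             xbounds: tuple[float, float],
             ybounds: tuple[float, float]) -> np.ndarray:
    """Candidate positions on a lattice, ordered by (x, then y) ascending."""
    k = np.arange(-np.floor(half / step), np.floor(half / step) + 1)
    xs = np.unique(np.clip(cx + k * step, *xbounds))
    ys = np.unique(np.clip(cy + k * step, *ybounds))
    # x-major ordering makes argmax's first-hit tie-break = lowest x, then y
    pts = np.empty((xs.size * ys.size, 2))
    pts[:, 0] = np.repeat(xs, ys.size)
    pts[:, 1] = np.tile(ys, xs.size)
    return pts


def _batched_loglik(event_n: np.ndarray, mdf: MDFSet, bkg: BackgroundModel,
                    pts: np.ndarray, rows: np.ndarray | None) -> np.ndarray:
    m = mdf.sample(pts, rows=rows)              # (P, Nc_sel, Nd)
    p = _probabilities_from_m(m, bkg)
    return _loglik_from_p(event_n, p)


def localize_mle(event: EventMatrix, mdf: MDFSet, bkg: BackgroundModel,
                 search: SearchSpec | None = None,
                 rows: np.ndarray | None = None) -> LocalizationResult:
    """Brute-force maximum-likelihood localization of one event.

    A coarse lattice pass over the search region followed by
    ``refine_levels`` local refinements, each halving the step, down to (at
    most) the MDF pixel size. Deterministic; ties break toward the lowest x,
    then the lowest y. The result is flagged ``on_border`` when the optimum
    touches the search region boundary and ``degenerate`` when no candidate
    had finite likelihood.
    """
    if event.N < 1:
        raise ValueError("cannot localize an empty event")
    if rows is None and event.n_ij.shape != (mdf.n_positions, mdf.n_elements):
        raise ValueError(
            f"event shape {event.n_ij.shape} does not match the MDF set "
            f"({mdf.n_positions}, {mdf.n_elements})")
    search = search or SearchSpec()
    n = event.n_ij if rows is None else event.n_ij[np.asarray(rows)]

    cx, cy = search.center
    s = mdf.grid.pixel_size
    max_half = mdf.sampling_halfwidth()
    half = search.halfwidth
    if half is None:
        half = min(mdf.detector.fov_halfwidth, max_half)
    half = min(half, max_half)
    if half <= 0:
        raise ValueError("search region is empty for this MDF grid")
    xbounds = (max(-max_half, cx - half), min(max_half, cx + half))
    ybounds = (max(-max_half, cy - half), min(max_half, cy + half))

    step = search.coarse_step_px * s
    if 2 * half / step < 4:                     # tiny regions: exhaustive
        step = s
    pts = _lattice(cx, cy, half, step, xbounds, ybounds)
    ll = _batched_loglik(n, mdf, bkg, pts, rows)
    best = int(np.argmax(ll))
    bx, by, bll = pts[best, 0], pts[best, 1], ll[best]

    level = 0
    for level in range(1, search.refine_levels + 1):
        prev = step
        step = max(step / 2.0, s)
        pts = _lattice(bx, by, prev, step, xbounds, ybounds)
        ll = _batched_loglik(n, mdf, bkg, pts, rows)
        best = int(np.argmax(ll))
        if ll[best] > bll or (ll[best] == bll and
                              (pts[best, 0], pts[best, 1]) < (bx, by)):
            bx, by, bll = pts[best, 0], pts[best, 1], ll[best]
        if step <= s:
            break

    on_border = (abs(abs(bx - cx) - half) < step / 2
                 or abs(abs(by - cy) - half) < step / 2)
    degenerate = not np.isfinite(bll) or bll <= _LOGLIK_FLOOR / 2
    return LocalizationResult(x=float(bx), y=float(by),
                              log_likelihood=float(bll),
                              n_photons=int(n.sum()), grid_level=level,
                              on_border=bool(on_border),
                              degenerate=bool(degenerate))


def localize_per_subset(event: EventMatrix, mdf: MDFSet,
                        bkg: BackgroundModel,
                        subsets: list[np.ndarray],
                        search: SearchSpec | None = None
                        ) -> list[LocalizationResult | None]:
    """One MLE per orbit-angle subset (probabilities renormalized per subset).

    Subsets with no photons are skipped (None in the returned list). With the
    trivial partition (all angles in one subset) this reduces to
    ``localize_mle``.
    """
    out: list[LocalizationResult | None] = []
    for rows in subsets:
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0 or event.n_ij[rows].sum() < 1:
            out.append(None)
            continue
        out.append(localize_mle(event, mdf, bkg, search=search, rows=rows))
    return out


def quadrant_subsets(n_positions: int, n_subsets: int = 4
                     ) -> list[np.ndarray]:
    """Partition orbit positions into consecutive angular blocks."""
    if n_positions % n_subsets:
        raise ValueError("n_subsets must divide the number of orbit positions")
    block = n_positions // n_subsets
    return [np.arange(q * block, (q + 1) * block) for q in range(n_subsets)]
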