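"""DNA-PAINT event detection, filtering, and three-segment localization.

The analysis chain for blinking single-molecule data: build a per-orbit
intensity trace, find the signal threshold from a two-Gaussian fit of the
count histogram, cut the trace into above-threshold events, filter events on
photon count / duration / count stability, localize each surviving event in
three equal-duration segments, and accept the event when the three segment
positions agree (sigma = sqrt(0.5 (sigma_x^2 + sigma_y^2)) below a
user-chosen threshold). Accepted positions can be rendered with a
fixed-width Gaussian kernel and summarized per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .estimator import (BackgroundModel, EventMatrix, LocalizationResult,
                        SearchSpec, localize_mle)
from .mdf import MDFSet
from .simulate import CountTensor

__all__ = [
    "FilterConfig", "EventRecord", "ThresholdFitError", "trace_from_tensor",
    "fit_threshold", "segment_events", "apply_filters", "localize_event",
    "segment_spread", "run_pipeline", "reconstruct", "cluster_uncertainty",
]


class ThresholdFitError(RuntimeError):
    """Two-Gaussian histogram fit failed (e.g., unimodal trace)."""


@dataclass(frozen=True)
class FilterConfig:
    """Event filters.

    min_photons: least total photons per event (2000).
    min_orbits: least event duration in orbits (5).
    poisson_factor: cap on the per-orbit count std, in units of sqrt(mean
        per-orbit count), rejecting events with super-Poissonian
        fluctuations (2.5).
    sigma_threshold: accept an event only if the spread of its three segment
        localizations stays below this [nm] (8.25, or 5 for the tighter
        ruler analysis).
    """

    min_photons: int = 2000
    min_orbits: int = 5
    poisson_factor: float = 2.5
    sigma_threshold: float = 8.25

    def __post_init__(self):
        if min(self.min_photons, self.min_orbits, self.poisson_factor,
               self.sigma_threshold) <= 0:
            raise ValueError("all filter parameters must be positive")


@dataclass
class EventRecord:
    """One above-threshold trace span and everything derived from it."""

    start_orbit: int
    end_orbit: int                      # half-open
    n_ij: EventMatrix | None = None
    total_photons: int = 0
    per_orbit_std: float = 0.0
    verdicts: dict = field(default_factory=dict)
    segments: list = field(default_factory=list)
    sigma: float | None = None          # nm, spread of segment localizations
    position: tuple | None = None       # mean of the 3 segment positions
    accepted: bool = False
    flags: list = field(default_factory=list)

    @property
    def duration_orbits(self) -> int:
        return self.end_orbit - self.start_orbit

    @property
    def passed_filters(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


def trace_from_tensor(tensor: CountTensor,
                      excluded_elements=()) -> np.ndarray:
    """Per-orbit intensity trace: photons summed over angles and elements.

    ``excluded_elements`` are indices along the tensor's element axis
    (e.g., hot pixels) to leave out of the sum.
    """
    counts = tensor.counts
    if len(excluded_elements):
        keep = np.setdiff1d(np.arange(counts.shape[2]),
                            np.asarray(excluded_elements))
        counts = counts[:, :, keep]
    return counts.sum(axis=(1, 2))


def _double_gaussian(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def fit_threshold(trace: np.ndarray, bins="auto", mode: str = "first-peak",
                  manual: float | None = None) -> float:
    """Signal/background threshold from a two-Gaussian histogram fit.

    The per-orbit count histogram is fitted with a sum of two Gaussians;
    mode="first-peak" (default) returns the mean of the lower component,
    mode="valley" the intersection point between the two components.
    A supplied ``manual`` value is returned unchanged. Raises
    ThresholdFitError when the trace is not bimodal enough to fit.
    """
    if manual is not None:
        return float(manual)
    if mode not in ("first-peak", "valley"):
        raise ValueError("mode must be 'first-peak' or 'valley'")
    trace = np.asarray(trace, dtype=float)
    hist, edges = np.histogram(trace, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # background dominates the trace: init the low mode at the median and
    # the high mode near the top of the distribution (on-events may occupy
    # only a few percent of the orbits)
    lo = float(np.median(trace))
    hi = float(np.percentile(trace, 99.8))
    if hi - lo < 1e-9:
        raise ThresholdFitError("trace has no spread; cannot fit two modes")
    width = max((hi - lo) / 8, 1.0)
    p0 = [hist.max(), lo, width, max(hist.max() / 50, 1.0), hi, width]
    bounds = ([0, centers.min(), 1e-6, 0, centers.min(), 1e-6],
              [np.inf, centers.max(), np.ptp(centers) + 1e-6,
               np.inf, centers.max(), np.ptp(centers) + 1e-6])
    try:
        popt, _ = curve_fit(_double_gaussian, centers, hist, p0=p0,
                            bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise ThresholdFitError(f"two-Gaussian fit failed: {err}") from err
    a1, m1, s1, a2, m2, s2 = popt
    comps = sorted([(m1, abs(s1), a1), (m2, abs(s2), a2)])
    (mlo, slo, alo), (mhi, shi, ahi) = comps
    if alo <= 0 or ahi <= 0 or mhi - mlo < max(slo, shi):
        raise ThresholdFitError(
            "fitted components overlap; trace looks unimodal "
            "(supply a manual threshold)")
    if mode == "first-peak":
        return float(mlo)
    # valley: intersection of the two fitted Gaussians between the means
    x = np.linspace(mlo, mhi, 2001)
    g_lo = alo * np.exp(-0.5 * ((x - mlo) / slo) ** 2)
    g_hi = ahi * np.exp(-0.5 * ((x - mhi) / shi) ** 2)
    return float(x[np.argmin(np.abs(g_lo - g_hi))])


def segment_events(trace: np.ndarray, threshold: float
                   ) -> list[tuple[int, int]]:
    """Maximal runs with trace > threshold, as half-open orbit intervals."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    above = np.asarray(trace) > threshold
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def apply_filters(events: list[tuple[int, int]], tensor: CountTensor,
                  cfg: FilterConfig,
                  excluded_elements=()) -> list[EventRecord]:
    """Attach per-event verdicts for the photon, duration and stability cuts.

    The stability cut rejects events whose per-orbit count standard
    deviation exceeds poisson_factor * sqrt(mean per-orbit count), i.e.,
    super-Poissonian intensity fluctuations.
    """
    counts = tensor.counts
    if len(excluded_elements):
        keep = np.setdiff1d(np.arange(counts.shape[2]),
                            np.asarray(excluded_elements))
        counts = counts[:, :, keep]
    records = []
    for start, end in events:
        block = counts[start:end]
        per_orbit = block.sum(axis=(1, 2))
        total = int(per_orbit.sum())
        std = float(per_orbit.std())
        mean = per_orbit.mean()
        rec = EventRecord(
            start_orbit=int(start), end_orbit=int(end),
            n_ij=EventMatrix(block.sum(axis=0), n_orbits=end - start),
            total_photons=total, per_orbit_std=std,
            verdicts={
                "photons": total >= cfg.min_photons,
                "duration": (end - start) >= cfg.min_orbits,
                "stability": std <= cfg.poisson_factor * np.sqrt(mean),
            })
        records.append(rec)
    return records


def segment_spread(positions: np.ndarray) -> tuple[float, tuple]:
    """sigma = sqrt(0.5 (sigma_x^2 + sigma_y^2)) and mean of segment positions.

    Standard deviations use the population convention (divide by the number
    of segments, n = 3).
    """
    xy = np.atleast_2d(np.asarray(positions, dtype=float))
    sx, sy = xy.std(axis=0, ddof=0)
    return float(np.sqrt(0.5 * (sx ** 2 + sy ** 2))), tuple(xy.mean(axis=0))


def _segment_bounds(start: int, end: int) -> list[tuple[int, int]]:
    """Three equal-duration segments; the last absorbs the remainder."""
    d = end - start
    base = d // 3
    return [(start, start + base),
            (start + base, start + 2 * base),
            (start + 2 * base, end)]


def localize_event(rec: EventRecord, tensor: CountTensor, mdf: MDFSet,
                   bkg: BackgroundModel, cfg: FilterConfig,
                   search: SearchSpec | None = None,
                   excluded_elements=()) -> EventRecord:
    """Three-segment localization and the sigma acceptance decision.

    The event is split into three equal-duration segments (remainder orbits
    to the last); each segment is localized by MLE, sigma is the rms of the
    per-axis population standard deviations of the three positions, and the
    event is accepted iff sigma < cfg.sigma_threshold. The reported position
    is the mean of the three segment positions.
    """
    if not rec.passed_filters:
        raise ValueError("localize_event expects an event that passed filters")
    counts = tensor.counts
    if len(excluded_elements):
        keep = np.setdiff1d(np.arange(counts.shape[2]),
                            np.asarray(excluded_elements))
        counts = counts[:, :, keep]
    bounds = _segment_bounds(rec.start_orbit, rec.end_orbit)
    if bounds[0][1] <= bounds[0][0]:
        rec.flags.append("too_short_to_segment")
        rec.accepted = False
        return rec
    segs: list[LocalizationResult] = []
    for s, e in bounds:
        n = counts[s:e].sum(axis=0)
        if n.sum() < 1:
            rec.flags.append("empty_segment")
            rec.accepted = False
            return rec
        segs.append(localize_mle(EventMatrix(n, n_orbits=e - s), mdf, bkg,
                                 search=search))
    rec.segments = segs
    rec.sigma, rec.position = segment_spread([[s.x, s.y] for s in segs])
    rec.accepted = rec.sigma < cfg.sigma_threshold
    return rec


def run_pipeline(tensor: CountTensor, mdf: MDFSet, bkg: BackgroundModel,
                 cfg: FilterConfig, threshold: float | None = None,
                 search: SearchSpec | None = None,
                 excluded_elements=()) -> list[EventRecord]:
    """Trace -> threshold -> events -> filters -> 3-segment localization."""
    trace = trace_from_tensor(tensor, excluded_elements)
    thr = fit_threshold(trace, manual=threshold)
    spans = segment_events(trace, thr)
    records = apply_filters(spans, tensor, cfg, excluded_elements)
    for rec in records:
        if rec.passed_filters:
            localize_event(rec, tensor, mdf, bkg, cfg, search=search,
                           excluded_elements=excluded_elements)
    return records


def reconstruct(locs: np.ndarray, kernel_sigma: float = 6.0,
                pixel_size: float = 2.0, pad: float = 30.0
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render localizations as a sum of unit-mass Gaussian kernels.

    Returns (image, xs, ys): image[iy, ix] is a density in nm^-2, so each
    localization integrates to ~1 over the map (sum * pixel_size^2).
    """
    locs = np.atleast_2d(np.asarray(locs, dtype=float))
    if locs.shape[0] < 1:
        raise ValueError("need at least one localization")
    x0, y0 = locs.min(axis=0) - pad
    x1, y1 = locs.max(axis=0) + pad
    xs = np.arange(x0, x1 + pixel_size, pixel_size)
    ys = np.arange(y0, y1 + pixel_size, pixel_size)
    X, Y = np.meshgrid(xs, ys)
    img = np.zeros_like(X)
    norm = 1.0 / (2 * np.pi * kernel_sigma ** 2)
    for x, y in locs:
        img += norm * np.exp(-((X - x) ** 2 + (Y - y) ** 2)
                             / (2 * kernel_sigma ** 2))
    return img, xs, ys


def cluster_uncertainty(locs: np.ndarray, labels: np.ndarray
                        ) -> tuple[dict, float, float]:
    """Per-cluster localization spread sqrt((var_x + var_y)/2) [nm].

    Clusters of fewer than 2 points are skipped. Returns (per-cluster dict,
    mean across clusters, sd across clusters).
    """
    locs = np.atleast_2d(np.asarray(locs, dtype=float))
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        pts = locs[labels == lab]
        if len(pts) < 2:
            continue
        vx, vy = pts.var(axis=0, ddof=1)
        out[lab] = float(np.sqrt((vx + vy) / 2.0))
    vals = np.array(list(out.values()))
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return out, mean, sd
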