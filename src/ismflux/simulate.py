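"""Synthetic photon-count tensors: static, stepped, and blinking emitters.

The generator emulates the acquisitions used to characterize the method: a
bright scatterer stepped across the detector field of view by a piezo stage,
and DNA-PAINT-style blinking emitters on origami nanorulers. Photon counts
are Poisson draws from the position-dependent expected rates given by the
MDFs plus a uniform background; blinking is a two-state renewal process with
exponential on/off sojourns (mean on-time 100 ms for the origami imagers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import EventMatrix
from .geometry import OrbitGeometry
from .mdf import MDFSet

__all__ = [
    "EmitterScript", "CountTensor", "expected_counts", "simulate_trace",
    "step_pattern", "nanoruler_script", "nanoruler_tensor",
]


@dataclass(frozen=True)
class EmitterScript:
    """Piecewise-constant emitter trajectory with optional on/off blinking.

    waypoints: sequence of (time_ms, x_nm, y_nm, brightness); the emitter
    holds each waypoint's position/brightness until the next waypoint time.
    blinking: None, or (mean_on_ms, mean_off_ms) exponential sojourn means.
    """

    waypoints: tuple = ()
    blinking: tuple | None = None

    def __post_init__(self):
        wp = tuple(tuple(map(float, w)) for w in self.waypoints)
        if not wp:
            raise ValueError("script needs at least one waypoint")
        times = [w[0] for w in wp]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("waypoint times must be strictly increasing")
        if any(w[3] < 0 for w in wp):
            raise ValueError("brightness must be non-negative")
        if self.blinking is not None:
            on, off = self.blinking
            if on <= 0 or off <= 0:
                raise ValueError("blinking sojourn means must be positive")
            object.__setattr__(self, "blinking", (float(on), float(off)))
        object.__setattr__(self, "waypoints", wp)

    @classmethod
    def static(cls, x: float, y: float, brightness: float = 1.0,
               blinking: tuple | None = None) -> "EmitterScript":
        return cls(waypoints=((0.0, x, y, brightness),), blinking=blinking)

    def state_at(self, t_ms: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """(positions (..., 2), brightness (...,)) at times t_ms."""
        t = np.asarray(t_ms, dtype=float)
        wp = np.asarray(self.waypoints)          # (n, 4)
        idx = np.clip(np.searchsorted(wp[:, 0], t, side="right") - 1, 0, None)
        return wp[idx, 1:3], wp[idx, 3]

    @property
    def end_time(self) -> float:
        return self.waypoints[-1][0]


@dataclass(frozen=True)
class CountTensor:
    """Photon counts I(c, alpha, d): orbit x angular position x element."""

    counts: np.ndarray          # (N_t, N_c, N_d) non-negative ints
    orbit: OrbitGeometry
    t0: float = 0.0             # [ms]
    seed: int | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (N_t, N_c, N_d)")
        if c.shape[1] != self.orbit.n_positions:
            raise ValueError("counts axis 1 must match the orbit positions")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_orbits(self) -> int:
        return self.counts.shape[0]

    def reduce(self, start: int = 0, end: int | None = None) -> EventMatrix:
        """Sum a half-open orbit range into an event matrix n_ij."""
        end = self.n_orbits if end is None else end
        if not 0 <= start < end <= self.n_orbits:
            raise ValueError(f"invalid orbit range [{start}, {end})")
        return EventMatrix(self.counts[start:end].sum(axis=0),
                           n_orbits=end - start)


def expected_counts(mdf: MDFSet, r_E: np.ndarray, rate: float,
                    bkg_rate: float) -> np.ndarray:
    """Expected photons per orbit, per (orbit position, element).

    ``rate`` is the expected signal photon count per orbit for an emitter at
    the TCP center; elsewhere the yield follows the MDFs (constant laser
    power), so lambda_ij = rate * m_ij(r) / sum_ij m_ij(0). The background
    contributes bkg_rate photons per orbit, uniform over all (i, j) cells.
    """
    if rate < 0 or bkg_rate < 0:
        raise ValueError("rates must be non-negative")
    m = mdf.sample(np.asarray(r_E, dtype=float))
    s0 = float(mdf.sum_signal(np.zeros(2)))
    lam = rate * m / s0 + bkg_rate / m.size
    return lam


def _blink_states(rng: np.random.Generator, t_mid: np.ndarray,
                  mean_on: float, mean_off: float) -> np.ndarray:
    """On/off state at each dwell midpoint; renewal process starting OFF."""
    total = float(t_mid[-1]) + 1.0
    edges = [0.0]
    t = 0.0
    on = False                       # imagers start unbound
    states = []
    while t < total:
        mean = mean_on if on else mean_off
        t += rng.exponential(mean)
        edges.append(t)
        states.append(on)
        on = not on
    # state between edges[k] and edges[k+1] is states[k]
    k = np.searchsorted(np.asarray(edges), t_mid, side="right") - 1
    return np.asarray(states, dtype=bool)[np.clip(k, 0, len(states) - 1)]


def simulate_trace(mdf: MDFSet, script: EmitterScript, rate: float,
                   bkg_rate: float, n_orbits: int,
                   seed: int | np.random.SeedSequence) -> CountTensor:
    """Poisson photon-count tensor for a scripted emitter.

    Per orbit and angular position, counts are drawn from the expected rates
    at the emitter's instantaneous position and brightness (piecewise
    constant between waypoints, evaluated at the dwell midpoint; blinking
    states drawn from exponential sojourns). Bit-exact reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    orb = mdf.orbit
    n_c, n_d = orb.n_positions, mdf.n_elements
    dwell = orb.dwell_time
    c_idx = np.arange(n_orbits)
    a_idx = np.arange(n_c)
    t_mid = (c_idx[:, None] * orb.period
             + (a_idx[None, :] + 0.5) * dwell)          # (Nt, Nc)

    pos, bright = script.state_at(t_mid)                # (Nt, Nc, 2), (Nt, Nc)
    if script.blinking is not None:
        on = _blink_states(rng, t_mid.ravel(), *script.blinking)
        bright = bright * on.reshape(bright.shape)

    s0 = float(mdf.sum_signal(np.zeros(2)))
    bkg_cell = bkg_rate / (n_c * n_d)
    lam = np.empty((n_orbits, n_c, n_d))
    # dwell (orbit c, angle i) only uses MDF row i at that dwell's position
    flat_pos = pos.reshape(-1, 2)
    uniq, inv = np.unique(flat_pos, axis=0, return_inverse=True)
    m_rows = mdf.sample(uniq)                           # (U, Nc, Nd)
    i_of_dwell = np.tile(a_idx, n_orbits)
    lam = (rate / s0) * m_rows[inv, i_of_dwell, :]
    lam = lam * bright.reshape(-1, 1) + bkg_cell
    counts = rng.poisson(lam).reshape(n_orbits, n_c, n_d)
    return CountTensor(counts=counts, orbit=orb,
                       seed=None if not np.isscalar(seed) else int(seed))


def step_pattern(kind: str, *, step: float = 100.0, extent: float = 600.0,
                 n: int = 10, dwell_ms: float = 100.0,
                 brightness: float = 1.0, start: tuple = (0.0, 0.0),
                 waypoints=None) -> EmitterScript:
    """Waypoint scripts for the stepping experiments.

    kind="grid": a square grid covering ``extent`` with the given step
    (default 7x7 over 600 nm), visited row by row. kind="steps": a 1-D
    staircase of ``n`` positions advancing +step in x from ``start``.
    kind="custom": pass ``waypoints`` through unchanged.
    """
    if kind == "grid":
        k = int(round(extent / step)) + 1
        xs = -extent / 2 + step * np.arange(k)
        wp = []
        t = 0.0
        for y in xs:
            for x in xs:
                wp.append((t, x, y, brightness))
                t += dwell_ms
        return EmitterScript(waypoints=tuple(wp))
    if kind == "steps":
        x0, y0 = start
        wp = tuple((i * dwell_ms, x0 + i * step, y0, brightness)
                   for i in range(n))
        return EmitterScript(waypoints=wp)
    if kind == "custom":
        if waypoints is None:
            raise ValueError("custom pattern needs waypoints")
        return EmitterScript(waypoints=tuple(waypoints))
    raise ValueError(f"unknown pattern kind: {kind!r}")


def nanoruler_script(sites, duration_ms: float, site_dwell_ms: float = 500.0,
                     mean_on_ms: float = 100.0, mean_off_ms: float = 1900.0
                     ) -> EmitterScript:
    """DNA-origami nanoruler stand-in: docking sites visited in rotation.

    Imager strands bind transiently (mean on-time 100 ms) to one docking
    site at a time; which site is "armed" rotates every ``site_dwell_ms``
    (faster than the mean binding cycle), so successive on-events sample
    all sites evenly. Brightness 1 at every
    waypoint: under constant laser power the photon yield per site follows
    the MDFs.
    """
    sites = [tuple(map(float, s)) for s in sites]
    wp = []
    t, k = 0.0, 0
    while t < duration_ms:
        x, y = sites[k % len(sites)]
        wp.append((t, x, y, 1.0))
        t += site_dwell_ms
        k += 1
    return EmitterScript(waypoints=tuple(wp),
                         blinking=(mean_on_ms, mean_off_ms))


def nanoruler_tensor(mdf: MDFSet, sites, duration_ms: float,
                     signal_per_orbit: float = 36.0, sbr: float = 3.0,
                     mean_on_ms: float = 100.0, mean_off_ms: float = 1900.0,
                     site_dwell_ms: float = 500.0,
                     seed: int | np.random.SeedSequence = 0) -> CountTensor:
    """Simulate a blinking nanoruler acquisition.

    ``signal_per_orbit`` is the expected signal photon count per orbit for
    an on-event at the centroid of the sites; individual sites deviate
    according to their MDF yield. The default (36 signal photons per orbit,
    ~48 total at SBR 3) reproduces the photon economy of DNA-PAINT events
    whose mean 100 ms (~52 orbit) binding clears a 2000-photon threshold at
    every site of a ruler despite the position-dependent yield. The default
    off-time of 1.9 s matches an observed event rate of ~one binding per
    2 s. The uniform background rate is signal_per_orbit / sbr, so an
    on-event at the centroid has the given signal-to-background ratio.
    """
    script = nanoruler_script(sites, duration_ms, site_dwell_ms=site_dwell_ms,
                              mean_on_ms=mean_on_ms, mean_off_ms=mean_off_ms)
    centroid = np.mean(np.asarray(sites, dtype=float), axis=0)
    s0 = float(mdf.sum_signal(np.zeros(2)))
    s_ref = float(mdf.sum_signal(centroid))
    rate = signal_per_orbit * s0 / s_ref
    n_orbits = int(duration_ms / mdf.orbit.period)
    return simulate_trace(mdf, script, rate=rate,
                          bkg_rate=signal_per_orbit / sbr,
                          n_orbits=n_orbits, seed=seed)
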