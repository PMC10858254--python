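"""Synthetic time-varying coastal velocity fields.

The generator emulates the statistical regime the transport stage assumes
from a hindcast product: a predominant south-to-north mean current, a
rotary tidal oscillation (default period the M2 semidiurnal 12.42 h), and
a spatially smooth, temporally autocorrelated eddy-like noise field.  It
replaces a full hydrodynamic model at desk scale; it is not one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .domain import Domain

__all__ = ["FlowConfig", "FlowField", "AnalyticField", "generate_flow"]

HOUR_S = 3600.0


@dataclass(frozen=True)
class FlowConfig:
    """Parameters of the synthetic flow regime.

    mean_current_speed : northward alongshore mean, m/s
    tidal_amplitude    : rotary tidal current amplitude, m/s (per component)
    tidal_period_h     : tidal period in hours (M2 default 12.42)
    noise_speed        : RMS of the smooth eddy noise component, m/s
    diffusivity_D      : horizontal turbulent diffusivity passed to the
                         tracker, m^2/s -- a free parameter (see docs)
    noise_filter_cells : Gaussian low-pass scale of the noise, in cells
    noise_autocorr     : lag-1-hour temporal autocorrelation of the noise
    """

    mean_current_speed: float = 0.1
    tidal_amplitude: float = 0.3
    tidal_period_h: float = 12.42
    noise_speed: float = 0.05
    diffusivity_D: float = 10.0
    noise_filter_cells: float = 5.0
    noise_autocorr: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if min(self.mean_current_speed, self.tidal_amplitude, self.noise_speed) < 0:
            raise ValueError("speeds must be non-negative")
        if self.tidal_period_h <= 0:
            raise ValueError("tidal_period_h must be positive")
        if self.diffusivity_D < 0:
            raise ValueError("diffusivity_D must be non-negative")


@dataclass
class FlowField:
    """Hourly gridded horizontal velocity on a :class:`Domain`.

    u, v have shape (n_times, n_lat, n_lon) in m/s; land cells are zero.
    ``times`` are UTC, strictly increasing, uniformly spaced.
    """

    domain: Domain
    times: np.ndarray  # datetime64[s]
    u: np.ndarray
    v: np.ndarray
    depth_m: float = 6.0
    diffusivity_D: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        if self.times.size < 2:
            raise ValueError("need at least two time slices")
        steps = np.diff(self.times.astype("int64"))
        if not (steps > 0).all() or not (steps == steps[0]).all():
            raise ValueError("times must be strictly increasing and uniformly spaced")
        expect = (self.times.size, self.domain.n_lat, self.domain.n_lon)
        if self.u.shape != expect or self.v.shape != expect:
            raise ValueError(f"velocity shape {self.u.shape} != {expect}")
        wet = ~self.domain.land_mask
        if not (np.isfinite(self.u[:, wet]).all() and np.isfinite(self.v[:, wet]).all()):
            raise ValueError("non-finite velocity on water cells")

    @property
    def step_seconds(self) -> float:
        return float((self.times[1] - self.times[0]) / np.timedelta64(1, "s"))

    @property
    def span_seconds(self) -> float:
        return float((self.times[-1] - self.times[0]) / np.timedelta64(1, "s"))

    def seconds_since_start(self, when) -> float:
        return float((np.datetime64(when, "s") - self.times[0]) / np.timedelta64(1, "s"))

    def velocity(self, t_s: float, lon, lat):
        """Velocity (u, v) in m/s at time offset ``t_s`` seconds from the
        first slice, bilinear in space over wet cells (weights renormalised
        over the wet part of the stencil) and linear in time."""
        if not 0.0 <= t_s <= self.span_seconds:
            raise ValueError(f"time offset {t_s} s outside field span")
        dom = self.domain
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))

        dt = self.step_seconds
        it = int(min(t_s / dt, self.times.size - 2))
        ft = t_s / dt - it

        gx = np.clip((lon - dom.lon_min) / dom.cell_size - 0.5, 0.0, dom.n_lon - 1.0)
        gy = np.clip((lat - dom.lat_min) / dom.cell_size - 0.5, 0.0, dom.n_lat - 1.0)
        ix = np.minimum(gx.astype(np.int64), dom.n_lon - 2) if dom.n_lon > 1 else np.zeros_like(gx, dtype=np.int64)
        iy = np.minimum(gy.astype(np.int64), dom.n_lat - 2) if dom.n_lat > 1 else np.zeros_like(gy, dtype=np.int64)
        fx = gx - ix
        fy = gy - iy
        ix1 = np.minimum(ix + 1, dom.n_lon - 1)
        iy1 = np.minimum(iy + 1, dom.n_lat - 1)

        corners = ((iy, ix), (iy, ix1), (iy1, ix), (iy1, ix1))
        weights = (
            (1 - fx) * (1 - fy),
            fx * (1 - fy),
            (1 - fx) * fy,
            fx * fy,
        )
        wet = ~dom.land_mask
        u_out = np.zeros_like(lon)
        v_out = np.zeros_like(lon)
        w_tot = np.zeros_like(lon)
        for (cy, cx), w in zip(corners, weights):
            w_wet = w * wet[cy, cx]
            u_slice = (1 - ft) * self.u[it, cy, cx] + ft * self.u[it + 1, cy, cx]
            v_slice = (1 - ft) * self.v[it, cy, cx] + ft * self.v[it + 1, cy, cx]
            u_out += w_wet * u_slice
            v_out += w_wet * v_slice
            w_tot += w_wet
        ok = w_tot > 0
        u_out = np.where(ok, u_out / np.where(ok, w_tot, 1.0), 0.0)
        v_out = np.where(ok, v_out / np.where(ok, w_tot, 1.0), 0.0)
        return u_out, v_out


@dataclass
class AnalyticField:
    """Velocity field given by a closed-form function ``fn(t_s, lon, lat) -> (u, v)``.

    Satisfies the same sampling protocol as :class:`FlowField`; used for
    integrator verification against closed-form kinematics.
    """

    domain: Domain
    fn: object
    t0: np.datetime64 = field(default_factory=lambda: np.datetime64("2020-01-01T00:00:00", "s"))
    span_seconds: float = 1e10  # closed form: valid at any offset
    diffusivity_D: float = 0.0
    depth_m: float = 6.0

    @property
    def times(self):
        return np.array([self.t0, self.t0 + np.timedelta64(int(self.span_seconds), "s")])

    def seconds_since_start(self, when) -> float:
        return float((np.datetime64(when, "s") - self.t0) / np.timedelta64(1, "s"))

    def velocity(self, t_s: float, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        u, v = self.fn(t_s, lon, lat)
        return np.broadcast_to(np.asarray(u, dtype=float), lon.shape).copy(), np.broadcast_to(
            np.asarray(v, dtype=float), lon.shape
        ).copy()


def _smooth_noise(rng: np.random.Generator, shape, filter_cells: float, wet: np.ndarray) -> np.ndarray:
    """White noise, Gaussian low-passed, rescaled to unit RMS over wet cells."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=filter_cells, mode="nearest")
    rms = np.sqrt(np.mean(sm[wet] ** 2))
    return sm / rms if rms > 0 else sm


def generate_flow(domain: Domain, config: FlowConfig, t_start, t_end) -> FlowField:
    """Generate an hourly :class:`FlowField` on ``[t_start, t_end]``.

    The field is the sum of a steady northward current
    (``mean_current_speed`` on v), a rotary tide
    ``(u, v) = a (cos, sin)(2 pi t / T)``, and a smooth noise field of RMS
    ``noise_speed`` regenerated each hour with lag-1 autocorrelation
    ``noise_autocorr``.  Identical seed gives a bit-identical field.
    """
    t0 = np.datetime64(t_start, "s")
    t1 = np.datetime64(t_end, "s")
    if t1 <= t0:
        raise ValueError("t_end must be after t_start")
    n_hours = int(np.ceil(float((t1 - t0) / np.timedelta64(1, "s")) / HOUR_S)) + 1
    times = t0 + np.arange(n_hours) * np.timedelta64(int(HOUR_S), "s")

    ny, nx = domain.n_lat, domain.n_lon
    wet = ~domain.land_mask
    if not wet.any():
        raise ValueError("empty water set")
    u = np.zeros((n_hours, ny, nx))
    v = np.zeros((n_hours, ny, nx))

    t_hours = np.arange(n_hours, dtype=float)
    omega = 2.0 * np.pi / config.tidal_period_h
    u_tide = config.tidal_amplitude * np.cos(omega * t_hours)
    v_tide = config.tidal_amplitude * np.sin(omega * t_hours)

    v += config.mean_current_speed
    u += u_tide[:, None, None]
    v += v_tide[:, None, None]

    if config.noise_speed > 0:
        rng = np.random.default_rng(config.seed)
        rho = config.noise_autocorr
        innov = np.sqrt(1.0 - rho**2)
        nu = _smooth_noise(rng, (ny, nx), config.noise_filter_cells, wet)
        nv = _smooth_noise(rng, (ny, nx), config.noise_filter_cells, wet)
        for k in range(n_hours):
            if k > 0:
                nu = rho * nu + innov * _smooth_noise(rng, (ny, nx), config.noise_filter_cells, wet)
                nv = rho * nv + innov * _smooth_noise(rng, (ny, nx), config.noise_filter_cells, wet)
            u[k] += config.noise_speed * nu
            v[k] += config.noise_speed * nv

    u[:, domain.land_mask] = 0.0
    v[:, domain.land_mask] = 0.0
    return FlowField(domain, times, u, v, diffusivity_D=config.diffusivity_D)
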