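"""From trajectories to connectivity matrices, source/sink roles,
stepping-stone path lengths, cumulative seasonal networks and larval
accumulation density maps.

Settlement is scored post hoc: a particle released at site i "settles" at
site j if any of its recorded positions in the final settlement window
falls within the settlement radius (great-circle distance) of j.  A
particle may count toward several destinations, but at most once per
destination -- the distinct-particle convention usual for connectivity
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._geo import haversine_m
from .domain import Domain
from .tracking import Site, SimulationConfig, TrajectorySet

__all__ = [
    "ConnectivityMatrix",
    "DensityGrid",
    "settlement_connectivity",
    "source_sink_classify",
    "stepping_stone_generations",
    "cumulative_network",
    "density_map",
]

HOUR_S = 3600.0
DAY_S = 86400.0


@dataclass
class ConnectivityMatrix:
    """Origin x destination settled-particle counts for one simulation window.

    The diagonal holds self-recruitment counts.  Row sums are bounded by the
    number of particles released per origin.
    """

    site_ids: list
    counts: np.ndarray
    window: tuple
    settle_radius_m: float = 2000.0
    settle_window_days: float = 7.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        s = len(self.site_ids)
        if self.counts.shape != (s, s):
            raise ValueError("counts must be square over site_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.site_ids, columns=self.site_ids)

    def __eq__(self, other):
        return (
            isinstance(other, ConnectivityMatrix)
            and self.site_ids == other.site_ids
            and np.array_equal(self.counts, other.counts)
            and tuple(np.datetime64(w, "s") for w in self.window)
            == tuple(np.datetime64(w, "s") for w in other.window)
        )


@dataclass
class DensityGrid:
    """Particle-hours per grid cell over a window, and the implied larval
    density in particles/m^3 given the cell footprint and a nominal layer
    thickness."""

    domain: Domain
    particle_hours: np.ndarray
    window: tuple
    layer_thickness_m: float = 1.0

    @property
    def window_hours(self) -> float:
        t0, t1 = (np.datetime64(w, "s") for w in self.window)
        return float((t1 - t0) / np.timedelta64(1, "s")) / HOUR_S

    @property
    def density(self) -> np.ndarray:
        """particles/m^3 per cell."""
        area = self.domain.cell_area_m2()[:, None]
        vol = area * self.layer_thickness_m
        return self.particle_hours / (self.window_hours * vol)


def settlement_connectivity(
    traj: TrajectorySet, sites, config: SimulationConfig | None = None
) -> ConnectivityMatrix:
    """Count distinct particles from each origin whose recorded track passes
    within ``settle_radius_m`` of each site during the final
    ``settle_window_days`` of the run."""
    cfg = config or traj.config
    t_end = np.datetime64(traj.sim_end, "s")
    t_start = t_end - np.timedelta64(int(cfg.settle_window_days * DAY_S), "s")
    rec_t = traj.records["time"].to_numpy()
    if rec_t.size == 0 or rec_t.max() < t_start:
        raise ValueError("trajectory records do not cover the settlement window")

    window = traj.in_window(t_start, t_end)
    site_ids = [s.id for s in sites]
    s_lon = np.array([s.lon for s in sites])
    s_lat = np.array([s.lat for s in sites])
    n_sites = len(sites)
    counts = np.zeros((n_sites, n_sites), dtype=np.int64)
    origin_idx = {sid: i for i, sid in enumerate(site_ids)}

    p = window["particle_id"].to_numpy()
    lon = window["lon"].to_numpy()
    lat = window["lat"].to_numpy()
    # (particle, destination) hit pairs, deduplicated -> distinct-particle counts
    seen: set[tuple[int, int]] = set()
    chunk = 200_000
    for lo in range(0, p.size, chunk):
        sl = slice(lo, lo + chunk)
        d = haversine_m(lon[sl][:, None], lat[sl][:, None], s_lon[None, :], s_lat[None, :])
        hit_p, hit_s = np.nonzero(d <= cfg.settle_radius_m)
        for pp, ss in zip(p[sl][hit_p], hit_s):
            seen.add((int(pp), int(ss)))
    origins = traj.origins
    for pp, ss in seen:
        oi = origin_idx.get(origins.loc[pp])
        if oi is not None:
            counts[oi, ss] += 1
    return ConnectivityMatrix(
        site_ids,
        counts,
        window=(t_start, t_end),
        settle_radius_m=cfg.settle_radius_m,
        settle_window_days=cfg.settle_window_days,
    )


def source_sink_classify(C: ConnectivityMatrix) -> pd.DataFrame:
    """Per-site transport roles.

    out/in strengths exclude self-recruitment (the diagonal); ``net`` is
    out - in; the role is "source" (net donor) / "sink" / "balanced";
    ``n_sources`` counts distinct off-diagonal donors per destination
    (in-degree), the quantity behind statements like "receives larvae from
    N different source locations".
    """
    M = C.counts
    diag = np.diag(M)
    out_strength = M.sum(axis=1) - diag
    in_strength = M.sum(axis=0) - diag
    net = out_strength - in_strength
    role = np.where(net > 0, "source", np.where(net < 0, "sink", "balanced"))
    off = M.copy()
    np.fill_diagonal(off, 0)
    n_sources = (off > 0).sum(axis=0)
    return pd.DataFrame(
        {
            "site": C.site_ids,
            "out_strength": out_strength,
            "in_strength": in_strength,
            "net_flux": net,
            "role": role,
            "self_recruiting": diag > 0,
            "self_recruitment": diag,
            "n_sources": n_sources,
        }
    ).set_index("site")


def stepping_stone_generations(
    C: ConnectivityMatrix, origin: str, target: str, min_count: int = 1
) -> int | None:
    """Minimum number of dispersal events ("generations") linking origin to
    target: the shortest directed path length in the graph whose edge
    (i, j) exists iff counts[i][j] >= min_count, i != j.  Returns None when
    the target is unreachable."""
    ids = C.site_ids
    if origin not in ids or target not in ids:
        raise KeyError(f"unknown site id: {origin if origin not in ids else target}")
    G = nx.DiGraph()
    G.add_nodes_from(ids)
    M = C.counts
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j and M[i, j] >= min_count:
                G.add_edge(a, b)
    try:
        return nx.shortest_path_length(G, origin, target)
    except nx.NetworkXNoPath:
        return None


def cumulative_network(matrices) -> ConnectivityMatrix:
    """Element-wise sum of weekly-restart connectivity matrices; the window
    is the union (earliest start, latest end) of the inputs."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to accumulate")
    first = matrices[0]
    total = np.zeros_like(first.counts)
    starts, ends = [], []
    for m in matrices:
        if m.site_ids != first.site_ids:
            raise ValueError("mismatched site sets")
        total = total + m.counts
        starts.append(np.datetime64(m.window[0], "s"))
        ends.append(np.datetime64(m.window[1], "s"))
    return ConnectivityMatrix(
        first.site_ids,
        total,
        window=(min(starts), max(ends)),
        settle_radius_m=first.settle_radius_m,
        settle_window_days=first.settle_window_days,
    )


def density_map(
    traj: TrajectorySet, domain: Domain, window, layer_thickness_m: float = 1.0
) -> DensityGrid:
    """Accumulate recorded particle positions into per-cell particle-hours
    over ``window`` (half-open ``(start, end]``: each record stands for the
    preceding recording interval), then normalise to particles/m^3.
    """
    if layer_thickness_m <= 0:
        raise ValueError("layer thickness must be positive")
    t0, t1 = (np.datetime64(w, "s") for w in window)
    if t0 < np.datetime64(traj.sim_start, "s") or t1 > np.datetime64(traj.sim_end, "s"):
        raise ValueError("window outside trajectory span")
    rec_t = traj.records["time"].to_numpy()
    m = (rec_t > t0) & (rec_t <= t1)
    sub = traj.records.loc[m]
    hours_per_record = traj.config.record_interval_s / HOUR_S
    ph = np.zeros((domain.n_lat, domain.n_lon))
    iy, ix = domain.cell_index(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    ok = (iy >= 0) & (ix >= 0)
    np.add.at(ph, (iy[ok], ix[ok]), hours_per_record)
    return DensityGrid(domain, ph, window=(t0, t1), layer_thickness_m=layer_thickness_m)
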