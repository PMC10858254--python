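"""Connectivity matrices, source/sink roles, stepping stones, cumulative
networks and density maps."""

import numpy as np
import pandas as pd
import pytest

from larvaconnect import (
    ConnectivityMatrix,
    SimulationConfig,
    Site,
    cumulative_network,
    density_map,
    run_simulation,
    settlement_connectivity,
    source_sink_classify,
    stepping_stone_generations,
)
from larvaconnect.tracking import TrajectorySet

from conftest import northward_field


def manual_trajectory(track_points, sim_start="2021-02-01", total_days=34.0, settle_days=7.0):
    """Build a TrajectorySet from {particle: origin, [(hour, lon, lat), ...]}."""
    rows = []
    origins = {}
    releases = {}
    t0 = np.datetime64(sim_start, "s")
    for pid, (origin, pts) in track_points.items():
        origins[pid] = origin
        releases[pid] = t0
        for h, lon, lat in pts:
            rows.append({"particle_id": pid, "time": t0 + np.timedelta64(h * 3600, "s"), "lon": lon, "lat": lat})
    cfg = SimulationConfig(
        release_rate=1, release_days=1.0, total_days=total_days, settle_window_days=settle_days, seed=0
    )
    return TrajectorySet(
        records=pd.DataFrame(rows),
        origins=pd.Series(origins, name="origin_site"),
        config=cfg,
        sim_start=t0,
        sim_end=t0 + np.timedelta64(int(total_days * 86400), "s"),
        release_times=pd.Series(releases, name="release_time"),
    )


SITES = [Site("A", -5.5, 56.0), Site("B", -5.5, 56.5)]
# ~1.5 km north of B
NEAR_B = 56.5 + 1500 / 111194.9
# ~5 km north of B
FAR_B = 56.5 + 5000 / 111194.9


class TestSettlement:
    def test_pass_within_radius_in_window_counts(self):
        traj = manual_trajectory({0: ("A", [(30 * 24, -5.5, NEAR_B)])})
        C = settlement_connectivity(traj, SITES)
        assert C.counts[0, 1] == 1

    def test_pass_before_window_does_not_count(self):
        traj = manual_trajectory({0: ("A", [(10 * 24, -5.5, NEAR_B), (30 * 24, -5.5, FAR_B)])})
        C = settlement_connectivity(traj, SITES)
        assert C.counts[0, 1] == 0

    def test_lingering_particle_counts_once_per_destination(self):
        pts = [(28 * 24 + h, -5.5, NEAR_B) for h in range(50)]
        traj = manual_trajectory({0: ("A", pts)})
        C = settlement_connectivity(traj, SITES)
        assert C.counts[0, 1] == 1

    def test_self_recruitment_on_diagonal(self):
        traj = manual_trajectory({0: ("A", [(30 * 24, -5.5, 56.0)])})
        C = settlement_connectivity(traj, SITES)
        assert C.counts[0, 0] == 1

    def test_row_sums_bounded_by_released(self, open_water):
        cfg = SimulationConfig(release_rate=2, release_days=1.0, total_days=3.0, settle_window_days=2.0, seed=1)
        sites = [Site("A", -5.5, 56.1), Site("B", -5.5, 56.2), Site("C", -5.5, 56.3)]
        f = northward_field(open_water, 0.05)
        f.diffusivity_D = 2.0
        traj = run_simulation(sites, f, cfg, "2021-02-01")
        C = settlement_connectivity(traj, sites, cfg)
        released = 2 * 24
        assert (C.counts.max(axis=1) <= released).all()

    def test_northward_flow_gives_upper_triangular_matrix(self, open_water):
        """South-to-north transport: no connectivity edge ever points south."""
        cfg = SimulationConfig(release_rate=2, release_days=1.0, total_days=3.0, settle_window_days=1.0, seed=1)
        sites = [Site(f"S{i}", -5.5, 56.05 + 0.1 * i) for i in range(5)]
        traj = run_simulation(sites, northward_field(open_water, 0.15), cfg, "2021-02-01")
        C = settlement_connectivity(traj, sites, cfg)
        assert np.all(np.tril(C.counts, k=-1) == 0)
        assert C.counts.sum() > 0


class TestSourceSink:
    def test_simple_source_and_sink(self):
        C = ConnectivityMatrix(["s1", "s2"], np.array([[0, 10], [0, 0]]), ("2021-02-01", "2021-02-08"))
        r = source_sink_classify(C)
        assert r.loc["s1", "role"] == "source" and r.loc["s1", "net_flux"] == 10
        assert r.loc["s2", "role"] == "sink" and r.loc["s2", "net_flux"] == -10

    def test_pure_self_recruitment_is_balanced(self):
        C = ConnectivityMatrix(["a", "b"], np.diag([5, 5]), ("2021-02-01", "2021-02-08"))
        r = source_sink_classify(C)
        assert (r["role"] == "balanced").all() and r["self_recruiting"].all()

    def test_source_count_is_offdiagonal_indegree(self):
        M = np.zeros((5, 5), dtype=int)
        M[0, 4] = M[1, 4] = M[2, 4] = M[3, 4] = 3
        M[4, 4] = 9  # self-recruitment not a source
        C = ConnectivityMatrix(list("abcde"), M, ("2021-02-01", "2021-02-08"))
        assert source_sink_classify(C).loc["e", "n_sources"] == 4


class TestSteppingStones:
    CHAIN = ConnectivityMatrix(
        list("ABC"), np.array([[0, 5, 0], [0, 0, 5], [0, 0, 0]]), ("2021-02-01", "2021-02-08")
    )

    def test_chain_needs_two_generations(self):
        assert stepping_stone_generations(self.CHAIN, "A", "C") == 2

    def test_direct_edge_dominates(self):
        M = self.CHAIN.counts.copy()
        M[0, 2] = 1
        C = ConnectivityMatrix(list("ABC"), M, self.CHAIN.window)
        assert stepping_stone_generations(C, "A", "C") == 1

    def test_threshold_above_counts_unreachable(self):
        assert stepping_stone_generations(self.CHAIN, "A", "C", min_count=6) is None

    def test_unknown_site_rejected(self):
        with pytest.raises(KeyError):
            stepping_stone_generations(self.CHAIN, "A", "Z")


class TestCumulative:
    W = ("2021-02-01", "2021-02-08")

    def test_elementwise_sum_and_scaling(self):
        C = ConnectivityMatrix(["a", "b"], np.array([[1, 2], [3, 4]]), self.W)
        total = cumulative_network([C, C, C])
        assert np.array_equal(total.counts, 3 * C.counts)

    def test_single_matrix_identity(self):
        C = ConnectivityMatrix(["a", "b"], np.array([[1, 2], [3, 4]]), self.W)
        assert np.array_equal(cumulative_network([C]).counts, C.counts)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cumulative_network([])

    def test_mismatched_sites_rejected(self):
        C1 = ConnectivityMatrix(["a", "b"], np.zeros((2, 2), int), self.W)
        C2 = ConnectivityMatrix(["a", "c"], np.zeros((2, 2), int), self.W)
        with pytest.raises(ValueError):
            cumulative_network([C1, C2])

    def test_window_is_union(self):
        C1 = ConnectivityMatrix(["a"], np.zeros((1, 1), int), ("2021-02-01", "2021-02-08"))
        C2 = ConnectivityMatrix(["a"], np.zeros((1, 1), int), ("2021-02-08", "2021-02-15"))
        out = cumulative_network([C1, C2])
        assert out.window == (np.datetime64("2021-02-01", "s"), np.datetime64("2021-02-15", "s"))


class TestDensityMap:
    def test_stationary_particles_known_density(self, open_water):
        # 100 particles sitting in one cell through a 168 h window
        t_end = 34 * 24
        pts = {p: ("A", [(h, -5.975, 56.025) for h in range(t_end - 168, t_end + 1)]) for p in range(100)}
        traj = manual_trajectory(pts)
        window = (traj.sim_end - np.timedelta64(168 * 3600, "s"), traj.sim_end)
        dg = density_map(traj, open_water, window, layer_thickness_m=1.0)
        assert dg.particle_hours.sum() == 100 * 168
        cell_area = open_water.cell_area_m2()[0]
        iy, ix = open_water.cell_index(-5.975, 56.025)
        expect = 100 * 168 / (168 * cell_area * 1.0)
        assert np.isclose(dg.density[iy, ix], expect, rtol=1e-12)

    def test_no_particles_all_zero(self, open_water):
        traj = manual_trajectory({0: ("A", [(1, -5.5, 56.5)])})
        window = (traj.sim_end - np.timedelta64(168 * 3600, "s"), traj.sim_end)
        dg = density_map(traj, open_water, window)
        assert dg.particle_hours.sum() == 0

    def test_particle_hours_conserved(self, open_water):
        cfg = SimulationConfig(release_rate=2, release_days=1.0, total_days=3.0, settle_window_days=1.0, seed=5)
        f = northward_field(open_water, 0.02)
        f.diffusivity_D = 1.0
        traj = run_simulation([Site("A", -5.5, 56.4)], f, cfg, "2021-02-01")
        window = (traj.sim_end - np.timedelta64(24 * 3600, "s"), traj.sim_end)
        dg = density_map(traj, open_water, window)
        t = traj.records["time"].to_numpy()
        expect = ((t > window[0]) & (t <= window[1])).sum()
        assert dg.particle_hours.sum() == expect

    def test_zero_thickness_rejected(self, open_water):
        traj = manual_trajectory({0: ("A", [(1, -5.5, 56.5)])})
        with pytest.raises(ValueError):
            density_map(traj, open_water, (traj.sim_start, traj.sim_end), layer_thickness_m=0.0)
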