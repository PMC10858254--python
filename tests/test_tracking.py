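"""Transport engine: release bookkeeping, integrator accuracy against
closed-form kinematics and a brute-force Euler oracle, diffusion
statistics, and boundary policy."""

import numpy as np
import pytest

from larvaconnect import (
    SimulationConfig,
    Site,
    advect_step,
    apply_boundary,
    make_release_schedule,
    run_simulation,
)
from larvaconnect._geo import M_PER_DEG_LAT, haversine_m, m_per_deg_lon
from larvaconnect.flow import AnalyticField

from conftest import northward_field, still_field


class TestReleaseSchedule:
    def test_default_protocol_single_site(self):
        sched = make_release_schedule([Site("A", -5.5, 56.5)], SimulationConfig(), "2021-02-01")
        assert len(sched) == 20 * 24 * 14 == 6720

    def test_linear_in_sites(self):
        sites = [Site(f"S{i}", -5.5, 56.5) for i in range(3)]
        sched = make_release_schedule(sites, SimulationConfig(), "2021-02-01")
        assert len(sched) == 3 * 6720
        # deterministic ordering: site blocks, hourly within, index within hour
        assert list(sched["site_id"][:6720].unique()) == ["S0"]

    def test_zero_release_days_empty(self):
        cfg = SimulationConfig(release_days=0.0)
        assert len(make_release_schedule([Site("A", 0, 0)], cfg, "2021-02-01")) == 0

    def test_particle_ids_unique(self):
        sched = make_release_schedule(
            [Site("A", 0, 0), Site("B", 0, 0)], SimulationConfig(release_rate=2, release_days=1), "2021-02-01"
        )
        assert sched["particle_id"].is_unique


class TestAdvectStep:
    def test_uniform_flow_closed_form(self, open_water):
        f = northward_field(open_water, 0.1)
        lon, lat = advect_step(-5.5, 56.2, 0.0, 3600.0, f)
        d = haversine_m(-5.5, 56.2, lon, lat)[0]
        assert abs(d - 360.0) / 360.0 < 1e-6
        assert lat[0] > 56.2 and np.isclose(lon[0], -5.5)

    def test_rigid_rotation_conserves_radius(self, equator_box):
        omega = 2 * np.pi / (12 * 3600)  # one revolution in 12 h

        def rot(t, lon, lat):
            x = lon * m_per_deg_lon(0.0)
            y = lat * M_PER_DEG_LAT
            return -omega * y, omega * x

        f = AnalyticField(equator_box, rot)
        lon = np.array([5000.0 / m_per_deg_lon(0.0)])
        lat = np.array([0.0])
        r0 = haversine_m(0, 0, lon, lat)[0]
        for k in range(120):  # 120 x 360 s = one revolution
            lon, lat = advect_step(lon, lat, k * 360.0, 360.0, f)
        r1 = haversine_m(0, 0, lon, lat)[0]
        assert abs(r1 - r0) / r0 < 1e-3

    def test_rk4_agrees_with_fine_euler_oracle(self, equator_box):
        def smooth(t, lon, lat):
            x = lon * m_per_deg_lon(0.0)
            y = lat * M_PER_DEG_LAT
            return 0.1 + 0.05 * np.sin(2 * np.pi * y / 5e4), 0.05 * np.cos(2 * np.pi * x / 5e4)

        f = AnalyticField(equator_box, smooth)
        plon, plat = np.array([0.0]), np.array([0.0])
        for k in range(240):  # RK4, dt = 360 s, 24 h
            plon, plat = advect_step(plon, plat, k * 360.0, 360.0, f)
        elon, elat = np.array([0.0]), np.array([0.0])
        for k in range(86400):  # forward Euler, dt = 1 s
            u, v = f.velocity(float(k), elon, elat)
            elon = elon + u / m_per_deg_lon(elat)
            elat = elat + v / M_PER_DEG_LAT
        assert haversine_m(plon, plat, elon, elat)[0] < 1.0

    def test_diffusion_msd_matches_4dt(self, equator_box):
        rng = np.random.default_rng(0)
        D, n, hours = 10.0, 10_000, 24
        lon = np.zeros(n)
        lat = np.zeros(n)
        f = still_field(equator_box)
        for k in range(hours * 10):  # dt = 360 s
            lon, lat = advect_step(lon, lat, k * 360.0, 360.0, f, D=D, rng=rng)
        msd = (haversine_m(0, 0, lon, lat) ** 2).mean()
        assert abs(msd - 4 * D * hours * 3600) / (4 * D * hours * 3600) < 0.05

    def test_diffusion_requires_rng(self, equator_box):
        with pytest.raises(ValueError):
            advect_step(0.0, 0.0, 0.0, 360.0, still_field(equator_box), D=1.0, rng=None)


class TestBoundary:
    def test_water_proposal_kept(self, open_water):
        lon, lat, held = apply_boundary(-5.5, 56.5, -5.6, 56.5, open_water)
        assert lon[0] == -5.5 and not held[0]

    def test_land_proposal_held(self):
        from larvaconnect import CoastlineSpec, build_domain

        dom = build_domain((-6, -5, 56, 57), 0.05, CoastlineSpec(coast_lon=-5.5))
        lon, lat, held = apply_boundary(-5.2, 56.5, -5.6, 56.5, dom)
        assert lon[0] == -5.6 and held[0]

    def test_out_of_box_held(self, open_water):
        lon, lat, held = apply_boundary(-4.5, 56.5, -5.1, 56.5, open_water)
        assert lon[0] == -5.1 and held[0]

    def test_previous_on_land_is_contract_violation(self):
        from larvaconnect import CoastlineSpec, build_domain

        dom = build_domain((-6, -5, 56, 57), 0.05, CoastlineSpec(coast_lon=-5.5))
        with pytest.raises(ValueError, match="previous position"):
            apply_boundary(-5.6, 56.5, -5.2, 56.5, dom)


class TestRunSimulation:
    CFG = dict(release_rate=2, release_days=1.0, total_days=3.0, settle_window_days=1.0, dt_s=360.0)

    def test_particle_conservation_and_record_counts(self, open_water):
        sites = [Site("A", -5.5, 56.2), Site("B", -5.3, 56.2)]
        cfg = SimulationConfig(**self.CFG, seed=1)
        traj = run_simulation(sites, northward_field(open_water, 0.05), cfg, "2021-02-01")
        assert traj.n_particles == 2 * 2 * 24 == 96
        counts = traj.records.groupby("particle_id").size()
        for p, release in traj.release_times.items():
            expect = int((traj.sim_end - release) / np.timedelta64(3600, "s")) + 1
            assert counts[p] == expect

    def test_every_recorded_position_on_water(self):
        from larvaconnect import CoastlineSpec, build_domain

        dom = build_domain((-6, -5, 56, 57), 0.05, CoastlineSpec(coast_lon=-5.4))
        f = AnalyticField(dom, lambda t, lon, lat: (np.full_like(lon, 0.3), np.zeros_like(lon)))
        f.diffusivity_D = 5.0
        cfg = SimulationConfig(**self.CFG, seed=2)
        traj = run_simulation([Site("A", -5.6, 56.5)], f, cfg, "2021-02-01")
        assert dom.is_water(traj.records["lon"].to_numpy(), traj.records["lat"].to_numpy()).all()

    def test_still_field_keeps_particles_stationary_exactly(self, open_water):
        cfg = SimulationConfig(**self.CFG, seed=3)
        traj = run_simulation([Site("A", -5.5, 56.5)], still_field(open_water), cfg, "2021-02-01")
        assert (traj.records["lon"] == -5.5).all() and (traj.records["lat"] == 56.5).all()

    def test_seeded_determinism(self, open_water):
        f = northward_field(open_water, 0.05)
        f.diffusivity_D = 2.0
        cfg = SimulationConfig(**self.CFG, seed=7)
        t1 = run_simulation([Site("A", -5.5, 56.2)], f, cfg, "2021-02-01")
        t2 = run_simulation([Site("A", -5.5, 56.2)], f, cfg, "2021-02-01")
        assert t1.records.equals(t2.records)

    def test_northward_flow_moves_all_particles_north(self, open_water):
        cfg = SimulationConfig(**self.CFG, seed=4)
        traj = run_simulation([Site("A", -5.5, 56.05)], northward_field(open_water, 0.1), cfg, "2021-02-01")
        finals = traj.records.sort_values("time").groupby("particle_id").last()
        assert (finals["lat"] > 56.05).all()

    def test_short_field_rejected(self, open_water):
        from larvaconnect import FlowConfig, generate_flow

        ff = generate_flow(open_water, FlowConfig(noise_speed=0.0), "2021-02-01", "2021-02-02")
        with pytest.raises(ValueError, match="span"):
            run_simulation([Site("A", -5.5, 56.5)], ff, SimulationConfig(**self.CFG, seed=0), "2021-02-01")

    def test_site_off_water_rejected(self):
        from larvaconnect import CoastlineSpec, build_domain

        dom = build_domain((-6, -5, 56, 57), 0.05, CoastlineSpec(coast_lon=-5.5))
        f = still_field(dom)
        with pytest.raises(ValueError, match="water"):
            run_simulation([Site("A", -5.2, 56.5)], f, SimulationConfig(**self.CFG, seed=0), "2021-02-01")
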