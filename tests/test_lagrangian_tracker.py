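"""Advection kernel, release scheduling, stranding rules, densities."""

import numpy as np
import pytest
from scipy import stats

from mangroveshift import synthetic_data as sd
from mangroveshift.domain import METERS_PER_DEGREE, DomainSpec
from mangroveshift.lagrangian_tracker import (
    CoverageError,
    ReleaseSchedule,
    VelocityField,
    advect,
    build_release_schedule,
    euler_step,
    interp_velocity,
    summarize_trajectories,
    trajectory_density,
)


def strip_spec(n_hours=8, res=0.1, lat_max=25.0):
    return DomainSpec(lon_min=-81.0, lon_max=-80.0, lat_min=24.0, lat_max=lat_max,
                      resolution=res, n_hours=n_hours)


def strip_mask(spec, coast_lon=-80.65):
    return sd.make_land_mask(spec, sd.CoastlineParams(coast_lon=coast_lon, ecotone_lat=24.5))


# ----------------------------------------------------------------------
# interpolation
# ----------------------------------------------------------------------

class TestInterp:
    def test_constant_field_everywhere(self):
        spec = strip_spec()
        f = sd.make_velocity_field("uniform", {"u": 0.5, "v": 0.0}, spec)
        assert interp_velocity(f, -80.37, 24.61, 3.2) == pytest.approx((0.5, 0.0))

    def test_exact_at_nodes_and_snapshots(self):
        spec = strip_spec(n_hours=2)
        rng = np.random.default_rng(0)
        u = rng.normal(size=(2, spec.n_lat + 1, spec.n_lon + 1))
        v = rng.normal(size=u.shape)
        f = VelocityField(spec, u, v)
        i, j = 3, 4
        got = interp_velocity(f, float(spec.lon_edges[j]), float(spec.lat_edges[i]), 1.0)
        assert got == pytest.approx((u[1, i, j], v[1, i, j]))

    def test_bilinear_closed_form_at_cell_center(self):
        spec = strip_spec(n_hours=1)
        u = np.zeros((1, spec.n_lat + 1, spec.n_lon + 1))
        u[0, 3, 4] = u[0, 3, 5] = 0.0
        u[0, 4, 4] = u[0, 4, 5] = 2.0
        f = VelocityField(spec, u, np.zeros_like(u))
        lon_c = spec.lon_min + (4 + 0.5) * spec.resolution
        lat_c = spec.lat_min + (3 + 0.5) * spec.resolution
        got_u, _ = interp_velocity(f, lon_c, lat_c, 0.0)
        assert got_u == pytest.approx(1.0)

    def test_linear_in_time_between_snapshots(self):
        spec = strip_spec(n_hours=2)
        u = np.zeros((2, spec.n_lat + 1, spec.n_lon + 1))
        u[1, :, :] = 1.0
        f = VelocityField(spec, u, np.zeros_like(u))
        got_u, _ = interp_velocity(f, -80.5, 24.5, 0.25)
        assert got_u == pytest.approx(0.25)

    def test_out_of_coverage_signaled(self):
        spec = strip_spec(n_hours=2)
        f = sd.make_velocity_field("uniform", {"u": 0.1, "v": 0.0}, spec)
        with pytest.raises(CoverageError):
            interp_velocity(f, -80.5, 24.5, 5.0)
        with pytest.raises(CoverageError):
            interp_velocity(f, -79.5, 24.5, 0.0)


# ----------------------------------------------------------------------
# Euler step
# ----------------------------------------------------------------------

class TestEulerStep:
    def test_zero_velocity_is_a_fixed_point(self):
        assert euler_step(-80.5, 24.5, 0.0, 0.0, 3600.0) == (pytest.approx(-80.5), pytest.approx(24.5))

    def test_equatorial_zonal_displacement_matches_arc_conversion(self):
        lon1, lat1 = euler_step(0.0, 0.0, 1.0, 0.0, 3600.0)
        assert lon1 == pytest.approx(3600.0 / METERS_PER_DEGREE)  # ~0.032376 deg
        assert lat1 == 0.0

    @pytest.mark.parametrize("lat", [-60.0, 0.0, 24.5, 75.0])
    def test_meridional_displacement_is_latitude_independent(self, lat):
        _, lat1 = euler_step(-80.5, lat, 0.0, 1.0, 3600.0)
        assert lat1 - lat == pytest.approx(3600.0 / METERS_PER_DEGREE)

    def test_polar_guard(self):
        with pytest.raises(ValueError, match="lat"):
            euler_step(0.0, 89.5, 0.1, 0.1, 3600.0)

    def test_uniform_flow_is_integrated_exactly(self):
        """Euler is exact for a constant field: T hours of eastward drift land
        on the closed-form longitude."""
        spec = strip_spec(n_hours=25)
        f = sd.make_velocity_field("uniform", {"u": 0.4, "v": 0.0}, spec)
        lon, lat = -80.9, 24.35
        for k in range(24):
            u, v = interp_velocity(f, lon, lat, float(k))
            lon, lat = euler_step(lon, lat, u, v, 3600.0)
        expected = -80.9 + 0.4 * 24 * 3600.0 / (METERS_PER_DEGREE * np.cos(np.radians(24.35)))
        assert lon == pytest.approx(expected, abs=1e-12)

    def test_double_gyre_error_shrinks_as_dt_halves(self, equatorial_spec):
        f = sd.make_velocity_field("double_gyre", {"max_speed": 0.5}, equatorial_spec)

        def integrate(dt, total=6 * 3600.0):
            lon, lat = 0.5, 0.25
            for _ in range(int(total / dt)):
                u, v = interp_velocity(f, lon, lat, 0.0)
                lon, lat = euler_step(lon, lat, u, v, dt)
            return lon, lat

        ref = integrate(25.0)
        errors = []
        for dt in (3600.0, 1800.0, 900.0, 450.0):
            lon, lat = integrate(dt)
            errors.append(np.hypot(lon - ref[0], lat - ref[1]))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_double_gyre_conserves_stream_function_at_small_dt(self, equatorial_spec):
        f = sd.make_velocity_field("double_gyre", {"max_speed": 0.5}, equatorial_spec)
        lon, lat = 0.5, 0.25
        psi0 = sd.double_gyre_stream_function(equatorial_spec, lon, lat)
        for _ in range(int(12 * 3600 / 60)):
            u, v = interp_velocity(f, lon, lat, 0.0)
            lon, lat = euler_step(lon, lat, u, v, 60.0)
        psi1 = sd.double_gyre_stream_function(equatorial_spec, lon, lat)
        assert psi1 == pytest.approx(psi0, rel=0.05)


# ----------------------------------------------------------------------
# release schedule
# ----------------------------------------------------------------------

class TestReleaseSchedule:
    def test_events_are_cells_times_hours(self):
        spec = strip_spec(n_hours=4)
        mask = strip_mask(spec)
        coastal = np.argwhere(mask.coastal)[:2]
        points = [(spec.lon_centers[c], spec.lat_centers[r]) for r, c in coastal]
        sched = build_release_schedule(mask, points, (spec.t0, spec.t0 + np.timedelta64(2, "h")))
        assert sched.n_events == 4

    def test_lagoon_points_collapse_to_their_inlet(self, spec, mask):
        lagoon = np.argwhere(mask.lagoon_id > 0)[:2]
        points = [(spec.lon_centers[c], spec.lat_centers[r]) for r, c in lagoon]
        sched = build_release_schedule(mask, points, (spec.t0, spec.t0 + np.timedelta64(1, "h")))
        assert len(sched.cells) == 1
        (ilon, ilat) = mask.waterbodies["lagoon_1"]
        ir, ic = spec.cell_index(ilon, ilat)
        assert tuple(sched.cells[0]) == (int(ir), int(ic))

    def test_release_design_calendar_arithmetic(self):
        """Hourly releases from 87 cells over a 92-day window (August through
        October) give 87 x 2208 = 192,096 events."""
        spec = DomainSpec(lon_min=-81.0, lon_max=-80.0, lat_min=24.0, lat_max=35.0,
                          resolution=0.1, t0=np.datetime64("2011-08-01T00:00"), n_hours=2209)
        mask = strip_mask(spec)
        coastal = np.argwhere(mask.coastal)[:87]
        points = [(spec.lon_centers[c], spec.lat_centers[r]) for r, c in coastal]
        sched = build_release_schedule(
            mask, points, (np.datetime64("2011-08-01T00:00"), np.datetime64("2011-11-01T00:00"))
        )
        assert len(sched.cells) == 87
        assert len(sched.release_times) == 2208
        assert sched.n_events == 192096

    def test_window_past_coverage_rejected(self, mask, spec):
        points = [(-80.3, 25.0)]
        with pytest.raises(CoverageError):
            build_release_schedule(mask, points, (spec.t0, spec.t0 + np.timedelta64(10_000, "h")))


# ----------------------------------------------------------------------
# advection + stranding
# ----------------------------------------------------------------------

class TestAdvect:
    def test_static_particle_expires_in_place(self):
        spec = strip_spec(n_hours=40, res=0.1)
        mask = strip_mask(spec)
        f = sd.make_velocity_field("uniform", {"u": 0.0, "v": 0.0}, spec, mask=mask)
        # release mid-ocean, far from the coastal column
        sched = ReleaseSchedule(spec, np.array([[5, 8]]), spec.t0, spec.t0 + np.timedelta64(1, "h"))
        trs = advect(f, mask, sched, max_float_months=1 / 30.44, seed=0)  # 1 day
        assert len(trs) == 1 and trs[0].status == "expired"
        assert np.allclose(trs[0].lons, trs[0].lons[0])
        assert len(trs[0].lons) == 25  # release + 24 hourly steps

    def _onshore_setup(self, release_col, u=-0.5, n_hours=400):
        spec = strip_spec(n_hours=n_hours, res=0.1)
        mask = strip_mask(spec, coast_lon=-80.65)  # land cols 0..3, coastal col 4
        f = sd.make_velocity_field("uniform", {"u": u, "v": 0.0}, spec, mask=mask)
        sched = ReleaseSchedule(spec, np.array([[5, release_col]]), spec.t0,
                                spec.t0 + np.timedelta64(1, "h"))
        return spec, mask, f, sched

    def test_stranding_waits_for_min_float_when_coast_is_close(self):
        # coast reachable in hours; min float forced to 1 day
        spec, mask, f, sched = self._onshore_setup(release_col=6)
        trs = advect(f, mask, sched, max_float_months=10 / 30.44,
                     min_float_range=(1.0, 1.0), seed=0)
        tr = trs[0]
        assert tr.status == "stranded"
        elapsed_h = (tr.stranding_time - tr.release_time) / np.timedelta64(1, "h")
        assert elapsed_h == 24.0  # strands at the first eligible hourly step
        assert mask.coastal[tr.stranding_cell]

    def test_stranding_time_matches_crossing_oracle_when_coast_is_far(self):
        # min float elapses long before the particle reaches the coast
        spec, mask, f, sched = self._onshore_setup(release_col=9, u=-0.1)
        trs = advect(f, mask, sched, max_float_months=10 / 30.44,
                     min_float_range=(1.0, 1.0), seed=0)
        tr = trs[0]
        assert tr.status == "stranded"
        # analytic crossing: westward drift from the col-9 centre until the
        # position first falls inside the coastal column (entry at its
        # eastern edge); latitude never changes, so the metric is constant
        coastal_col = int(np.argwhere(mask.coastal[5])[0][0])
        east_edge = spec.lon_min + (coastal_col + 1) * spec.resolution
        dist_deg = float(spec.lon_centers[9]) - east_edge
        deg_per_h = 0.1 * 3600.0 / (METERS_PER_DEGREE * np.cos(np.radians(float(spec.lat_centers[5]))))
        crossing_h = dist_deg / deg_per_h
        elapsed_h = (tr.stranding_time - tr.release_time) / np.timedelta64(1, "h")
        assert elapsed_h == pytest.approx(np.ceil(crossing_h), abs=1.0)

    def test_min_float_of_five_days_suppresses_early_stranding(self):
        spec, mask, f, sched = self._onshore_setup(release_col=6)
        trs = advect(f, mask, sched, max_float_months=10 / 30.44,
                     min_float_range=(5.0, 5.0), seed=0)
        tr = trs[0]
        assert tr.status == "stranded"
        elapsed_h = (tr.stranding_time - tr.release_time) / np.timedelta64(1, "h")
        assert elapsed_h >= 5 * 24
        assert mask.coastal[tr.stranding_cell]

    def test_outflow_leaves_the_domain(self):
        spec, mask, f, sched = self._onshore_setup(release_col=9, u=0.5)
        trs = advect(f, mask, sched, max_float_months=10 / 30.44, seed=0)
        assert trs[0].status == "out_of_domain"

    def test_schedule_beyond_coverage_rejected_before_integration(self):
        spec, mask, f, sched = self._onshore_setup(release_col=6, n_hours=50)
        with pytest.raises(CoverageError):
            advect(f, mask, sched, max_float_months=17, seed=0)

    def test_invariants_on_large_seeded_run(self, tracker_run_10k):
        spec, mask, trajectories = tracker_run_10k
        assert len(trajectories) == 10000
        statuses = {"stranded": 0, "expired": 0, "out_of_domain": 0}
        for tr in trajectories:
            statuses[tr.status] += 1
            row, col = spec.cell_index(tr.lons, tr.lats)
            assert (row >= 0).all() and (col >= 0).all()
            assert not mask.land[row, col].any(), "recorded position on a land cell"
            if tr.status == "stranded":
                assert mask.coastal[tr.stranding_cell]
                elapsed_d = (tr.stranding_time - tr.release_time) / np.timedelta64(1, "h") / 24.0
                assert elapsed_d >= tr.min_float_days
        assert sum(statuses.values()) == 10000  # exactly one terminal status each

    def test_min_float_draws_are_uniform_on_1_to_5_days(self, tracker_run_10k):
        _, _, trajectories = tracker_run_10k
        draws = np.array([tr.min_float_days for tr in trajectories])
        ks = stats.kstest(draws, "uniform", args=(1.0, 4.0))
        assert ks.pvalue > 0.01


# ----------------------------------------------------------------------
# density
# ----------------------------------------------------------------------

class TestDensity:
    def test_counts_distinct_trajectories_once_per_cell(self):
        spec = strip_spec(n_hours=40, res=0.1)
        mask = strip_mask(spec)
        f = sd.make_velocity_field("uniform", {"u": 0.0, "v": 0.0}, spec, mask=mask)
        sched = ReleaseSchedule(spec, np.array([[5, 8]]), spec.t0, spec.t0 + np.timedelta64(2, "h"))
        trs = advect(f, mask, sched, max_float_months=1 / 30.44, seed=0)
        dens = trajectory_density(trs, spec)
        assert dens[5, 8] == 2  # two releases from the same cell
        assert dens.sum() == 2

    def test_moving_particle_tallies_every_visited_cell_once(self):
        spec, mask = strip_spec(n_hours=300, res=0.1), None
        mask = strip_mask(spec)
        f = sd.make_velocity_field("uniform", {"u": 0.0, "v": 0.3}, spec, mask=mask)
        sched = ReleaseSchedule(spec, np.array([[0, 8]]), spec.t0, spec.t0 + np.timedelta64(1, "h"))
        trs = advect(f, mask, sched, max_float_months=1 / 30.44, seed=0)
        dens = trajectory_density(trs, spec)
        visited = len(np.unique(spec.cell_index(trs[0].lons, trs[0].lats)[0]))
        assert (dens > 0).sum() == visited
        assert dens.max() == 1

    def test_empty_list_gives_zero_grid(self):
        spec = strip_spec()
        assert trajectory_density([], spec).sum() == 0

    def test_summary_frame_carries_the_audit_columns(self, tracker_run_10k):
        spec, _, trajectories = tracker_run_10k
        df = summarize_trajectories(trajectories[:100], spec)
        assert set(df["status"]) <= {"stranded", "expired", "out_of_domain"}
        assert df["min_float_days"].between(1, 5).all()
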