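"""Velocity-profile estimation, plateau rules and kinematic quantities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers_brute import brute_plateau
from rootkinetics import (
    BoundaryNotFoundError,
    DomainError,
    EstimationError,
    GrowthZoneSpec,
    InsufficientDataError,
    VelocityProfile,
    analyze_cohort,
    analyze_root,
    cell_cycle_duration,
    cell_production_rate,
    compute_flux,
    elongation_transit_time,
    estimate_velocity_profile,
    growth_zone_boundary,
    interpolate_cell_lengths,
    meristem_boundary,
    plateau_boundary,
    simulate_cell_file,
    simulate_cohort,
    simulate_particles,
    strain_rate_profile,
)


def _make_profile(grid, v):
    grid = np.asarray(grid, float)
    v = np.asarray(v, float)
    return VelocityProfile(
        grid=grid, v=v, raw_midpoints=grid, raw_velocities=v, bandwidth=50.0
    )


@pytest.fixture(scope="module")
def noiseless_fit():
    """Dense noiseless particles with a short displacement interval.

    dt = 0.1 h keeps the secant reading of the velocity field essentially
    pointwise (a 1 h interval smears readings by up to ~12% of V near the
    bump's curvature — a property of the measurement design, not the
    estimator — so estimator checks use the short interval).
    """
    spec = GrowthZoneSpec(500.0, 10.0, 0.04, 400.0, 280.0)
    obs = simulate_particles(spec, 2000, dt=0.1, seed=1)
    vp = estimate_velocity_profile(obs, bandwidth=50.0)
    return spec, vp


class TestVelocityEstimation:
    def test_noiseless_rmse_below_2pct(self, noiseless_fit):
        spec, vp = noiseless_fit
        rmse = float(np.sqrt(np.mean((vp.v - spec.velocity(vp.grid)) ** 2)))
        assert rmse < 0.02 * spec.final_velocity

    def test_monotone_nonnegative_by_construction(self, noiseless_fit):
        _, vp = noiseless_fit
        assert (vp.v >= 0).all()
        assert (np.diff(vp.v) >= -1e-12).all()

    def test_constant_velocity_data(self, default_spec):
        obs = simulate_particles(default_spec, 100, dt=0.5, seed=2)
        rec = obs.records[obs.records["x_start_um"] > default_spec.growth_zone_length]
        assert len(rec) >= 10
        from rootkinetics import ParticleObservations

        vp = estimate_velocity_profile(
            ParticleObservations(rec.reset_index(drop=True)), bandwidth=100.0,
            min_points=8,
        )
        np.testing.assert_allclose(vp.v, default_spec.final_velocity, rtol=1e-6)

    def test_sparse_windows_raise_without_floor(self, default_spec):
        obs = simulate_particles(default_spec, 12, dt=1.0, seed=3)
        with pytest.raises(EstimationError, match="fewer than 3 particles"):
            estimate_velocity_profile(obs, bandwidth=10.0, min_points=None)

    def test_duplicate_midpoints_are_both_used(self):
        import pandas as pd

        from rootkinetics import ParticleObservations

        x0 = np.linspace(0, 100, 12)
        df = pd.DataFrame(
            {
                "root_id": "r",
                "x_start_um": np.concatenate([x0, [50.0, 50.0]]),
                "x_end_um": np.concatenate([x0 + 10.0, [58.0, 62.0]]),
                "dt_h": 1.0,
            }
        )
        vp = estimate_velocity_profile(
            ParticleObservations(df), bandwidth=60.0
        )
        # both duplicate points pull the local mean at x=55
        assert 9.0 < vp.interp(55.0) < 11.0

    def test_too_few_records(self, default_spec):
        obs = simulate_particles(default_spec, 5, dt=1.0, seed=1)
        with pytest.raises(InsufficientDataError):
            estimate_velocity_profile(obs)


class TestFlux:
    def test_elementwise_division(self):
        assert compute_flux(300.0, 150.0) == pytest.approx(2.0)
        assert compute_flux(0.0, 150.0) == 0.0
        np.testing.assert_allclose(
            compute_flux([300.0, 150.0], [150.0, 100.0]), [2.0, 1.5]
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DomainError):
            compute_flux([10.0], [0.0])

    def test_flux_constant_beyond_meristem_noiseless(self, noiseless_fit):
        spec, vp = noiseless_fit
        prof = simulate_cell_file(spec, 0.0, seed=1)
        lengths = interpolate_cell_lengths(vp.grid, prof)
        mask = (vp.grid >= spec.meristem_length) & np.isfinite(lengths)
        flux = compute_flux(vp.v[mask], lengths[mask])
        assert flux.std() / flux.mean() < 0.02
        assert flux.mean() == pytest.approx(spec.cell_production, rel=0.02)


class TestPlateauRule:
    def test_hand_scanned_example(self):
        pos = [0, 100, 200, 300, 400, 500]
        vals = [1, 2, 10, 10, 10, 10]
        assert plateau_boundary(pos, vals) == 200.0

    def test_constant_series_first_point(self):
        assert plateau_boundary([0, 10, 20, 30], [5, 5, 5, 5]) == 0.0

    def test_strictly_increasing_has_no_boundary(self):
        with pytest.raises(BoundaryNotFoundError):
            plateau_boundary([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            kind = rng.integers(0, 3)
            if kind == 0:  # ramp + plateau + noise
                ramp = np.minimum(np.arange(n) / max(n // 2, 1), 1.0)
                vals = ramp * 10 + rng.normal(0, 0.5, n)
            elif kind == 1:  # monotone increase
                vals = np.cumsum(rng.uniform(0.1, 1.0, n))
            else:  # pure noise
                vals = rng.uniform(0, 10, n)
            pos = np.arange(n, dtype=float)
            expected = brute_plateau(list(pos), list(vals))
            if expected is None:
                with pytest.raises(BoundaryNotFoundError):
                    plateau_boundary(pos, vals)
            else:
                assert plateau_boundary(pos, vals) == expected

    @given(
        st.lists(
            st.floats(min_value=-100.0, max_value=100.0, allow_nan=False),
            min_size=3,
            max_size=30,
        )
    )
    def test_plateau_property_vs_brute(self, vals):
        pos = list(range(len(vals)))
        expected = brute_plateau(pos, vals)
        if expected is None:
            with pytest.raises(BoundaryNotFoundError):
                plateau_boundary(pos, vals)
        else:
            assert plateau_boundary(pos, vals) == expected


class TestBoundaries:
    def test_noiseless_boundaries_at_95pct_rise_points(self, noiseless_fit):
        # the 95% rule fires where the curve reaches ~95% of the plateau
        # mean: ~0.95*Lm on the linear flux ramp, and near the velocity
        # field's 95% point (~810 um) for the raised cosine — not at the
        # true boundaries (500, 900)
        spec, vp = noiseless_fit
        prof = simulate_cell_file(spec, 0.0, seed=1)
        lengths = interpolate_cell_lengths(vp.grid, prof)
        lm = meristem_boundary(vp, lengths)
        assert abs(lm - 0.95 * spec.meristem_length) <= 10.0
        lg, v_final = growth_zone_boundary(vp)
        assert 780.0 <= lg <= 860.0
        assert v_final == pytest.approx(spec.final_velocity, rel=0.005)

    def test_constant_profile_boundary_at_first_point(self):
        vp = _make_profile(np.arange(0, 50.0), np.full(50, 7.0))
        lg, v_final = growth_zone_boundary(vp)
        assert lg == 0.0
        assert v_final == pytest.approx(7.0)


class TestScalars:
    def test_cell_production(self):
        assert cell_production_rate(300.0, 150.0) == pytest.approx(2.0)
        assert cell_production_rate(0.0, 150.0) == 0.0
        with pytest.raises(DomainError):
            cell_production_rate(300.0, 0.0)

    def test_cell_cycle_duration(self):
        assert cell_cycle_duration(1.0, np.log(2.0)) == pytest.approx(1.0)
        assert cell_cycle_duration(50.0, 2.0) == pytest.approx(
            np.log(2.0) * 25.0
        )
        with pytest.raises(DomainError):
            cell_cycle_duration(50.0, 0.0)


class TestStrainRate:
    def test_linear_field(self):
        grid = np.arange(0.0, 100.0)
        r = strain_rate_profile(_make_profile(grid, 0.5 * grid))
        np.testing.assert_allclose(r, 0.5, rtol=1e-9)

    def test_constant_field(self):
        grid = np.arange(0.0, 100.0)
        r = strain_rate_profile(_make_profile(grid, np.full(100, 42.0)))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_integral_recovers_final_velocity(self, noiseless_fit):
        spec, vp = noiseless_fit
        r = strain_rate_profile(vp)
        _, v_final = growth_zone_boundary(vp)
        total = float(np.trapezoid(r, vp.grid))
        assert total == pytest.approx(v_final, rel=0.01)


class TestTransitTime:
    def test_constant_velocity(self):
        grid = np.arange(0.0, 400.0)
        vp = _make_profile(grid, np.full(400, 300.0))
        assert elongation_transit_time(vp, 0.0, 300.0) == pytest.approx(
            1.0, rel=1e-3
        )

    def test_linear_velocity_log_closed_form(self):
        grid = np.arange(50.0, 1100.0)
        vp = _make_profile(grid, grid.copy())
        t = elongation_transit_time(vp, 100.0, 1000.0)
        assert t == pytest.approx(np.log(10.0), rel=1e-3)

    def test_noiseless_profile_matches_analytic_integral(self, noiseless_fit):
        from rootkinetics import transit_time_true

        spec, vp = noiseless_fit
        t = elongation_transit_time(
            vp, spec.meristem_length, spec.growth_zone_length
        )
        assert t == pytest.approx(transit_time_true(spec), rel=0.005)

    def test_scaling_velocity_up_reduces_transit(self, noiseless_fit):
        _, vp = noiseless_fit
        faster = _make_profile(vp.grid, vp.v * 1.5)
        assert elongation_transit_time(faster, 500.0, 800.0) < (
            elongation_transit_time(vp, 500.0, 800.0)
        )

    def test_zero_velocity_rejected(self):
        grid = np.arange(0.0, 10.0)
        vp = _make_profile(grid, np.concatenate([[0.0], np.ones(9)]))
        with pytest.raises(DomainError):
            elongation_transit_time(vp, 0.0, 5.0)


class TestEndToEnd:
    def test_single_root_full_analysis(self, default_spec):
        roots = simulate_cohort(
            default_spec, 1, 40, dt=1.0, position_noise_sd=5.0,
            length_cv=0.05, seed=12,
        )
        s = analyze_root(*roots[0])
        assert 0 < s.meristem_length_um < s.growth_zone_length_um
        assert s.cell_production_per_h == pytest.approx(
            s.final_velocity_um_h / s.mature_cell_length_um
        )
        assert s.cell_cycle_duration_h == pytest.approx(
            np.log(2.0) * s.meristem_cell_count / s.cell_production_per_h
        )
        assert s.transit_time_h > 0
        assert s.n_source in ("static", "length_fallback")

    def test_cohort_collects_failures_without_aborting(self, default_spec):
        roots = simulate_cohort(default_spec, 3, 40, seed=4)
        # sabotage one root with too few particles
        broken = roots[1][0].records.iloc[:5].reset_index(drop=True)
        from rootkinetics import ParticleObservations

        roots[1] = (ParticleObservations(broken), roots[1][1])
        table, failures = analyze_cohort(roots)
        assert len(table) == 2
        assert list(failures) == ["root2"]
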