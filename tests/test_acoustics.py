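import math

import numpy as np
import pytest

from sonolfa import acoustics
from sonolfa.acoustics import (
    MediumSpec,
    ParticleSpec,
    StandingWaveField,
    acoustic_contrast_factor,
    enrichment_factor,
    pressure_nodes,
    primary_radiation_force,
    simulate_migration,
)


def make_medium(rho=1000.0, c=1500.0, eta=1e-3):
    return MediumSpec(
        density_m=rho,
        compressibility_m=1.0 / (rho * c * c),
        sound_speed=c,
        dynamic_viscosity=eta,
    )


class TestSpecs:
    def test_particle_invariants(self):
        with pytest.raises(ValueError):
            ParticleSpec(radius=0.0, density_p=1000.0, compressibility_p=0.0)
        with pytest.raises(ValueError):
            ParticleSpec(radius=1e-8, density_p=-1.0, compressibility_p=0.0)
        with pytest.raises(ValueError):
            ParticleSpec(radius=1e-8, density_p=1000.0, compressibility_p=-1e-10)

    def test_particle_volume(self):
        p = ParticleSpec(radius=2.0, density_p=1.0, compressibility_p=0.0)
        assert p.volume == pytest.approx(4.0 / 3.0 * math.pi * 8.0)

    def test_medium_consistency_check(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MediumSpec(
                density_m=1000.0,
                compressibility_m=1e-10,  # implies c far from 1500
                sound_speed=1500.0,
                dynamic_viscosity=1e-3,
            )

    def test_wavelength_wavenumber_consistency(self, fundamental_field):
        assert fundamental_field.wavelength * fundamental_field.wavenumber == pytest.approx(
            2.0 * math.pi, rel=1e-12
        )

    def test_resonance_predicate(self, water):
        lam = water.sound_speed / 700e3
        res = StandingWaveField.for_medium(water, 1e5, 700e3, 1.5 * lam)
        assert res.is_resonant() and res.mode_number == 3
        off = StandingWaveField.for_medium(water, 1e5, 700e3, 1.3 * lam)
        assert not off.is_resonant()


class TestContrastFactor:
    def test_matched_medium_is_zero(self):
        m = make_medium()
        p = ParticleSpec(radius=1e-8, density_p=m.density_m, compressibility_p=m.compressibility_m)
        assert acoustic_contrast_factor(p, m) == pytest.approx(0.0, abs=1e-15)

    def test_gold_in_water_oracle(self):
        # frozen from a by-hand evaluation: 1 + 3*18320/39640 - 0
        m = make_medium(rho=1000.0)
        p = ParticleSpec(radius=2e-8, density_p=19320.0, compressibility_p=0.0)
        assert acoustic_contrast_factor(p, m) == pytest.approx(2.386478304742684, rel=1e-12)

    def test_rigid_dense_particle_positive(self, water):
        # beta_p/beta_m -> 0 with rho_p >= rho_m gives a node seeker
        p = ParticleSpec(radius=1e-8, density_p=water.density_m, compressibility_p=0.0)
        assert acoustic_contrast_factor(p, water) > 0

    def test_monotone_in_particle_density(self, water):
        rhos = np.linspace(100.0, 20000.0, 40)
        phis = [
            acoustic_contrast_factor(
                ParticleSpec(radius=1e-8, density_p=r, compressibility_p=0.0), water
            )
            for r in rhos
        ]
        assert np.all(np.diff(phis) > 0)


class TestRadiationForce:
    def test_zero_at_nodes_and_antinodes(self, gold_40nm, water, fundamental_field):
        lam = fundamental_field.wavelength
        for n in range(5):
            x = n * lam / 4.0  # 2kx = n*pi
            assert primary_radiation_force(x, gold_40nm, water, fundamental_field) == pytest.approx(
                0.0, abs=1e-30
            )

    def test_zero_for_matched_particle(self, water, fundamental_field):
        p = ParticleSpec(
            radius=2e-8, density_p=water.density_m, compressibility_p=water.compressibility_m
        )
        x = np.linspace(0, fundamental_field.cavity_length, 33)
        f = primary_radiation_force(x, p, water, fundamental_field)
        np.testing.assert_allclose(f, 0.0, atol=1e-28)

    def test_term_by_term_fixture(self, gold_40nm, water, fundamental_field):
        # frozen from an independent term-by-term evaluation at x = lambda/8
        x = fundamental_field.wavelength / 8.0
        f = primary_radiation_force(x, gold_40nm, water, fundamental_field)
        assert f == pytest.approx(-2.629383043819751e-19, rel=1e-10)

    def test_restoring_toward_node(self, gold_40nm, water, fundamental_field):
        # x is displacement from a node: small positive x gives negative force
        lam = fundamental_field.wavelength
        assert primary_radiation_force(lam / 100, gold_40nm, water, fundamental_field) < 0
        assert primary_radiation_force(-lam / 100, gold_40nm, water, fundamental_field) > 0

    def test_period_and_odd_symmetry(self, gold_40nm, water, fundamental_field):
        lam = fundamental_field.wavelength
        x = np.linspace(0, lam / 4, 17)
        f = lambda v: primary_radiation_force(v, gold_40nm, water, fundamental_field)
        np.testing.assert_allclose(f(x), f(x + lam / 2.0), rtol=1e-9, atol=1e-30)
        np.testing.assert_allclose(f(x), -f(-x), rtol=1e-12, atol=1e-30)


class TestPressureNodes:
    def test_fundamental_single_node_at_center(self, fundamental_field):
        nodes = pressure_nodes(fundamental_field, 1)
        assert nodes.shape == (1,)
        assert nodes[0] == pytest.approx(fundamental_field.cavity_length / 2.0)

    def test_full_wavelength_two_nodes(self, water):
        lam = water.sound_speed / 700e3
        field = StandingWaveField.for_medium(water, 1e5, 700e3, lam)
        nodes = pressure_nodes(field, 1)
        np.testing.assert_allclose(nodes, [lam / 4.0, 3.0 * lam / 4.0])

    def test_mode_count_matches_mode_number(self, water):
        lam = water.sound_speed / 700e3
        for m in range(1, 6):
            field = StandingWaveField.for_medium(water, 1e5, 700e3, m * lam / 2.0)
            assert pressure_nodes(field, 1).size == m

    def test_negative_contrast_targets_antinodes(self, water):
        lam = water.sound_speed / 700e3
        field = StandingWaveField.for_medium(water, 1e5, 700e3, lam)
        anti = pressure_nodes(field, -1)
        np.testing.assert_allclose(anti, [lam / 2.0])

    def test_non_resonant_raises(self, water):
        lam = water.sound_speed / 700e3
        field = StandingWaveField.for_medium(water, 1e5, 700e3, 1.37 * lam)
        with pytest.raises(ValueError, match="not an integer"):
            pressure_nodes(field, 1)


@pytest.fixture()
def cluster_particle():
    """Aggregate-scale particle so migration happens on short time scales."""
    return ParticleSpec(
        radius=20e-9,
        density_p=19320.0,
        compressibility_p=0.0,
        effective_cluster_radius=2e-6,
    )


@pytest.fixture()
def strong_field(water):
    lam = water.sound_speed / 700e3
    return StandingWaveField.for_medium(water, 5e5, 700e3, lam / 2.0)


def migrate(x0, particle, water, field, duration=0.5, dt=1e-4, **kw):
    return simulate_migration(
        np.asarray(x0, dtype=float), particle, water, field, duration, dt,
        force_scale=kw.pop("force_scale", 1e7), **kw,
    )


class TestMigration:
    def test_node_start_is_stationary(self, cluster_particle, water, strong_field):
        node = strong_field.cavity_length / 2.0
        traj = migrate([node], cluster_particle, water, strong_field, duration=0.01)
        np.testing.assert_array_equal(traj.positions, node)

    def test_mirror_symmetry(self, cluster_particle, water, strong_field):
        node = strong_field.cavity_length / 2.0
        delta = strong_field.wavelength / 16.0
        traj = migrate([node - delta, node + delta], cluster_particle, water, strong_field)
        np.testing.assert_allclose(
            traj.positions[0] - node, node - traj.positions[1], atol=1e-12
        )

    def test_uniform_cloud_fully_converges(self, cluster_particle, water, strong_field):
        rng = np.random.default_rng(0)
        x0 = rng.uniform(0.0, strong_field.cavity_length, 100)
        traj = migrate(x0, cluster_particle, water, strong_field, duration=2.0)
        assert traj.converged_fraction == 1.0

    def test_distance_to_node_nonincreasing(self, cluster_particle, water, strong_field):
        rng = np.random.default_rng(3)
        x0 = rng.uniform(0.0, strong_field.cavity_length, 30)
        traj = migrate(x0, cluster_particle, water, strong_field, duration=0.2)
        node = strong_field.cavity_length / 2.0
        dist = np.abs(traj.positions - node)
        total = dist.sum(axis=0)
        assert np.all(np.diff(total) <= 1e-12)

    def test_bit_reproducible_with_seed(self, cluster_particle, water, strong_field):
        x0 = np.linspace(0.1, 0.9, 20) * strong_field.cavity_length
        a = migrate(x0, cluster_particle, water, strong_field, brownian=True, seed=42)
        b = migrate(x0, cluster_particle, water, strong_field, brownian=True, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_positions_stay_in_cavity(self, cluster_particle, water, strong_field):
        x0 = np.linspace(0.0, 1.0, 11) * strong_field.cavity_length
        traj = migrate(x0, cluster_particle, water, strong_field, brownian=True, seed=7)
        assert np.all(traj.positions >= 0.0)
        assert np.all(traj.positions <= strong_field.cavity_length)

    def test_overshoot_dt_raises(self, cluster_particle, water, strong_field):
        with pytest.raises(ValueError, match="dt too large"):
            migrate(
                [0.1 * strong_field.cavity_length], cluster_particle, water, strong_field,
                duration=10.0, dt=10.0, force_scale=1e9,
            )

    def test_bad_inputs(self, cluster_particle, water, strong_field):
        with pytest.raises(ValueError):
            migrate([2 * strong_field.cavity_length], cluster_particle, water, strong_field)
        with pytest.raises(ValueError):
            simulate_migration(
                np.array([0.0]), cluster_particle, water, strong_field, duration=1.0, dt=-1.0
            )


class TestEnrichment:
    def test_unchanged_positions_give_unity(self, cluster_particle, water, strong_field):
        node = strong_field.cavity_length / 2.0
        traj = migrate([node - 1e-7, node + 1e-7], cluster_particle, water, strong_field,
                       duration=0.001)
        assert enrichment_factor(traj, strong_field.wavelength / 8.0, strong_field) == 1.0

    def test_uniform_to_tenth_window_is_tenfold(self, cluster_particle, water, strong_field):
        L = strong_field.cavity_length
        # symmetric cloud: exactly 10 of 100 start inside the L/10 window
        x0 = (np.arange(100) + 0.5) / 100.0 * L
        traj = migrate(x0, cluster_particle, water, strong_field, duration=2.0)
        factor = enrichment_factor(traj, L / 20.0, strong_field)
        assert factor == pytest.approx(10.0)

    def test_seeded_run_reproducible(self, cluster_particle, water, strong_field):
        rng = np.random.default_rng(11)
        x0 = rng.uniform(0, strong_field.cavity_length, 50)
        vals = [
            enrichment_factor(
                migrate(x0, cluster_particle, water, strong_field, brownian=True, seed=5),
                strong_field.wavelength / 20.0,
                strong_field,
            )
            for _ in range(2)
        ]
        assert vals[0] == vals[1]

    def test_window_outside_cavity_raises(self, cluster_particle, water, strong_field):
        traj = migrate([0.3 * strong_field.cavity_length], cluster_particle, water, strong_field,
                       duration=0.001)
        with pytest.raises(ValueError, match="outside"):
            enrichment_factor(traj, strong_field.cavity_length, strong_field)


def test_trajectory_result_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        acoustics.TrajectoryResult(
            times=np.array([0.0, 0.0, 1.0]),
            positions=np.zeros((2, 3)),
            converged_fraction=0.0,
        )
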