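"""Brownian dynamics: release geometry, steps, reflections, proximity."""

import numpy as np
import pytest
from scipy import stats

from gluspill import (ArenaSpec, CleftSpec, DiffusionSpec, TransporterSpec,
                      astro_proximity, boundary_condition, brownian_step,
                      empty_environment, estimate_diffusivity,
                      free_diffusion_msd, release_particles,
                      resolve_collisions, simulate_run,
                      single_sphere_environment)


class TestRelease:
    def test_all_inside_cylinder(self):
        cleft = CleftSpec()
        ens = release_particles(cleft, 1000, rng=0)
        r = np.hypot(ens.positions[:, 0], ens.positions[:, 1])
        assert np.all(r <= cleft.radius_um + 1e-12)
        assert np.all(np.abs(ens.positions[:, 2]) <= cleft.half_height_um + 1e-12)
        assert ens.counts()["free"] == 1000

    def test_single_particle(self):
        ens = release_particles(CleftSpec(), 1, rng=1)
        assert ens.positions.shape == (1, 3)

    def test_uniform_in_r2_and_z(self):
        """Uniform-in-cylinder sampling: r^2 and z are each uniform (KS)."""
        cleft = CleftSpec()
        ens = release_particles(cleft, 100_000, rng=2)
        r2 = (ens.positions[:, 0] ** 2 + ens.positions[:, 1] ** 2) / cleft.radius_um ** 2
        z = (ens.positions[:, 2] + cleft.half_height_um) / (2 * cleft.half_height_um)
        assert stats.kstest(r2, "uniform").pvalue > 0.01
        assert stats.kstest(z, "uniform").pvalue > 0.01

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            release_particles(CleftSpec(), 0, rng=0)


class TestBrownianStep:
    def test_zero_diffusivity_keeps_positions(self):
        pos = np.random.default_rng(0).normal(size=(100, 3))
        out = brownian_step(pos, D=0.0, dt=1e-3, rng=1)
        assert np.array_equal(out, pos)

    def test_displacement_variance_matches_2Ddt(self):
        pos = np.zeros((100_000, 3))
        D, dt = 0.5, 1e-3
        out = brownian_step(pos, D, dt, rng=3)
        var = out.var(axis=0)
        # 3 independent axes, each variance 2*D*dt = 1e-3
        assert np.allclose(var, 2 * D * dt, rtol=0.02)

    def test_free_space_msd_recovers_D(self):
        """Einstein relation on obstacle-free particles (slope/6 = D)."""
        t, msd = free_diffusion_msd(n=20_000, D=0.5, dt=1e-3, t_end=2.0,
                                    sample_interval=0.1, seed=4)
        D_hat = estimate_diffusivity(t, msd)
        assert abs(D_hat - 0.5) / 0.5 < 0.02


class TestReflections:
    def test_non_intersecting_segment_unchanged(self):
        spec = ArenaSpec(edge_um=2.0, alpha=0.9, vf_astro=0.0,
                         cleft_obstacles=False)
        env = single_sphere_environment(spec, (0.5, 0.5, 0.5), 0.2)
        old = np.array([[0.0, 0.0, 0.0]])
        prop = np.array([[0.01, -0.01, 0.02]])
        out, esc = resolve_collisions(env, old, prop)
        assert np.allclose(out, prop)
        assert not esc.any()

    def test_head_on_radial_reflection(self):
        """Head-on approach: outgoing point lies on the incoming radial line
        with the distance to the surface preserved (analytic mirror)."""
        spec = ArenaSpec(edge_um=4.0, alpha=0.9, vf_astro=0.0,
                         cleft_obstacles=False)
        env = single_sphere_environment(spec, (1.0, 0.0, 0.0), 0.2)
        old = np.array([[0.7, 0.0, 0.0]])       # 0.1 outside the surface
        prop = np.array([[0.85, 0.0, 0.0]])     # 0.05 inside
        out, _ = resolve_collisions(env, old, prop)
        assert np.allclose(out, [[0.75, 0.0, 0.0]], atol=1e-12)

    def test_oblique_reflection_preserves_path_length(self):
        spec = ArenaSpec(edge_um=4.0, alpha=0.9, vf_astro=0.0,
                         cleft_obstacles=False)
        centre, radius = np.array([1.0, 0.2, -0.1]), 0.25
        env = single_sphere_environment(spec, centre, radius)
        rng = np.random.default_rng(5)
        for _ in range(20):
            # aim from a point outside at a point inside the sphere
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            old = centre + u * (radius + 0.03)
            inside = centre + rng.standard_normal(3) * 0.05
            while np.linalg.norm(inside - centre) >= radius - 0.01:
                inside = centre + rng.standard_normal(3) * 0.05
            out, _ = resolve_collisions(env, old[None], inside[None])
            out = out[0]
            # independent oracle: entry point by quadratic root, mirror about
            # the tangent plane, compare endpoint
            d = inside - old
            oc = old - centre
            a, b, c = d @ d, 2 * oc @ d, oc @ oc - radius ** 2
            t = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
            q = old + t * d
            n = (q - centre) / radius
            rem = inside - q
            expect = q + rem - 2 * (rem @ n) * n
            assert np.allclose(out, expect, atol=1e-9)
            assert np.linalg.norm(out - centre) >= radius - 1e-9

    def test_tortuosity_reduces_effective_diffusivity(self, small_env):
        """MSD slope in a crowded arena is strictly below the free-space 6D
        (tortuosity is emergent)."""
        dspec = DiffusionSpec(t_end=0.4)
        tspec = TransporterSpec(enabled=False)
        res = simulate_run(small_env, dspec, tspec, 400,
                           record_times=[0.2, 0.4], seed_noise=6,
                           seed_events=7)
        msd = [np.mean(np.sum(p ** 2, axis=1)) for p in res.positions]
        D_eff = (msd[1] - msd[0]) / (6 * 0.2)
        assert D_eff < 0.45   # free D = 0.5; expect ~0.2-0.35 at alpha = 0.2


class TestProximity:
    def test_distances_and_cutoff(self):
        spec = ArenaSpec(edge_um=2.0, alpha=0.9, vf_astro=0.05,
                         cleft_obstacles=False)
        env = single_sphere_environment(spec, (0.0, 0.0, 0.0), 0.2,
                                        astro=True)
        pts = np.array([[0.204, 0.0, 0.0],    # 4 nm away -> contact
                        [0.206, 0.0, 0.0]])   # 6 nm away -> no contact
        contact, dist = astro_proximity(env, pts, cutoff_um=0.005)
        assert contact.tolist() == [True, False]
        assert np.allclose(dist, [0.004, 0.006], atol=1e-9)

    def test_no_astroglia_all_false(self, small_env):
        spec = ArenaSpec(edge_um=2.0, alpha=0.9, vf_astro=0.0,
                         cleft_obstacles=False)
        env = single_sphere_environment(spec, (0.3, 0.3, 0.3), 0.2,
                                        astro=False)
        pts = np.random.default_rng(0).uniform(-0.9, 0.9, (100, 3))
        contact, _ = astro_proximity(env, pts)
        assert not contact.any()


class TestBoundaries:
    def test_reflective_folds_back(self):
        pos = np.array([[2.05, 0.0, -2.2]])
        out, esc = boundary_condition(pos, edge_um=4.0, mode="reflective")
        assert np.allclose(out, [[1.95, 0.0, -1.8]])
        assert not esc.any()

    def test_open_flags_escapes(self):
        pos = np.array([[2.05, 0.0, 0.0], [0.0, 0.0, 0.0]])
        _, esc = boundary_condition(pos, edge_um=4.0, mode="open")
        assert esc.tolist() == [True, False]


class TestEnsembleInvariants:
    def test_conservation_and_no_penetration(self, small_env):
        """Particle statuses always partition N; no free particle sits deeper
        than the geometric tolerance inside any solid."""
        dspec = DiffusionSpec(t_end=1.0)
        tspec = TransporterSpec()
        res = simulate_run(small_env, dspec, tspec, 300,
                           record_times=[0.25, 0.5, 1.0], seed_noise=8,
                           seed_events=9)
        for k in range(len(res.times)):
            c = res.ensemble_at(k).counts()
            assert sum(c.values()) == 300
            free = res.positions[k][res.status[k] == 0]
            depth = (small_env.radii[None, :]
                     - np.linalg.norm(free[:, None, :]
                                      - small_env.centres[None, :, :], axis=2))
            assert depth.max() <= 2e-6

    def test_resolution_guard(self):
        with pytest.raises(ValueError, match="rms step"):
            DiffusionSpec(dt=1e-3).check_resolution(0.005)
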