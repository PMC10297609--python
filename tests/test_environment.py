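"""Probabilistic environment generation: geometry, roles, classification."""

import numpy as np
import pytest
from scipy import stats

from gluspill import (ArenaSpec, CleftSpec, EnvironmentRealisation,
                      empty_environment, estimate_volume_fractions,
                      generate_environment, point_classification,
                      single_sphere_environment)


def brute_force_classify(env, points):
    """Independent per-sphere containment oracle (deepest owner, lowest
    index on ties; hemispheric obstacles labelled 3)."""
    labels = np.zeros(len(points), dtype=int)
    z0 = env.spec.cleft.half_height_um
    rap = env.spec.cleft.apposition_radius_um
    for k, p in enumerate(points):
        if env.spec.cleft_obstacles:
            top = p[2] > z0 and p[0] ** 2 + p[1] ** 2 + (p[2] - z0) ** 2 < rap ** 2
            bot = p[2] < -z0 and p[0] ** 2 + p[1] ** 2 + (p[2] + z0) ** 2 < rap ** 2
            if top or bot:
                labels[k] = 3
                continue
        depth = env.radii - np.linalg.norm(env.centres - p, axis=1)
        if depth.size and depth.max() > 0:
            owner = int(np.argmax(depth > depth.max() - 1e-15))
            labels[k] = 2 if env.astro[owner] else 1
    return labels


class TestGeneration:
    def test_identical_seed_bit_identical(self):
        spec = ArenaSpec(edge_um=2.0, alpha=0.3, vf_astro=0.1, seed=5,
                         n_test_points=50_000)
        a = generate_environment(spec)
        b = generate_environment(spec)
        assert np.array_equal(a.centres, b.centres)
        assert np.array_equal(a.radii, b.radii)
        assert np.array_equal(a.astro, b.astro)

    def test_different_seeds_differ(self):
        kw = dict(edge_um=2.0, alpha=0.3, vf_astro=0.1, n_test_points=50_000)
        a = generate_environment(ArenaSpec(seed=1, **kw))
        b = generate_environment(ArenaSpec(seed=2, **kw))
        assert a.centres.shape != b.centres.shape or not np.allclose(
            a.centres, b.centres)

    def test_measured_fractions_near_targets(self, small_env, small_spec):
        assert abs(small_env.alpha_measured - small_spec.alpha) <= small_spec.tolerance
        assert abs(small_env.vf_astro_measured - small_spec.vf_astro) <= small_spec.tolerance

    def test_radii_uniform_on_range(self):
        """Radii follow U(50, 300) nm (KS test over >= 1e4 spheres)."""
        radii = []
        for seed in (3, 4):
            env = generate_environment(ArenaSpec(alpha=0.1, vf_astro=0.0,
                                                 seed=seed,
                                                 n_test_points=100_000))
            radii.append(env.radii)
        radii = np.concatenate(radii)
        assert radii.size >= 10_000
        p = stats.kstest(radii, stats.uniform(loc=0.05, scale=0.25).cdf).pvalue
        assert p > 0.01

    def test_cleft_gap_respected(self, small_env):
        """No spheroid surface within the minimum gap of the cleft region
        (exhaustive over all spheres)."""
        reach = small_env.spec.cleft.reach_um
        gap = small_env.spec.min_gap_nm / 1000.0
        d = np.linalg.norm(small_env.centres, axis=1) - small_env.radii
        assert np.all(d >= reach + gap - 1e-9)

    def test_unreachable_target_raises(self):
        with pytest.raises(RuntimeError, match="not reached"):
            generate_environment(ArenaSpec(edge_um=2.0, alpha=0.2,
                                           vf_astro=0.0, max_spheres=10,
                                           n_test_points=20_000))

    def test_obstacle_free_limit(self):
        spec = ArenaSpec(alpha=1.0, vf_astro=0.0, seed=0,
                         n_test_points=10_000)
        env = generate_environment(spec)
        assert env.n_spheres == 0
        assert env.alpha_measured == 1.0


class TestVolumeFractions:
    def test_empty_environment_alpha_exactly_one(self):
        env = empty_environment()
        a, v, _, _ = estimate_volume_fractions(env, 10_000, seed=0)
        assert a == 1.0
        assert v == 0.0

    def test_single_sphere_matches_analytic_volume(self):
        """alpha_hat for one fully interior sphere equals 1 - (4/3)pi r^3/L^3
        within 3 SE of the Monte Carlo test points."""
        spec = ArenaSpec(edge_um=2.0, alpha=0.9, vf_astro=0.0,
                         cleft_obstacles=False)
        r = 0.3
        env = single_sphere_environment(spec, (0.5, -0.4, 0.3), r)
        a, _, se, _ = estimate_volume_fractions(env, 1_000_000, seed=3)
        expected = 1.0 - 4.0 / 3.0 * np.pi * r ** 3 / 2.0 ** 3
        assert abs(a - expected) < 3 * se

    def test_baseline_estimate_near_target(self, small_env):
        a, v, ase, vse = estimate_volume_fractions(small_env, 200_000, seed=9)
        assert abs(a - 0.2) < 0.012
        assert abs(v - 0.1) < 0.012

    def test_invalid_n_points(self, small_env):
        with pytest.raises(ValueError):
            estimate_volume_fractions(small_env, 0, seed=0)


class TestClassification:
    def test_matches_brute_force_oracle(self, small_env):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-0.99, 0.99, size=(2000, 3))
        fast = small_env.classify(pts)
        slow = brute_force_classify(small_env, pts)
        assert np.array_equal(fast, slow)

    def test_overlap_owned_by_deepest_sphere(self):
        """A point inside both a neuronal and an astroglial sphere belongs to
        the sphere whose surface is farthest inside."""
        spec = ArenaSpec(edge_um=2.0, alpha=0.5, vf_astro=0.2,
                         cleft_obstacles=False)
        env = EnvironmentRealisation(
            spec=spec,
            centres=np.array([[0.3, 0.0, 0.0], [0.55, 0.0, 0.0]]),
            radii=np.array([0.25, 0.15]),
            astro=np.array([False, True]),
            alpha_measured=0.5, vf_astro_measured=0.2, seed_used=0)
        # point in the overlap, deeper inside sphere 0 (neuronal)
        assert point_classification(env, (0.45, 0.0, 0.0)) == "neuronal"
        # point in the overlap, deeper inside sphere 1 (astroglial)
        assert point_classification(env, (0.53, 0.0, 0.0)) == "astroglial"

    def test_corner_is_extracellular_and_obstacle_labelled(self):
        spec = ArenaSpec(alpha=1.0, vf_astro=0.0, cleft_obstacles=True)
        env = empty_environment(spec)
        corner = np.array(3 * [spec.edge_um / 2 - 1e-6])
        assert point_classification(env, corner) == "extracellular"
        # inside a hemispheric obstacle dome
        z0 = spec.cleft.half_height_um
        assert point_classification(env, (0.0, 0.0, z0 + 0.05)) == "cleft_obstacle"

    def test_outside_arena_rejected(self, small_env):
        with pytest.raises(ValueError, match="inside the arena"):
            small_env.classify(np.array([[5.0, 0.0, 0.0]]))


def test_save_load_roundtrip(tmp_path, small_env):
    path = tmp_path / "env.csv"
    small_env.save(path)
    loaded = EnvironmentRealisation.load(path)
    assert np.allclose(loaded.centres, small_env.centres)
    assert np.allclose(loaded.radii, small_env.radii)
    assert np.array_equal(loaded.astro, small_env.astro)
    assert loaded.spec.alpha == small_env.spec.alpha
    assert loaded.alpha_measured == pytest.approx(small_env.alpha_measured,
                                                  abs=1e-6)


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):
        ArenaSpec(alpha=0.5, vf_astro=0.6)
    with pytest.raises(ValueError):
        ArenaSpec(r_min_nm=300, r_max_nm=100)
    with pytest.raises(ValueError):
        ArenaSpec(edge_um=0.5)
    with pytest.raises(ValueError):
        CleftSpec(width_nm=300, apposition_nm=250)
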