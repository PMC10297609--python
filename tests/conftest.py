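"""Shared fixtures.

``small_env`` is a reduced arena (2 um edge) for fast geometric tests;
``baseline_paired`` runs the full baseline paired experiment (4 um arena,
1000 particles, 5 paired runs, 9 ms) once per session and is shared by every
test that inspects the unbinding contrast.
"""

import pytest

from gluspill import ArenaSpec, generate_environment
from gluspill.run import Condition, RunConfig, paired_conditions


@pytest.fixture(scope="session")
def small_spec():
    return ArenaSpec(edge_um=2.0, alpha=0.2, vf_astro=0.1, seed=11,
                     n_test_points=100_000)


@pytest.fixture(scope="session")
def small_env(small_spec):
    return generate_environment(small_spec)


@pytest.fixture(scope="session")
def baseline_config():
    return RunConfig(conditions=(Condition(alpha=0.2, vf_astro=0.1,
                                           unbinding="both"),),
                     n_runs=5, n_particles=1000, master_seed=1)


@pytest.fixture(scope="session")
def baseline_paired(baseline_config):
    """Paired unbinding-on/off baseline experiment (the heavy fixture)."""
    return paired_conditions(baseline_config)
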