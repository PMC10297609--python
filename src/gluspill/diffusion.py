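"""Brownian dynamics of free glutamate in the porous neuropil.

Particles are released uniformly inside the cleft cylinder, take isotropic
Gaussian steps (per-axis variance ``2 D dt``; D = 0.5 um^2/ms from in situ
measurements), reflect elastically off every solid surface, and report their
proximity to astroglial surfaces to the transporter hazard model. Tortuosity
of the extracellular space is emergent: nothing slows a particle other than
geometry.

``simulate_run`` is the fused driver used by experiments; the standalone
operations (``brownian_step``, ``resolve_collisions``, ``astro_proximity``,
``boundary_condition``) expose the same primitives individually for testing
and for small-scale exploratory work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._kernels import run_steps, resolve_many, astro_distance_many, seed_kernel_rng
from .environment import CleftSpec, EnvironmentRealisation
from .transporters import (BOUND, ESCAPED, FREE, RETAINED, TransporterBook,
                           TransporterSpec)

_MAX_CHUNK_STEPS = 8192
_NEIGH_CAP = 48


@dataclass(frozen=True)
class DiffusionSpec:
    """Diffusion parameters: D (um^2/ms), time step and horizon (ms)."""

    D: float = 0.5
    dt: float = 2e-5
    t_end: float = 9.0
    reflective_walls: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.D < 0:
            raise ValueError("need dt > 0 and D >= 0")

    @property
    def step_sigma(self) -> float:
        return float(np.sqrt(2.0 * self.D * self.dt))

    def check_resolution(self, proximity_cutoff_um: float = 0.005) -> None:
        """Guard: the rms 3D step must stay comparable to the proximity shell,
        or the 5 nm contact test becomes step-size dependent."""
        rms3d = np.sqrt(6.0 * self.D * self.dt)
        if rms3d > 2.0 * proximity_cutoff_um:
            raise ValueError(
                f"dt={self.dt} gives rms step {rms3d * 1e3:.1f} nm, above twice "
                f"the {proximity_cutoff_um * 1e3:.0f} nm proximity cutoff; "
                "reduce dt")


@dataclass
class ParticleEnsemble:
    """Positions (um) and kinetic states of all glutamate particles."""

    positions: np.ndarray
    status: np.ndarray
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def counts(self) -> dict[str, int]:
        s = self.status
        return {"free": int(np.sum(s == FREE)), "bound": int(np.sum(s == BOUND)),
                "retained": int(np.sum(s == RETAINED)),
                "escaped": int(np.sum(s == ESCAPED))}


def release_particles(cleft: CleftSpec, n: int, rng) -> ParticleEnsemble:
    """Release ``n`` particles uniformly inside the cleft cylinder at t = 0
    (uniform in r^2, angle and height)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    r = cleft.radius_um * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(-cleft.half_height_um, cleft.half_height_um, n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return ParticleEnsemble(positions=pos, status=np.zeros(n, dtype=np.int8))


def brownian_step(positions: np.ndarray, D: float, dt: float, rng) -> np.ndarray:
    """Propose isotropic Brownian displacements (per-axis variance 2 D dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    sig = np.sqrt(2.0 * D * dt)
    return positions + sig * rng.standard_normal(positions.shape)


def resolve_collisions(env: EnvironmentRealisation, old_positions: np.ndarray,
                       proposed: np.ndarray, reflective_walls: bool = True):
    """Mirror-reflect proposed steps off every solid surface.

    Old positions must be valid (outside solids). Steps are assumed small
    relative to the spatial-hash margin (~90 nm); raises if any reflection
    fails to converge, which signals an oversized time step.
    """
    old = np.ascontiguousarray(old_positions, dtype=np.float64).reshape(-1, 3)
    prop = np.ascontiguousarray(proposed, dtype=np.float64).reshape(-1, 3)
    ka = env.kernel_args()
    out = np.empty_like(old)
    codes = np.zeros(old.shape[0], dtype=np.int8)
    resolve_many(old, prop, out, codes,
                 ka["sx"], ka["sy"], ka["sz"], ka["sr"], ka["sr2"],
                 ka["cell_start"], ka["cell_items"], ka["csize"], ka["ncell"],
                 ka["half"], ka["z0"], ka["rap"], ka["rap2"], reflective_walls)
    if np.any(codes == 2):
        raise RuntimeError(
            f"{int(np.sum(codes == 2))} reflections failed to converge in 12 "
            "iterations; the time step is too large for this geometry")
    return out, codes == 1


def astro_proximity(env: EnvironmentRealisation, positions: np.ndarray,
                    cutoff_um: float = 0.005):
    """Per-particle contact test against astroglial surfaces.

    Returns ``(in_contact, distance_um)``; distances beyond the spatial-hash
    margin (~90 nm) are reported as inf, which is always out of contact.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    pts = np.ascontiguousarray(positions, dtype=np.float64).reshape(-1, 3)
    ka = env.kernel_args()
    dist = np.empty(pts.shape[0])
    astro_distance_many(pts, dist, ka["sx"], ka["sy"], ka["sz"], ka["sr"],
                        ka["astro"], ka["cell_start"], ka["cell_items"],
                        ka["csize"], ka["ncell"], ka["half"])
    return dist <= cutoff_um, dist


def boundary_condition(positions: np.ndarray, edge_um: float,
                       mode: str = "reflective"):
    """Arena-edge handling: reflective folding (default) or open walls, in
    which case out-of-bounds particles are flagged escaped."""
    pos = np.array(positions, dtype=np.float64).reshape(-1, 3)
    half = edge_um / 2.0
    if mode == "reflective":
        # single fold suffices for sub-cell steps
        over = pos > half
        pos[over] = 2 * half - pos[over]
        under = pos < -half
        pos[under] = -2 * half - pos[under]
        return pos, np.zeros(pos.shape[0], dtype=bool)
    if mode == "open":
        escaped = np.any(np.abs(pos) > half, axis=1)
        return pos, escaped
    raise ValueError(f"unknown boundary mode {mode!r}")


@dataclass
class SimulationResult:
    """Snapshots of the ensemble at the recorded times plus bookkeeping."""

    times: np.ndarray                    # recorded times (ms)
    positions: list                      # list of (N, 3) arrays
    status: list                         # list of (N,) int8 arrays
    book: TransporterBook
    counters: np.ndarray                 # [bind, release, clamp, escape] totals
    n_particles: int

    def ensemble_at(self, k: int) -> ParticleEnsemble:
        return ParticleEnsemble(positions=self.positions[k],
                                status=self.status[k], time=float(self.times[k]))


def simulate_run(env: EnvironmentRealisation, dspec: DiffusionSpec,
                 tspec: TransporterSpec, n_particles: int,
                 record_times: Sequence[float], seed_noise: int,
                 seed_events: int, unbinding: bool = True,
                 release_seed: int | None = None) -> SimulationResult:
    """Run one full release-diffusion-binding-unbinding simulation.

    ``seed_noise`` drives the pre-generated Brownian increments (shared
    between paired arms); ``seed_events`` drives binding/fate draws. With
    ``unbinding=False`` the fate draw can never select release (the
    "no unbinding" arm) while consuming the identical random stream.
    """
    dspec.check_resolution(tspec.cutoff_um)
    n = int(n_particles)
    ens = release_particles(env.spec.cleft, n,
                            np.random.SeedSequence((seed_noise, 17))
                            if release_seed is None else release_seed)
    pos = np.ascontiguousarray(ens.positions)
    status = np.zeros(n, dtype=np.int8)
    clock = np.zeros(n)
    bind_t = np.full(n, np.nan)
    rel_t = np.full(n, np.inf)
    fate = np.zeros(n, dtype=np.int8)
    nbind = np.zeros(n, dtype=np.int64)
    counters = np.zeros(4, dtype=np.int64)
    neigh = np.zeros((n, _NEIGH_CAP), dtype=np.int32)
    nblock = np.zeros((n, _NEIGH_CAP, 5))
    nn = np.zeros(n, dtype=np.int64)
    anchor = np.full((n, 3), 1e9)        # forces list build on first step
    budget = np.full(n, -1.0)
    ka = env.kernel_args()
    rc2 = (ka["sr"] + tspec.cutoff_um) ** 2
    transporters_on = bool(tspec.enabled) and bool(ka["astro"].any())
    p_unbind = tspec.p_unbind if unbinding else 0.0
    hazard = float(-np.expm1(-dspec.dt / tspec.psi_ms))

    record_times = np.asarray(sorted(record_times), dtype=float)
    rec_steps = np.unique(np.maximum(1, np.round(record_times / dspec.dt).astype(np.int64)))
    noise_rng = np.random.default_rng(np.random.SeedSequence(seed_noise))
    ev_ss = np.random.SeedSequence(seed_events)

    out_pos: list[np.ndarray] = []
    out_status: list[np.ndarray] = []
    out_t: list[float] = []
    step = 0
    chunk_idx = 0
    for target in rec_steps:
        while step < target:
            nsteps = int(min(_MAX_CHUNK_STEPS, target - step))
            gauss = noise_rng.standard_normal((nsteps, n, 3), dtype=np.float32)
            seed_kernel_rng(int(np.random.SeedSequence((seed_events, chunk_idx))
                                .generate_state(1)[0] % (2 ** 31)))
            run_steps(pos, status, clock, bind_t, rel_t, fate, nbind,
                      step * dspec.dt, nsteps, dspec.dt, dspec.step_sigma, gauss,
                      ka["sx"], ka["sy"], ka["sz"], ka["sr"], ka["sr2"], rc2,
                      ka["astro"], ka["cell_start"], ka["cell_items"],
                      ka["csize"], ka["ncell"], ka["half"],
                      ka["z0"], ka["rap"], ka["rap2"], tspec.cutoff_um,
                      hazard, p_unbind, tspec.unbind_mu_ms,
                      tspec.unbind_sigma_ms, transporters_on,
                      dspec.reflective_walls, neigh, nblock, nn, anchor,
                      budget, counters)
            step += nsteps
            chunk_idx += 1
        out_pos.append(pos.copy())
        out_status.append(status.copy())
        out_t.append(step * dspec.dt)

    book = TransporterBook(contact_clock=clock,
                           bound=(status == BOUND) | (status == RETAINED),
                           bind_time=bind_t, fate=fate, release_time=rel_t,
                           n_bindings=nbind)
    return SimulationResult(times=np.asarray(out_t), positions=out_pos,
                            status=out_status, book=book, counters=counters,
                            n_particles=n)


def dump_trajectory(result: SimulationResult, path) -> None:
    """Write recorded snapshots as a tidy CSV with fixed column order
    (t_ms, id, x_um, y_um, z_um, status)."""
    import pandas as pd

    frames = []
    for k, t in enumerate(result.times):
        pos = result.positions[k]
        frames.append(pd.DataFrame({
            "t_ms": t, "id": np.arange(result.n_particles),
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "status": result.status[k]}))
    pd.concat(frames).to_csv(path, index=False)


def free_diffusion_msd(n: int, D: float, dt: float, t_end: float,
                       sample_interval: float, seed: int):
    """Ensemble MSD of obstacle-free Brownian particles started at the origin.

    Returns ``(t, msd)`` sampled every ``sample_interval``. Vectorised over
    particles; used for the Einstein-relation check (slope of MSD = 6 D t).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sig = np.sqrt(2.0 * D * dt)
    per = max(1, int(round(sample_interval / dt)))
    nsamp = int(round(t_end / (per * dt)))
    pos = np.zeros((n, 3))
    t = np.empty(nsamp)
    msd = np.empty(nsamp)
    # between samples only the summed increment matters, so per-step draws
    # are generated in blocks and reduced immediately (identical walk, no
    # per-step python overhead)
    block = 64
    buf = np.empty((block, n, 3), dtype=np.float32)
    for k in range(nsamp):
        left = per
        while left > 0:
            m = min(block, left)
            g = buf[:m]
            rng.standard_normal(out=g, dtype=np.float32)
            pos += sig * g.sum(axis=0, dtype=np.float64)
            left -= m
        t[k] = (k + 1) * per * dt
        msd[k] = np.mean(np.einsum("ij,ij->i", pos, pos))
    return t, msd


def estimate_diffusivity(t: np.ndarray, msd: np.ndarray) -> float:
    """Einstein relation: slope of MSD(t) through the origin, divided by 6."""
    res = stats.linregress(t, msd)
    return float(res.slope / 6.0)
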