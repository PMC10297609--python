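"""Experiment orchestration: config, seed discipline, paired-condition runs.

An experiment is a list of conditions (alpha, vf_astro, unbinding arm); for
each condition and run index a fresh environment is generated, the full
release-diffusion-binding simulation executed, and shell profiles computed.
Paired unbinding-on/off arms share the environment, the release positions and
the pre-generated Brownian noise, so the contrast between arms is
variance-reduced.

Seed discipline: every random stream is derived from the master seed through
``numpy.random.SeedSequence`` keyed by (condition index, run index, stream
role), so any single run is reproducible in isolation and arms share exactly
the streams they must share.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .diffusion import DiffusionSpec, simulate_run
from .environment import ArenaSpec, CleftSpec, generate_environment
from .nmdar import KineticScheme, activation_map
from .profiles import (ProfileSeries, PsiFit, ShellGrid, average_runs,
                       fit_psi, profile_from_snapshots)
from .transporters import TransporterSpec

logger = logging.getLogger("gluspill")

__version__ = "0.1.0"

DEFAULT_RECORD_TIMES = (0.1, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 9.0)

# stream roles for seed derivation
_ROLE_ENV = 0
_ROLE_NOISE = 1
_ROLE_EVENTS = 2
_ROLE_VOLUMES = 3


@dataclass(frozen=True)
class Condition:
    alpha: float = 0.2
    vf_astro: float = 0.1
    unbinding: str = "both"        # "on" | "off" | "both"

    def arms(self) -> tuple[str, ...]:
        if self.unbinding == "both":
            return ("off", "on")
        if self.unbinding in ("on", "off"):
            return (self.unbinding,)
        raise ValueError("unbinding must be 'on', 'off' or 'both'")


@dataclass
class RunConfig:
    """Full configuration of one experiment."""

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    diffusion: DiffusionSpec = field(default_factory=DiffusionSpec)
    transporter: TransporterSpec = field(default_factory=TransporterSpec)
    conditions: tuple[Condition, ...] = (Condition(),)
    n_particles: int = 1000
    n_runs: int = 10
    scale_factor: float = 3.0
    shell_width_nm: float = 20.0
    volume_points_per_shell: int = 1000
    record_times_ms: tuple[float, ...] = DEFAULT_RECORD_TIMES
    master_seed: int = 1

    def __post_init__(self):
        self.diffusion.check_resolution(self.transporter.cutoff_um)
        for c in self.conditions:
            if c.alpha + c.vf_astro > 1.0:
                raise ValueError(
                    f"condition alpha={c.alpha} vf_astro={c.vf_astro}: "
                    "implied solid fraction exceeds 1")

    # -- presets ------------------------------------------------------------
    def with_preset(self, preset: str) -> "RunConfig":
        """'desk' (n_runs 5) or 'paper' (n_runs 10) scale."""
        if preset == "desk":
            return replace(self, n_runs=5)
        if preset == "paper":
            return replace(self, n_runs=10)
        raise ValueError("preset must be 'desk' or 'paper'")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "arena": {k: v for k, v in asdict(self.arena).items() if k != "cleft"},
            "cleft": asdict(self.arena.cleft),
            "diffusion": asdict(self.diffusion),
            "transporter": asdict(self.transporter),
            "conditions": [asdict(c) for c in self.conditions],
            "n_particles": self.n_particles, "n_runs": self.n_runs,
            "scale_factor": self.scale_factor,
            "shell_width_nm": self.shell_width_nm,
            "volume_points_per_shell": self.volume_points_per_shell,
            "record_times_ms": list(self.record_times_ms),
            "master_seed": self.master_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        arena_kw = dict(d.get("arena", {}))
        cleft = CleftSpec(**d.get("cleft", {}))
        arena = ArenaSpec(cleft=cleft, **arena_kw)
        return cls(
            arena=arena,
            diffusion=DiffusionSpec(**d.get("diffusion", {})),
            transporter=TransporterSpec(**d.get("transporter", {})),
            conditions=tuple(Condition(**c) for c in d.get("conditions",
                                                           [{}])),
            n_particles=int(d.get("n_particles", 1000)),
            n_runs=int(d.get("n_runs", 10)),
            scale_factor=float(d.get("scale_factor", 3.0)),
            shell_width_nm=float(d.get("shell_width_nm", 20.0)),
            volume_points_per_shell=int(d.get("volume_points_per_shell", 1000)),
            record_times_ms=tuple(d.get("record_times_ms",
                                        DEFAULT_RECORD_TIMES)),
            master_seed=int(d.get("master_seed", 1)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def derive_seed(master: int, cond: int, run: int, role: int) -> int:
    """Deterministic sub-stream seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(cond, run, role))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ConditionResult:
    """Per-arm averaged profiles (and per-run series) for one condition."""

    condition: Condition
    arms: dict                       # arm -> AveragedProfiles
    runs: dict                       # arm -> list[ProfileSeries]
    env_stats: list                  # per-run (alpha_measured, vf_measured)


def run_condition(config: RunConfig, cond_idx: int,
                  keep_runs: bool = True) -> ConditionResult:
    """Generate n_runs fresh environments and simulate every arm in each."""
    cond = config.conditions[cond_idx]
    grid = ShellGrid.for_arena(config.arena.edge_um,
                               config.shell_width_nm / 1000.0)
    series: dict[str, list[ProfileSeries]] = {a: [] for a in cond.arms()}
    env_stats = []
    for run_idx in range(config.n_runs):
        spec = replace(config.arena, alpha=cond.alpha, vf_astro=cond.vf_astro,
                       seed=derive_seed(config.master_seed, cond_idx, run_idx,
                                        _ROLE_ENV))
        env = generate_environment(spec)
        env_stats.append((env.alpha_measured, env.vf_astro_measured))
        noise = derive_seed(config.master_seed, cond_idx, run_idx, _ROLE_NOISE)
        events = derive_seed(config.master_seed, cond_idx, run_idx, _ROLE_EVENTS)
        vol_seed = derive_seed(config.master_seed, cond_idx, run_idx, _ROLE_VOLUMES)
        for arm in cond.arms():
            t_arm = time.time()
            result = simulate_run(env, config.diffusion, config.transporter,
                                  config.n_particles, config.record_times_ms,
                                  seed_noise=noise, seed_events=events,
                                  unbinding=(arm == "on"))
            tallies = "; ".join(
                f"t={t:g}ms {result.ensemble_at(k).counts()}"
                for k, t in enumerate(result.times))
            logger.info("condition %d run %d arm %s: %.1fs, env alpha=%.3f "
                        "vf=%.3f | %s", cond_idx, run_idx, arm,
                        time.time() - t_arm, env.alpha_measured,
                        env.vf_astro_measured, tallies)
            series[arm].append(profile_from_snapshots(
                result, env, grid, scale_factor=config.scale_factor,
                n_per_shell=config.volume_points_per_shell,
                volume_seed=vol_seed))
    arms = {a: average_runs(s) for a, s in series.items()}
    return ConditionResult(condition=cond, arms=arms,
                           runs=series if keep_runs else {},
                           env_stats=env_stats)


def paired_conditions(config: RunConfig, cond_idx: int = 0) -> ConditionResult:
    """Run the unbinding-on and unbinding-off arms with shared environments,
    release positions and Brownian noise (paired seeds)."""
    cond = config.conditions[cond_idx]
    if cond.unbinding != "both":
        config = replace(config, conditions=tuple(
            replace(c, unbinding="both") if i == cond_idx else c
            for i, c in enumerate(config.conditions)))
    return run_condition(config, cond_idx)


def run_experiment(config: RunConfig, outdir: str | Path) -> dict:
    """Run every condition, write tidy CSV outputs and a manifest.

    Per condition and arm: a per-run tidy table and an aggregated mean/SEM
    table. The manifest records the config, seeds, wall time and the output
    inventory; identical config + master seed reproduce identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "status": "running",
        "outputs": [],
        "seeds": {},
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    t0 = time.time()
    results = {}
    for ci, cond in enumerate(config.conditions):
        res = run_condition(config, ci)
        results[ci] = res
        tag = f"c{ci}_a{cond.alpha}_vf{cond.vf_astro}"
        for arm, avg in res.arms.items():
            agg = outdir / f"profiles_{tag}_unbind_{arm}_aggregated.csv"
            avg.to_frame().to_csv(agg, index=False)
            runs_df = pd.concat([s.to_frame(run=i)
                                 for i, s in enumerate(res.runs[arm])])
            raw = outdir / f"profiles_{tag}_unbind_{arm}_runs.csv"
            runs_df.to_csv(raw, index=False)
            manifest["outputs"] += [agg.name, raw.name]
        manifest["seeds"][f"condition_{ci}"] = {
            f"run_{r}": {"env": derive_seed(config.master_seed, ci, r, _ROLE_ENV),
                         "noise": derive_seed(config.master_seed, ci, r, _ROLE_NOISE),
                         "events": derive_seed(config.master_seed, ci, r, _ROLE_EVENTS)}
            for r in range(config.n_runs)}
    manifest["status"] = "complete"
    manifest["wall_time_s"] = round(time.time() - t0, 2)
    man_path.write_text(json.dumps(manifest, indent=2))
    return results


def unbinding_activation_ratio(result: ConditionResult,
                               scheme: KineticScheme | None = None,
                               r_lo_um: float = 0.5, r_hi_um: float = 1.0,
                               t_end_ms: float = 300.0):
    """Peak NMDAR activation (open probability) with vs without transporter
    unbinding, averaged over shells between ``r_lo_um`` and ``r_hi_um``.

    Returns ``(ratio, peaks_on, peaks_off, distances)``.
    """
    if scheme is None:
        scheme = KineticScheme.from_file()
    avg_on = result.arms["on"]
    avg_off = result.arms["off"]
    mids = avg_on.grid.mids_um
    dists = mids[(mids >= r_lo_um) & (mids <= r_hi_um)]
    _, _, met_on = activation_map(avg_on, scheme, dists, t_end_ms=t_end_ms)
    _, _, met_off = activation_map(avg_off, scheme, dists, t_end_ms=t_end_ms)
    peaks_on = np.array([m.peak_open_prob for m in met_on])
    peaks_off = np.array([m.peak_open_prob for m in met_off])
    ratio = float(peaks_on.mean() / peaks_off.mean())
    return ratio, peaks_on, peaks_off, dists


def simulate_bound_profile(config: RunConfig, psi_ms: float, t_eval_ms: float,
                           seed_offset: int = 0):
    """Averaged bound-glutamate spatial profile at ``t_eval_ms`` for a given
    Psi (the quantity the Psi calibration compares against a reference).

    Returns ``(r_mid_nm, bound_mM_mean)``.
    """
    tspec = replace(config.transporter, psi_ms=psi_ms)
    cfg = replace(config, transporter=tspec,
                  record_times_ms=(t_eval_ms,),
                  master_seed=config.master_seed + seed_offset)
    res = run_condition(cfg, 0)
    arm = cfg.conditions[0].arms()[-1]
    avg = res.arms[arm]
    return avg.grid.mids_um * 1000.0, avg.mean_bound_mM[0]


def calibrate_psi(config: RunConfig, reference: pd.DataFrame,
                  psi_grid: Sequence[float] = (0.1, 0.32, 1.0, 3.2, 10.0),
                  t_eval_ms: float = 4.0, seed_offset: int = 0) -> PsiFit:
    """Grid-search Psi between 0.1 and 10 ms against a reference bound
    profile at 4 ms post-release."""
    return fit_psi(reference,
                   lambda psi: simulate_bound_profile(config, psi, t_eval_ms,
                                                      seed_offset),
                   psi_grid=psi_grid)


def synthetic_reference_profile(config: RunConfig, psi_true_ms: float = 1.0,
                                t_eval_ms: float = 4.0, seed_offset: int = 1000,
                                r_max_nm: float = 1500.0) -> pd.DataFrame:
    """Synthetic stand-in for an experimental bound-glutamate spatial profile.

    Simulates the bound profile at ``psi_true_ms`` with an independent seed
    set and returns it as a (distance_nm, signal) table normalised to unit
    peak -- the shape a fluorescence reporter of bound glutamate would see.
    """
    r_nm, prof = simulate_bound_profile(config, psi_true_ms, t_eval_ms,
                                        seed_offset)
    sel = r_nm <= r_max_nm
    prof = np.nan_to_num(prof[sel])
    peak = prof.max()
    return pd.DataFrame({"distance_nm": r_nm[sel],
                         "signal": prof / peak if peak > 0 else prof})
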