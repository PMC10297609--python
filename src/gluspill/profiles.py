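"""Concentration profiles in concentric shells and Psi calibration.

Particle snapshots are binned into 20 nm thick concentric shells centred at
the release site. Per-shell extracellular volumes are estimated by Monte
Carlo (uniform points inside each shell classified by the environment), and
absolute concentrations follow from particle counts, Avogadro's number and a
vesicle scale factor (1000 simulated particles x 3 emulate a ~3000-molecule
vesicle). Profiles are averaged across environment realisations (mean +/-
SEM), and the transporter binding time constant Psi is calibrated by a grid
search against a reference bound-glutamate spatial profile at 4 ms
post-release, both profiles normalised to unit peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .environment import EXTRACELLULAR, EnvironmentRealisation
from .transporters import BOUND, FREE, RETAINED

#: conversion: particles per um^3 -> mM  (1 um^3 = 1e-15 L)
_COUNT_PER_UM3_TO_MM = 1.0 / (Avogadro * 1e-15) * 1e3


@dataclass(frozen=True)
class ShellGrid:
    """Concentric shells [k*w, (k+1)*w) around the release site.

    By default the grid extends to the arena's corner radius so that every
    in-arena particle falls in exactly one shell and counts are conserved.
    """

    shell_width_um: float = 0.02
    n_shells: int = 174

    @classmethod
    def for_arena(cls, edge_um: float, shell_width_um: float = 0.02) -> "ShellGrid":
        n = int(np.ceil(edge_um * np.sqrt(3.0) / 2.0 / shell_width_um))
        return cls(shell_width_um=shell_width_um, n_shells=n)

    @property
    def edges_um(self) -> np.ndarray:
        return np.arange(self.n_shells + 1) * self.shell_width_um

    @property
    def mids_um(self) -> np.ndarray:
        return (np.arange(self.n_shells) + 0.5) * self.shell_width_um

    def full_volumes_um3(self) -> np.ndarray:
        e = self.edges_um
        return 4.0 / 3.0 * np.pi * (e[1:] ** 3 - e[:-1] ** 3)


def shell_counts(positions: np.ndarray, status: np.ndarray, grid: ShellGrid):
    """Tally free and bound particles per shell by distance from the origin.

    Transporter-bound particles on the translocation path count as bound:
    within the simulated window they have not been released or taken up.
    Returns ``(free_counts, bound_counts)``; escaped particles are excluded.
    """
    r = np.linalg.norm(positions, axis=1)
    idx = np.minimum((r / grid.shell_width_um).astype(np.int64), grid.n_shells - 1)
    free = np.bincount(idx[status == FREE], minlength=grid.n_shells)
    bound_mask = (status == BOUND) | (status == RETAINED)
    bound = np.bincount(idx[bound_mask], minlength=grid.n_shells)
    return free, bound


def shell_ec_volumes(env: EnvironmentRealisation, grid: ShellGrid,
                     n_per_shell: int = 1000, seed: int = 0) -> np.ndarray:
    """Monte Carlo extracellular volume of each shell (um^3).

    Uniform points are drawn inside each shell (uniform in volume); points
    outside the arena or inside any solid do not count. The shell EC volume is
    the analytic shell volume times the extracellular point fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edges = grid.edges_um
    half = env.spec.edge_um / 2.0
    u = rng.random((grid.n_shells, n_per_shell))
    radii = np.cbrt(edges[:-1, None] ** 3
                    + u * (edges[1:, None] ** 3 - edges[:-1, None] ** 3))
    vec = rng.standard_normal((grid.n_shells, n_per_shell, 3))
    vec /= np.linalg.norm(vec, axis=2, keepdims=True)
    pts = radii[..., None] * vec
    flat = pts.reshape(-1, 3)
    inside = np.all(np.abs(flat) <= half, axis=1)
    frac_ec = np.zeros(grid.n_shells * n_per_shell)
    if inside.any():
        labels = env.classify(flat[inside])
        frac_ec[inside] = labels == EXTRACELLULAR
    frac = frac_ec.reshape(grid.n_shells, n_per_shell).mean(axis=1)
    return grid.full_volumes_um3() * frac


def to_concentration(counts: np.ndarray, ec_volumes_um3: np.ndarray,
                     scale_factor: float = 3.0) -> np.ndarray:
    """Convert per-shell particle counts to mM.

    ``conc = scale * count / (N_A * V_ec)``. Shells with zero extracellular
    volume but non-zero counts are flagged NaN rather than dropped.
    """
    counts = np.asarray(counts, dtype=float)
    vol = np.asarray(ec_volumes_um3, dtype=float)
    counts, vol = np.broadcast_arrays(counts, vol)
    ok = vol > 0
    out = np.where(ok, scale_factor * counts / np.where(ok, vol, 1.0)
                   * _COUNT_PER_UM3_TO_MM,
                   np.where(counts == 0, 0.0, np.nan))
    return out


@dataclass
class ProfileSeries:
    """Free/bound concentration profiles for one run: (time, shell) arrays."""

    times_ms: np.ndarray
    grid: ShellGrid
    free_mM: np.ndarray          # (n_times, n_shells)
    bound_mM: np.ndarray
    free_counts: np.ndarray
    bound_counts: np.ndarray
    ec_volumes_um3: np.ndarray   # (n_shells,)
    scale_factor: float = 3.0

    def to_frame(self, run: int | None = None) -> pd.DataFrame:
        e = self.grid.edges_um
        t, k = np.meshgrid(self.times_ms, np.arange(self.grid.n_shells),
                           indexing="ij")
        df = pd.DataFrame({
            "t_ms": t.ravel(),
            "r_lo_nm": (e[:-1] * 1000)[k.ravel()],
            "r_hi_nm": (e[1:] * 1000)[k.ravel()],
            "free_mM": self.free_mM.ravel(),
            "bound_mM": self.bound_mM.ravel(),
            "free_count": self.free_counts.ravel().astype(int),
            "bound_count": self.bound_counts.ravel().astype(int),
            "ec_vol_um3": np.tile(self.ec_volumes_um3, self.times_ms.size),
        })
        if run is not None:
            df.insert(0, "run", run)
        return df


@dataclass
class AveragedProfiles:
    """Across-run mean and SEM of free/bound concentration profiles."""

    times_ms: np.ndarray
    grid: ShellGrid
    mean_free_mM: np.ndarray
    sem_free_mM: np.ndarray
    mean_bound_mM: np.ndarray
    sem_bound_mM: np.ndarray
    n_runs: int

    def glu_timecourse(self, distance_um: float, kind: str = "free"):
        """Glutamate concentration time course at the shell containing
        ``distance_um`` (input for the NMDAR kinetics)."""
        k = int(distance_um / self.grid.shell_width_um)
        if not 0 <= k < self.grid.n_shells:
            raise ValueError("distance outside the shell grid")
        conc = self.mean_free_mM if kind == "free" else self.mean_bound_mM
        return self.times_ms, conc[:, k]

    def to_frame(self) -> pd.DataFrame:
        t, k = np.meshgrid(self.times_ms, np.arange(self.grid.n_shells),
                           indexing="ij")
        return pd.DataFrame({
            "t_ms": t.ravel(),
            "r_mid_nm": (self.grid.mids_um * 1000)[k.ravel()],
            "mean_free_mM": self.mean_free_mM.ravel(),
            "sem_free_mM": self.sem_free_mM.ravel(),
            "mean_bound_mM": self.mean_bound_mM.ravel(),
            "sem_bound_mM": self.sem_bound_mM.ravel(),
        })


def profile_from_snapshots(result, env: EnvironmentRealisation,
                           grid: ShellGrid | None = None,
                           scale_factor: float = 3.0,
                           n_per_shell: int = 1000,
                           volume_seed: int = 0) -> ProfileSeries:
    """Build a ProfileSeries from one SimulationResult."""
    if grid is None:
        grid = ShellGrid.for_arena(env.spec.edge_um)
    ec = shell_ec_volumes(env, grid, n_per_shell=n_per_shell, seed=volume_seed)
    nt = result.times.size
    fc = np.zeros((nt, grid.n_shells), dtype=np.int64)
    bc = np.zeros((nt, grid.n_shells), dtype=np.int64)
    for k in range(nt):
        fc[k], bc[k] = shell_counts(result.positions[k], result.status[k], grid)
    return ProfileSeries(times_ms=result.times, grid=grid,
                         free_mM=to_concentration(fc, ec, scale_factor),
                         bound_mM=to_concentration(bc, ec, scale_factor),
                         free_counts=fc, bound_counts=bc,
                         ec_volumes_um3=ec, scale_factor=scale_factor)


def average_runs(series: Sequence[ProfileSeries]) -> AveragedProfiles:
    """Pointwise mean and SEM across runs (independent realisations)."""
    if len(series) < 2:
        raise ValueError("need at least two runs to average")
    g0 = series[0].grid
    t0 = series[0].times_ms
    for s in series[1:]:
        if s.grid != g0 or not np.array_equal(s.times_ms, t0):
            raise ValueError("runs have mismatched grids or time points")
    free = np.stack([s.free_mM for s in series])
    bound = np.stack([s.bound_mM for s in series])
    n = len(series)
    with warnings.catch_warnings():
        # shells flagged NaN in every run (zero measured EC volume) stay NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        return AveragedProfiles(
            times_ms=t0, grid=g0,
            mean_free_mM=np.nanmean(free, axis=0),
            sem_free_mM=np.nanstd(free, axis=0, ddof=1) / np.sqrt(n),
            mean_bound_mM=np.nanmean(bound, axis=0),
            sem_bound_mM=np.nanstd(bound, axis=0, ddof=1) / np.sqrt(n),
            n_runs=n)


@dataclass
class PsiFit:
    """Result of the Psi grid search."""

    best_psi_ms: float
    psi_grid: np.ndarray
    discrepancy: np.ndarray   # sum of squared differences per grid value


def fit_psi(reference_profile: pd.DataFrame,
            sim_factory: Callable[[float], tuple[np.ndarray, np.ndarray]],
            psi_grid: Sequence[float] = (0.1, 0.32, 1.0, 3.2, 10.0),
            ) -> PsiFit:
    """Calibrate Psi against a reference spatial profile of bound glutamate.

    ``reference_profile`` is a two-column table (distance_nm, signal);
    ``sim_factory(psi)`` must return ``(r_mid_nm, bound_profile)`` for the
    simulated bound glutamate at the evaluation time (4 ms by default in the
    experiment driver). Both profiles are normalised to unit peak (only the
    shape is comparable between a fluorescence and a concentration profile)
    and compared by least squares over the overlapping distance range.
    """
    ref_d = np.asarray(reference_profile.iloc[:, 0], dtype=float)
    ref_s = np.asarray(reference_profile.iloc[:, 1], dtype=float)
    if ref_d.size < 3:
        raise ValueError("reference profile needs at least 3 points")
    peak = np.nanmax(ref_s)
    if peak <= 0:
        raise ValueError("reference profile has no positive signal")
    ref_s = ref_s / peak
    psi_grid = np.asarray(psi_grid, dtype=float)
    disc = np.empty(psi_grid.size)
    for i, psi in enumerate(psi_grid):
        r_nm, prof = sim_factory(float(psi))
        prof = np.asarray(prof, dtype=float)
        pmax = np.nanmax(prof)
        prof = prof / pmax if pmax > 0 else prof
        lo = max(ref_d.min(), np.min(r_nm))
        hi = min(ref_d.max(), np.max(r_nm))
        sel = (ref_d >= lo) & (ref_d <= hi)
        if sel.sum() < 3:
            raise ValueError("simulated and reference distance ranges do not overlap")
        interp = np.interp(ref_d[sel], r_nm, np.nan_to_num(prof))
        disc[i] = float(np.sum((interp - ref_s[sel]) ** 2))
    best = psi_grid[int(np.argmin(disc))]
    return PsiFit(best_psi_ms=float(best), psi_grid=psi_grid, discrepancy=disc)


def load_reference_profile(path: str | Path) -> pd.DataFrame:
    """Read a two-column reference profile CSV (distance_nm, signal)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("reference profile must have two columns")
    return df
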