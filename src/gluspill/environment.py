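"""Probabilistic synaptic environment generation and validation.

The perisynaptic neuropil is modelled as a random scatter of overlapping
spheroids inside a cubic arena, each spheroid assigned a neuronal or an
astroglial role, with a small cylindrical synaptic cleft at the arena centre
flanked by two hemispheric obstacles (the pre- and postsynaptic elements).
The voids between spheroids form the tortuous extracellular space with volume
fraction alpha; astroglial spheroids carry the glutamate transporters and
occupy volume fraction ``vf_astro`` of the tissue. A fresh environment is
generated for every simulation run, and its volume fractions are validated by
uniform Monte Carlo test points.

Internal units are micrometres; configuration values quoted in nanometres are
converted at the dataclass boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from ._geom import (ASTROGLIAL, CLEFT_OBSTACLE, EXTRACELLULAR, NEURONAL,
                    SphereGrid, classify_kernel)

LABEL_NAMES = {EXTRACELLULAR: "extracellular", NEURONAL: "neuronal",
               ASTROGLIAL: "astroglial", CLEFT_OBSTACLE: "cleft_obstacle"}


@dataclass(frozen=True)
class CleftSpec:
    """Synaptic cleft geometry: a 120 nm wide, 20 nm high cylindrical release
    volume at the arena centre, inside a wider synaptic apposition zone capped
    by two hemispheric obstacles of ``apposition_nm`` diameter."""

    width_nm: float = 120.0
    height_nm: float = 20.0
    apposition_nm: float = 250.0

    def __post_init__(self):
        if not (self.height_nm < self.width_nm <= self.apposition_nm):
            raise ValueError("cleft requires height < width <= apposition diameter")

    @property
    def radius_um(self) -> float:
        return self.width_nm / 2000.0

    @property
    def half_height_um(self) -> float:
        return self.height_nm / 2000.0

    @property
    def apposition_radius_um(self) -> float:
        return self.apposition_nm / 2000.0

    @property
    def reach_um(self) -> float:
        """Maximum distance from the release site reached by the cleft slab or
        either hemispheric obstacle."""
        return self.half_height_um + self.apposition_radius_um


@dataclass(frozen=True)
class ArenaSpec:
    """Specification of one stochastic neuropil arena."""

    edge_um: float = 4.0
    alpha: float = 0.2
    vf_astro: float = 0.1
    r_min_nm: float = 50.0
    r_max_nm: float = 300.0
    min_gap_nm: float = 10.0
    cleft: CleftSpec = field(default_factory=CleftSpec)
    cleft_obstacles: bool = True
    tolerance: float = 0.01
    n_test_points: int = 200_000
    max_spheres: int = 60_000
    max_role_iter: int = 60
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if not (0.0 <= self.vf_astro < 1.0):
            raise ValueError("vf_astro must be in [0, 1)")
        if self.alpha + self.vf_astro > 1.0 + 1e-12:
            raise ValueError("alpha + vf_astro must not exceed 1")
        if not (self.r_min_nm < self.r_max_nm):
            raise ValueError("radius range requires r_min < r_max")
        if self.edge_um <= 2.0 * self.r_max_nm / 1000.0:
            raise ValueError("arena edge must exceed twice the maximum radius")


@dataclass
class EnvironmentRealisation:
    """One stochastic realisation of the synaptic neuropil.

    ``centres``/``radii`` are in micrometres with the release site at the
    origin; ``astro`` flags astroglial spheroids. Measured fractions come from
    the generation-time Monte Carlo test points.
    """

    spec: ArenaSpec
    centres: np.ndarray
    radii: np.ndarray
    astro: np.ndarray
    alpha_measured: float
    vf_astro_measured: float
    seed_used: int
    _grid: SphereGrid | None = None

    @property
    def n_spheres(self) -> int:
        return int(self.radii.shape[0])

    @property
    def grid(self) -> SphereGrid:
        if self._grid is None:
            self._grid = SphereGrid(self.centres, self.radii, self.spec.edge_um)
        return self._grid

    def kernel_args(self):
        """Flat array bundle consumed by the numba kernels."""
        g = self.grid
        c = self.centres
        z0, rap = self._obstacle_geom()
        return dict(
            sx=np.ascontiguousarray(c[:, 0]), sy=np.ascontiguousarray(c[:, 1]),
            sz=np.ascontiguousarray(c[:, 2]),
            # inside tests use a 1e-6 um geometric tolerance so a point placed
            # numerically on a surface by a reflection does not re-trigger it
            sr=self.radii, sr2=np.maximum(self.radii - 1e-6, 0.0) ** 2,
            astro=self.astro.astype(np.uint8),
            cell_start=g.cell_start, cell_items=g.cell_items,
            csize=g.csize, ncell=g.ncell, half=g.half,
            z0=z0, rap=rap, rap2=(rap - 1e-6) ** 2 if rap > 0 else -1.0,
        )

    def _obstacle_geom(self) -> Tuple[float, float]:
        if not self.spec.cleft_obstacles:
            return 0.0, -1.0
        return self.spec.cleft.half_height_um, self.spec.cleft.apposition_radius_um

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Classify points as extracellular(0) / neuronal(1) / astroglial(2) /
        cleft obstacle(3) under the deepest-containment ownership rule."""
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        half = self.spec.edge_um / 2.0
        if np.any(np.abs(points) > half + 1e-12):
            raise ValueError("points must lie inside the arena")
        ka = self.kernel_args()
        labels = np.empty(points.shape[0], dtype=np.int8)
        owners = np.empty(points.shape[0], dtype=np.int64)
        classify_kernel(np.ascontiguousarray(points[:, 0]),
                        np.ascontiguousarray(points[:, 1]),
                        np.ascontiguousarray(points[:, 2]),
                        ka["sx"], ka["sy"], ka["sz"], ka["sr"], ka["astro"],
                        ka["cell_start"], ka["cell_items"], ka["csize"],
                        ka["ncell"], ka["half"], ka["z0"], ka["rap2"],
                        labels, owners)
        return labels

    def save(self, path: str | Path) -> None:
        """CSV dump: header lines with the spec and measured fractions, then
        one row per spheroid (x, y, z in um, radius in um, role)."""
        path = Path(path)
        s = self.spec
        header = [
            "# gluspill environment realisation",
            f"# edge_um={s.edge_um} alpha={s.alpha} vf_astro={s.vf_astro}",
            f"# r_min_nm={s.r_min_nm} r_max_nm={s.r_max_nm} min_gap_nm={s.min_gap_nm}",
            f"# cleft_width_nm={s.cleft.width_nm} cleft_height_nm={s.cleft.height_nm} "
            f"apposition_nm={s.cleft.apposition_nm} cleft_obstacles={int(s.cleft_obstacles)}",
            f"# alpha_measured={self.alpha_measured:.6f} "
            f"vf_astro_measured={self.vf_astro_measured:.6f} seed={self.seed_used}",
        ]
        df = pd.DataFrame({
            "x_um": self.centres[:, 0], "y_um": self.centres[:, 1],
            "z_um": self.centres[:, 2], "radius_um": self.radii,
            "role": np.where(self.astro, "astroglial", "neuronal"),
        })
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, index=False)

    @staticmethod
    def load(path: str | Path) -> "EnvironmentRealisation":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            n_header += 1
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        df = pd.read_csv(path, skiprows=n_header)
        spec = ArenaSpec(
            edge_um=float(meta["edge_um"]), alpha=float(meta["alpha"]),
            vf_astro=float(meta["vf_astro"]), r_min_nm=float(meta["r_min_nm"]),
            r_max_nm=float(meta["r_max_nm"]), min_gap_nm=float(meta["min_gap_nm"]),
            cleft=CleftSpec(width_nm=float(meta["cleft_width_nm"]),
                            height_nm=float(meta["cleft_height_nm"]),
                            apposition_nm=float(meta["apposition_nm"])),
            cleft_obstacles=bool(int(meta.get("cleft_obstacles", "1"))),
            seed=int(meta["seed"]))
        return EnvironmentRealisation(
            spec=spec,
            centres=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=np.float64),
            radii=df["radius_um"].to_numpy(dtype=np.float64),
            astro=(df["role"] == "astroglial").to_numpy(),
            alpha_measured=float(meta["alpha_measured"]),
            vf_astro_measured=float(meta["vf_astro_measured"]),
            seed_used=int(meta["seed"]))


def _coverage_update(px, py, pz, covered, cx, cy, cz, r):
    """Mark generation test points falling inside a new sphere. Vectorised
    with a bounding-box prefilter; returns nothing (in-place)."""
    m = (np.abs(px - cx) < r)
    if not m.any():
        return
    idx = np.nonzero(m)[0]
    dy = py[idx] - cy
    dz = pz[idx] - cz
    m2 = (np.abs(dy) < r) & (np.abs(dz) < r)
    idx = idx[m2]
    if idx.size == 0:
        return
    dx = px[idx] - cx
    d2 = dx * dx + (py[idx] - cy) ** 2 + (pz[idx] - cz) ** 2
    covered[idx[d2 < r * r]] = True


def generate_environment(spec: ArenaSpec) -> EnvironmentRealisation:
    """Generate one stochastic neuropil realisation.

    Spheroid centres are sampled uniformly in the arena box inflated by the
    maximum radius (so coverage is spatially stationary up to the walls), with
    radii uniform on [r_min, r_max]; candidates intruding within the minimum
    gap of the cleft region are rejected. Spheres are added until the running
    Monte Carlo estimate of the extracellular fraction first reaches the
    target. Roles are then assigned by independent Bernoulli draws whose
    probability is iteratively corrected until the measured astroglial
    fraction is within tolerance of the target.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    half = spec.edge_um / 2.0
    r_min = spec.r_min_nm / 1000.0
    r_max = spec.r_max_nm / 1000.0
    half_inflated = half + r_max
    excl = spec.cleft.reach_um + spec.min_gap_nm / 1000.0 if spec.cleft_obstacles else 0.0

    pts = rng.uniform(-half, half, size=(spec.n_test_points, 3))
    px, py, pz = pts[:, 0].copy(), pts[:, 1].copy(), pts[:, 2].copy()
    covered = np.zeros(spec.n_test_points, dtype=bool)
    target_covered = 1.0 - spec.alpha

    cxs: list[float] = []
    cys: list[float] = []
    czs: list[float] = []
    rs: list[float] = []
    n_cov = 0
    n_pts = spec.n_test_points
    while n_cov / n_pts < target_covered:
        if len(rs) >= spec.max_spheres:
            raise RuntimeError(
                f"extracellular fraction target alpha={spec.alpha} not reached "
                f"after {spec.max_spheres} spheres (measured "
                f"{1 - n_cov / n_pts:.3f}); the radius range or arena may make "
                "the target unreachable")
        c = rng.uniform(-half_inflated, half_inflated, size=3)
        r = rng.uniform(r_min, r_max)
        if excl > 0.0 and np.sqrt(c @ c) < r + excl:
            continue  # would intrude on the cleft region
        cxs.append(c[0])
        cys.append(c[1])
        czs.append(c[2])
        rs.append(r)
        _coverage_update(px, py, pz, covered, c[0], c[1], c[2], r)
        n_cov = int(covered.sum())

    centres = np.column_stack([cxs, cys, czs]) if rs else np.zeros((0, 3))
    radii = np.asarray(rs, dtype=np.float64)
    alpha_measured = 1.0 - n_cov / n_pts

    # --- role assignment ---------------------------------------------------
    n_sph = radii.shape[0]
    astro = np.zeros(n_sph, dtype=bool)
    vf_measured = 0.0
    if spec.vf_astro > 0.0 and n_sph > 0:
        grid = SphereGrid(centres, radii, spec.edge_um)
        labels = np.empty(n_pts, dtype=np.int8)
        owners = np.empty(n_pts, dtype=np.int64)
        z0 = spec.cleft.half_height_um if spec.cleft_obstacles else 0.0
        rap = spec.cleft.apposition_radius_um if spec.cleft_obstacles else -1.0
        classify_kernel(px, py, pz,
                        np.ascontiguousarray(centres[:, 0]),
                        np.ascontiguousarray(centres[:, 1]),
                        np.ascontiguousarray(centres[:, 2]),
                        radii, astro.astype(np.uint8),
                        grid.cell_start, grid.cell_items, grid.csize,
                        grid.ncell, grid.half, z0,
                        rap * rap if rap > 0 else -1.0, labels, owners)
        owned = owners[owners >= 0]
        p = min(0.95, spec.vf_astro / max(1e-9, 1.0 - spec.alpha))
        ok = False
        for _ in range(spec.max_role_iter):
            astro = rng.random(n_sph) < p
            vf_measured = float(astro[owned].mean()) * owned.size / n_pts
            if abs(vf_measured - spec.vf_astro) <= spec.tolerance:
                ok = True
                break
            p = min(0.95, max(1e-6, p * spec.vf_astro / max(1e-9, vf_measured)))
        if not ok:
            raise RuntimeError(
                f"astroglial fraction target {spec.vf_astro} not met within "
                f"tolerance {spec.tolerance} after {spec.max_role_iter} "
                f"role-assignment iterations (last measured {vf_measured:.4f})")

    env = EnvironmentRealisation(spec=spec, centres=centres, radii=radii,
                                 astro=astro, alpha_measured=alpha_measured,
                                 vf_astro_measured=vf_measured,
                                 seed_used=spec.seed)
    return env


def estimate_volume_fractions(env: EnvironmentRealisation, n_points: int,
                              seed: int) -> tuple[float, float, float, float]:
    """Monte Carlo re-estimate of (alpha, vf_astro) with fresh uniform test
    points; returns ``(alpha_hat, vf_hat, alpha_se, vf_se)``."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half = env.spec.edge_um / 2.0
    pts = rng.uniform(-half, half, size=(n_points, 3))
    labels = env.classify(pts)
    alpha_hat = float(np.mean(labels == EXTRACELLULAR))
    vf_hat = float(np.mean(labels == ASTROGLIAL))
    alpha_se = float(np.sqrt(alpha_hat * (1 - alpha_hat) / n_points))
    vf_se = float(np.sqrt(vf_hat * (1 - vf_hat) / n_points))
    return alpha_hat, vf_hat, alpha_se, vf_se


def point_classification(env: EnvironmentRealisation, position) -> str:
    """Classify a single position; returns one of 'extracellular', 'neuronal',
    'astroglial', 'cleft_obstacle'."""
    label = env.classify(np.asarray(position, dtype=float).reshape(1, 3))[0]
    return LABEL_NAMES[int(label)]


def single_sphere_environment(spec: ArenaSpec, centre, radius_um: float,
                              astro: bool = False) -> EnvironmentRealisation:
    """Deterministic single-sphere realisation (testing / analytic checks)."""
    centre = np.asarray(centre, dtype=np.float64).reshape(1, 3)
    vol = 4.0 / 3.0 * np.pi * radius_um ** 3 / spec.edge_um ** 3
    return EnvironmentRealisation(
        spec=spec, centres=centre, radii=np.array([radius_um]),
        astro=np.array([astro]), alpha_measured=1.0 - vol,
        vf_astro_measured=vol if astro else 0.0, seed_used=spec.seed)


def empty_environment(spec: ArenaSpec | None = None) -> EnvironmentRealisation:
    """Obstacle-free realisation (alpha = 1)."""
    if spec is None:
        spec = ArenaSpec(alpha=1.0, vf_astro=0.0, cleft_obstacles=False)
    return EnvironmentRealisation(
        spec=spec, centres=np.zeros((0, 3)), radii=np.zeros(0),
        astro=np.zeros(0, dtype=bool), alpha_measured=1.0,
        vf_astro_measured=0.0, seed_used=spec.seed)
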