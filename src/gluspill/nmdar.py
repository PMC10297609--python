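"""Five-state NMDA receptor kinetics driven by simulated glutamate.

The scheme has unbound (U), single-bound (C1), double-bound closed (C2),
desensitised (D) and open (O) states; glutamate concentration enters the two
binding transitions linearly. Occupancies follow the linear (in state) ODE
system with the time-varying concentration, integrated to 1e-8 accuracy.

The "tagging" metric: a receptor with both binding sites occupied (C2 or O by
default) can open on depolarisation without further glutamate. The default
double-occupancy readout therefore sums C2 + O; the desensitised state, while
doubly liganded, cannot open and is excluded unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import solve_ivp

STATES = ("U", "C1", "C2", "D", "O")
IDX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants of the 5-state scheme (per ms; kon per mM per ms)."""

    kon: float = 5.0
    koff: float = 0.0129
    k_desens: float = 0.0084
    k_resens: float = 0.0068
    k_open: float = 0.0465
    k_close: float = 0.0738
    source: str = "nmda5 (Destexhe, Mainen & Sejnowski 1994/1998)"

    def __post_init__(self):
        for name in ("kon", "koff", "k_desens", "k_resens", "k_open", "k_close"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "KineticScheme":
        """Load rates from a YAML parameter file (the packaged default set
        when ``path`` is None)."""
        if path is None:
            text = (resources.files("gluspill") / "data" / "nmdar_5state.yaml").read_text()
            source = "nmda5 (packaged default)"
        else:
            text = Path(path).read_text()
            source = str(path)
        doc = yaml.safe_load(text)
        r = doc["rates"]
        return cls(kon=float(r["kon_per_mM_ms"]), koff=float(r["koff_per_ms"]),
                   k_desens=float(r["k_desens_per_ms"]),
                   k_resens=float(r["k_resens_per_ms"]),
                   k_open=float(r["k_open_per_ms"]),
                   k_close=float(r["k_close_per_ms"]), source=source)

    def generator(self, glu_mM: float) -> np.ndarray:
        """Markov generator Q at fixed [glu]; columns sum to zero, so
        d(occupancy)/dt = Q @ occupancy conserves probability."""
        c = float(glu_mM)
        Q = np.zeros((5, 5))

        def add(src: str, dst: str, rate: float) -> None:
            i, j = IDX[src], IDX[dst]
            Q[j, i] += rate
            Q[i, i] -= rate

        add("U", "C1", self.kon * c)
        add("C1", "U", self.koff)
        add("C1", "C2", self.kon * c)
        add("C2", "C1", self.koff)
        add("C2", "D", self.k_desens)
        add("D", "C2", self.k_resens)
        add("C2", "O", self.k_open)
        add("O", "C2", self.k_close)
        return Q

    def stationary(self, glu_mM: float) -> np.ndarray:
        """Stationary occupancy at fixed [glu] by null-space linear algebra."""
        Q = self.generator(glu_mM)
        _, _, vh = np.linalg.svd(Q)
        v = np.abs(vh[-1])
        return v / v.sum()


@dataclass
class GluTimecourse:
    """Glutamate concentration (mM) at a fixed distance from the release site.

    Beyond the last simulated time the concentration is extended with zero
    (default) or held at its last value, so slow receptor kinetics can be
    integrated far past the simulated transient.
    """

    t_ms: np.ndarray
    conc_mM: np.ndarray
    extend: str = "zero"

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.conc_mM = np.nan_to_num(np.asarray(self.conc_mM, dtype=float))
        if np.any(self.conc_mM < 0):
            raise ValueError("concentration must be non-negative")
        if self.extend not in ("zero", "hold"):
            raise ValueError("extend must be 'zero' or 'hold'")

    def __call__(self, t):
        tail = self.conc_mM[-1] if self.extend == "hold" else 0.0
        return np.interp(t, self.t_ms, self.conc_mM, left=0.0, right=tail)


@dataclass
class NMDARTrajectory:
    """State occupancies over time plus the glutamate drive used."""

    t_ms: np.ndarray
    occupancy: np.ndarray      # (n_times, 5) in STATES order
    scheme: KineticScheme

    @property
    def open_prob(self) -> np.ndarray:
        return self.occupancy[:, IDX["O"]]

    def double_occupancy(self, include_desensitised: bool = False) -> np.ndarray:
        d = self.occupancy[:, IDX["C2"]] + self.occupancy[:, IDX["O"]]
        if include_desensitised:
            d = d + self.occupancy[:, IDX["D"]]
        return d


def simulate_nmdar(scheme: KineticScheme, glu: GluTimecourse,
                   t_end_ms: float = 300.0, tol: float = 1e-8,
                   n_eval: int = 3001) -> NMDARTrajectory:
    """Integrate the receptor ODEs under the given glutamate transient.

    Starts from U = 1, integrates to ``t_end_ms`` with relative and absolute
    tolerance ``tol`` (1e-8); occupancies stay in [0, 1] and sum to one within
    ten times the tolerance.
    """
    t_eval = np.linspace(0.0, t_end_ms, n_eval)

    def rhs(t, p):
        return scheme.generator(glu(t)) @ p

    p0 = np.zeros(5)
    p0[IDX["U"]] = 1.0
    sol = solve_ivp(rhs, (0.0, t_end_ms), p0, t_eval=t_eval, method="LSODA",
                    rtol=tol, atol=tol, max_step=1.0)
    if not sol.success:
        raise RuntimeError(f"NMDAR ODE integration failed: {sol.message}")
    return NMDARTrajectory(t_ms=sol.t, occupancy=sol.y.T, scheme=scheme)


@dataclass
class ActivationMetrics:
    peak_open_prob: float
    peak_double_occupancy: float
    tag_duration_ms: float


def activation_metrics(traj: NMDARTrajectory, threshold_fraction: float = 0.05,
                       include_desensitised: bool = False) -> ActivationMetrics:
    """Peak open probability, peak double occupancy, and tag duration.

    Tag duration is the length of the maximal contiguous interval on which
    double occupancy stays at or above ``threshold_fraction`` of its peak.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    docc = traj.double_occupancy(include_desensitised)
    peak_d = float(docc.max())
    peak_o = float(traj.open_prob.max())
    if peak_d <= 0.0:
        return ActivationMetrics(0.0, 0.0, 0.0)
    above = docc >= threshold_fraction * peak_d
    best = 0.0
    start = None
    t = traj.t_ms
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            best = max(best, t[i - 1] - t[start])
            start = None
    if start is not None:
        best = max(best, t[-1] - t[start])
    return ActivationMetrics(peak_open_prob=peak_o, peak_double_occupancy=peak_d,
                             tag_duration_ms=float(best))


def activation_map(averaged, scheme: KineticScheme,
                   distances_um, t_end_ms: float = 300.0,
                   extend: str = "zero"):
    """Drive the receptor scheme with the averaged free-glutamate transient at
    each requested distance (shell midpoints) and collect trajectories.

    Returns ``(distances_um, trajectories, metrics)`` with lists parallel to
    the distances.
    """
    trajectories = []
    metrics = []
    for d in distances_um:
        t, c = averaged.glu_timecourse(float(d), kind="free")
        glu = GluTimecourse(t_ms=t, conc_mM=c, extend=extend)
        traj = simulate_nmdar(scheme, glu, t_end_ms=t_end_ms)
        trajectories.append(traj)
        metrics.append(activation_metrics(traj))
    return np.asarray(list(distances_um), dtype=float), trajectories, metrics
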