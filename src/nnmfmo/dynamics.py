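"""Microcanonical anharmonic dynamics on the elastic network.

A chosen normal mode is excited with total energy E0 and the equations
of motion are integrated with velocity Verlet at a 1 fs step (no
thermostat, no friction).  Per-node total energies — kinetic plus half
of every incident bond's potential energy — are recorded at the sampling
stride; designated probe coordinates are recorded at every step for
spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .modes import NormalModeSet
from .network import ElasticNetwork, edge_energies, potential_energy
from .units import TIME_UNIT_FS

DEFAULT_DT_FS = 1.0


@dataclass
class ExcitationSpec:
    """How the network is kicked into a normal mode.

    ``mode_from_top`` counts from the top of the spectrum (0 = highest
    frequency).  The default protocol puts all of E0 into kinetic energy
    along the mode's displacement pattern; the displacement protocol
    stretches along the pattern until the anharmonic potential equals
    E0.  ``perturbation`` adds a seeded random velocity component of the
    given relative RMS magnitude (total energy is rescaled back to E0),
    used to break exact symmetries that would otherwise survive in exact
    arithmetic.
    """

    mode_from_top: int = 0
    e0: float = 40.0  # kcal/mol
    protocol: str = "velocity_kick"  # or "displacement"
    sign: int = 1
    seed: int = 0
    perturbation: float = 0.0

    def __post_init__(self):
        if self.e0 <= 0:
            raise ValueError("excitation energy E0 must be positive")
        if self.protocol not in ("velocity_kick", "displacement"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be ±1")


def excite(
    network: ElasticNetwork, modes: NormalModeSet, spec: ExcitationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (positions, velocities) with total energy exactly E0."""
    k = modes.from_top(spec.mode_from_top)
    pattern = modes.mode_displacements(k)  # (N, d), Cartesian

    x = network.positions0.copy()
    v = np.zeros_like(x)
    if spec.protocol == "velocity_kick":
        # mass-weighted eigenvector is unit norm, so KE = e0 c²/2 with
        # v = c·pattern ⇒ c = sqrt(2 E0)
        v = spec.sign * np.sqrt(2.0 * spec.e0) * pattern
        if spec.perturbation > 0:
            rng = np.random.default_rng(spec.seed)
            rms = np.sqrt(np.mean(v**2))
            v = v + spec.perturbation * rms * rng.standard_normal(v.shape)
            ke = 0.5 * np.sum(network.masses[:, None] * v**2)
            v *= np.sqrt(spec.e0 / ke)
    else:
        from scipy.optimize import brentq

        def pot(a):
            return potential_energy(network, network.positions0 + a * pattern)

        a_hi = 1.0
        while pot(a_hi) < spec.e0:
            a_hi *= 2.0
        a = brentq(lambda a: pot(a) - spec.e0, 0.0, a_hi, xtol=1e-12)
        x = network.positions0 + spec.sign * a * pattern
        if spec.perturbation > 0:
            rng = np.random.default_rng(spec.seed)
            x = x + spec.perturbation * a * rng.standard_normal(x.shape) * np.abs(
                pattern
            ).max()
    return x, v


@dataclass
class Trajectory:
    """Sampled states plus dense probe traces.

    Full positions/velocities are stored every ``stride`` steps; the
    coordinates named in ``probes`` (node, component) are stored at
    every integrator step for high-resolution spectra.
    """

    times_fs: np.ndarray  # (S,) sample times
    positions: np.ndarray  # (S, N, d)
    velocities: np.ndarray  # (S, N, d)
    dt_fs: float
    stride: int
    probes: list[tuple[int, int]] = field(default_factory=list)
    probe_times_fs: np.ndarray | None = None  # (n_steps + 1,)
    probe_traces: np.ndarray | None = None  # (n_steps + 1, n_probes)
    total_energy: np.ndarray | None = None  # (S,)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.times_fs)


def total_energy(network: ElasticNetwork, x: np.ndarray, v: np.ndarray) -> float:
    ke = 0.5 * np.sum(network.masses[:, None] * v**2)
    return float(ke + potential_energy(network, x))


def integrate(
    state: tuple[np.ndarray, np.ndarray],
    network: ElasticNetwork,
    n_steps: int,
    dt_fs: float = DEFAULT_DT_FS,
    stride: int = 100,
    probes: list[tuple[int, int]] | None = None,
    drift_abort: float = 0.05,
) -> Trajectory:
    """Velocity-Verlet integration for ``n_steps`` steps of ``dt_fs``.

    Microcanonical and symplectic; aborts with a diagnostic if total
    energy drifts by more than ``drift_abort`` relative to its initial
    value (checked at every sample).
    """
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    x = np.array(state[0], dtype=float)
    v = np.array(state[1], dtype=float)
    probes = probes or []
    dt = dt_fs / TIME_UNIT_FS

    # flat views and precomputed edge arrays for the inner loop
    m = network.masses[:, None]
    ei = network.edges[:, 0]
    ej = network.edges[:, 1]
    shifts = network.edge_shifts
    r0 = network.r0
    k2, k4 = network.k2, network.k4

    n_nodes, dim = x.shape

    def force(xx):
        d = xx[ej] - xx[ei] + shifts
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        xdev = r - r0
        coef = (k2 * xdev + k4 * xdev**3) / r
        fe = coef[:, None] * d
        out = np.empty_like(xx)
        for c in range(dim):
            out[:, c] = np.bincount(ei, fe[:, c], n_nodes) - np.bincount(
                ej, fe[:, c], n_nodes
            )
        return out

    n_samples = n_steps // stride + 1
    S_times = np.empty(n_samples)
    S_x = np.empty((n_samples, *x.shape))
    S_v = np.empty((n_samples, *v.shape))
    S_e = np.empty(n_samples)
    if probes:
        p_nodes = np.array([p[0] for p in probes])
        p_comps = np.array([p[1] for p in probes])
        P = np.empty((n_steps + 1, len(probes)))
        P[0] = x[p_nodes, p_comps]
    e0 = total_energy(network, x, v)
    S_times[0], S_x[0], S_v[0], S_e[0] = 0.0, x, v, e0

    a = force(x) / m
    isample = 1
    for step in range(1, n_steps + 1):
        x += v * dt + 0.5 * a * dt * dt
        a_new = force(x) / m
        v += 0.5 * (a + a_new) * dt
        a = a_new
        if probes:
            P[step] = x[p_nodes, p_comps]
        if step % stride == 0:
            e = total_energy(network, x, v)
            S_times[isample] = step * dt_fs
            S_x[isample], S_v[isample], S_e[isample] = x, v, e
            isample += 1
            if abs(e - e0) > drift_abort * max(abs(e0), 1e-12):
                raise RuntimeError(
                    f"energy blow-up at step {step}: E = {e:.6g} vs E0 = {e0:.6g}"
                    " — reduce the time step"
                )

    return Trajectory(
        times_fs=S_times[:isample],
        positions=S_x[:isample],
        velocities=S_v[:isample],
        dt_fs=dt_fs,
        stride=stride,
        probes=list(probes),
        probe_times_fs=np.arange(n_steps + 1) * dt_fs if probes else None,
        probe_traces=P if probes else None,
        total_energy=S_e[:isample],
        meta={"n_steps": n_steps, "drift_abort": drift_abort},
    )


@dataclass
class EnergyTimeSeries:
    """Per-node total energies at the trajectory's sampling stride."""

    times_fs: np.ndarray  # (S,)
    node_energy: np.ndarray  # (S, N) kcal/mol

    @property
    def totals(self) -> np.ndarray:
        return self.node_energy.sum(axis=1)

    def group_totals(self, group_index: np.ndarray, n_groups=None) -> np.ndarray:
        """(S, n_groups) energies summed over a node grouping."""
        n_groups = n_groups or int(np.max(group_index)) + 1
        out = np.zeros((self.node_energy.shape[0], n_groups))
        for g in range(n_groups):
            out[:, g] = self.node_energy[:, group_index == g].sum(axis=1)
        return out

    def node_subset_total(self, nodes: np.ndarray) -> np.ndarray:
        return self.node_energy[:, nodes].sum(axis=1)

    def time_average(self, t_start_fs: float = 0.0, t_end_fs=None) -> np.ndarray:
        """Per-node mean energy over a time window."""
        t_end_fs = t_end_fs if t_end_fs is not None else self.times_fs[-1]
        sel = (self.times_fs >= t_start_fs) & (self.times_fs <= t_end_fs)
        if not sel.any():
            raise ValueError("window contains no samples")
        return self.node_energy[sel].mean(axis=0)


def node_energies(traj: Trajectory, network: ElasticNetwork) -> EnergyTimeSeries:
    """Kinetic plus half-bond potential energy per node per sample.

    The half-bond convention splits each spring's energy equally between
    its endpoints, so node energies sum exactly to the total energy.
    """
    S, N = traj.positions.shape[0], network.n_nodes
    E = np.empty((S, N))
    m = network.masses
    for s in range(S):
        ke = 0.5 * m * np.sum(traj.velocities[s] ** 2, axis=1)
        ve = edge_energies(network, traj.positions[s])
        pe = np.zeros(N)
        np.add.at(pe, network.edges[:, 0], 0.5 * ve)
        np.add.at(pe, network.edges[:, 1], 0.5 * ve)
        E[s] = ke + pe
    return EnergyTimeSeries(times_fs=traj.times_fs.copy(), node_energy=E)
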