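"""Harmonic normal modes of the elastic network.

The Hessian of the pair potential at the equilibrium geometry gets only
harmonic (k2) contributions — the quartic term has zero curvature at
x = 0 — so each contact contributes the familiar elastic-network block
k2·(û ûᵀ) along the bond direction.  The mass-weighted Hessian is
diagonalised densely; frequencies are reported in cm⁻¹ and amplitude
shares are squared components of the mass-weighted eigenvectors, which
sum to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .network import ElasticNetwork
from .units import omega_to_cm1

#: frequencies below this (cm⁻¹) are classified as rigid-body modes
ZERO_MODE_THRESHOLD_CM1 = 0.1


def hessian(network: ElasticNetwork, mass_weighted: bool = True) -> np.ndarray:
    """Assemble the (dN × dN) Hessian at the equilibrium geometry.

    With ``mass_weighted`` the blocks are divided by sqrt(m_i m_j); its
    eigenvalues are then squared angular frequencies in internal units.
    """
    n, dim = network.n_nodes, network.dim
    if np.any(network.masses <= 0):
        raise ValueError("all node masses must be positive")
    H = np.zeros((n * dim, n * dim))
    d = network.bond_vectors(network.positions0)
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    for (i, j), ue in zip(network.edges, u):
        block = network.k2 * np.outer(ue, ue)
        si, sj = slice(dim * i, dim * i + dim), slice(dim * j, dim * j + dim)
        H[si, si] += block
        H[sj, sj] += block
        H[si, sj] -= block
        H[sj, si] -= block
    if mass_weighted:
        w = np.repeat(np.sqrt(network.masses), dim)
        H /= np.outer(w, w)
    return H


@dataclass
class NormalModeSet:
    """Eigenpairs of the mass-weighted Hessian, ascending in frequency.

    ``eigenvectors[:, k]`` is the orthonormal mass-weighted mode k; its
    squared entries, summed per node, are that node's amplitude share.
    """

    frequencies_cm1: np.ndarray  # (dN,) ascending
    eigenvectors: np.ndarray  # (dN, dN), columns
    masses: np.ndarray  # (N,)
    dim: int
    zero_threshold_cm1: float = ZERO_MODE_THRESHOLD_CM1

    @property
    def n_nodes(self) -> int:
        return len(self.masses)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm1)

    @property
    def band_edge_cm1(self) -> float:
        """Top of the harmonic spectrum."""
        return float(self.frequencies_cm1[-1])

    @property
    def n_rigid(self) -> int:
        return int(np.sum(self.frequencies_cm1 < self.zero_threshold_cm1))

    def from_top(self, k: int) -> int:
        """Index of the k-th highest-frequency mode (k = 0 is the top)."""
        if not 0 <= k < self.n_modes:
            raise IndexError(f"mode {k} from top out of range")
        return self.n_modes - 1 - k

    def mode_displacements(self, mode_index: int) -> np.ndarray:
        """Cartesian (un-mass-weighted) displacement pattern, (N, d)."""
        v = self.eigenvectors[:, mode_index].reshape(self.n_nodes, self.dim)
        return v / np.sqrt(self.masses)[:, None]


def normal_modes(network_or_hessian, masses=None, dim=None) -> NormalModeSet:
    """Diagonalise the mass-weighted Hessian.

    Accepts an ElasticNetwork, or a prebuilt mass-weighted Hessian with
    explicit ``masses`` and ``dim``.  Eigenvalues significantly below
    zero mean the input geometry is not an energy minimum and raise.
    """
    if isinstance(network_or_hessian, ElasticNetwork):
        net = network_or_hessian
        H = hessian(net)
        masses, dim = net.masses, net.dim
    else:
        H = np.asarray(network_or_hessian, dtype=float)
        if masses is None or dim is None:
            raise ValueError("masses and dim are required with a raw Hessian")
        masses = np.asarray(masses, dtype=float)
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hessian is not symmetric")
    evals, evecs = scipy.linalg.eigh(H)
    tol = 1e-8 * max(evals.max(), 1.0)
    if evals[0] < -tol:
        raise ValueError(
            f"negative Hessian eigenvalue {evals[0]:.3e}: not at equilibrium"
        )
    freqs = omega_to_cm1(np.sqrt(np.clip(evals, 0.0, None)))
    return NormalModeSet(
        frequencies_cm1=freqs, eigenvectors=evecs, masses=masses, dim=int(dim)
    )


def mode_node_shares(modes: NormalModeSet, mode_index: int) -> np.ndarray:
    """Per-node fraction of squared amplitude of one mode (sums to 1)."""
    v = modes.eigenvectors[:, mode_index]
    shares = (v.reshape(modes.n_nodes, modes.dim) ** 2).sum(axis=1)
    return shares / shares.sum()


def group_shares(shares: np.ndarray, group_index: np.ndarray, n_groups=None):
    """Sum per-node shares over groups (monomers, pigments...)."""
    n_groups = n_groups or int(group_index.max()) + 1
    out = np.zeros(n_groups)
    np.add.at(out, group_index, shares)
    return out


def degree_share_profile(network: ElasticNetwork, modes: NormalModeSet, top_k: int):
    """Node degree vs mean amplitude share over the ``top_k`` highest modes.

    Returns a DataFrame (node, degree, mean_share) — the profile behind
    the observation that high-frequency modes sit on highly connected
    nodes.
    """
    import pandas as pd

    if top_k > modes.n_modes:
        raise ValueError("top_k exceeds number of modes")
    idx = np.arange(modes.n_modes - top_k, modes.n_modes)
    share_mat = np.stack([mode_node_shares(modes, k) for k in idx])
    return pd.DataFrame(
        {
            "node": np.arange(network.n_nodes),
            "degree": network.degrees(),
            "mean_share": share_mat.mean(axis=0),
        }
    )


def highest_nondegenerate_mode(
    modes: NormalModeSet, min_gap_cm1: float = 0.5
) -> int:
    """Index of the highest mode separated from both neighbours.

    Symmetric structures carry degenerate pairs at the top of the band;
    analyses that rely on a unique mode (e.g. equal-share checks on a C3
    trimer) use the highest frequency that is isolated by at least
    ``min_gap_cm1`` from its neighbours.
    """
    f = modes.frequencies_cm1
    for k in range(modes.n_modes - 1, 0, -1):
        above_ok = k == modes.n_modes - 1 or f[k + 1] - f[k] >= min_gap_cm1
        below_ok = f[k] - f[k - 1] >= min_gap_cm1
        if above_ok and below_ok:
            return k
    raise ValueError("no isolated mode found")


def project_mode_energies(
    modes: NormalModeSet,
    network: ElasticNetwork,
    positions: np.ndarray,
    velocities: np.ndarray,
) -> np.ndarray:
    """Harmonic energy in every mode for a given phase-space state.

    Uses mass-weighted mode coordinates Q_k = v_kᵀ·(√m (x - x0)) and
    momenta; exact for k4 = 0 and small displacements, diagnostic
    otherwise.
    """
    sq = np.repeat(np.sqrt(network.masses), network.dim)
    dx = (np.asarray(positions) - network.positions0).ravel() * sq
    dv = np.asarray(velocities).ravel() * sq
    Q = modes.eigenvectors.T @ dx
    P = modes.eigenvectors.T @ dv
    from .units import cm1_to_omega

    omega = cm1_to_omega(modes.frequencies_cm1)
    return 0.5 * (P**2 + (omega * Q) ** 2)
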