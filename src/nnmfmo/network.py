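"""Anharmonic elastic network: contact topology, potential energy, forces.

Every node pair closer than the cutoff R_c in the equilibrium (t = 0)
geometry is connected by a spring with pair potential

    v(r) = (k2/2) (r - R0)**2 + (k4/4) (r - R0)**4

where R0 is the equilibrium separation, so the network is at a global
potential-energy minimum in its input geometry.  The contact set is
frozen at t = 0 and never updated during dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import CoarseStructure

#: study defaults: cutoff (Å) and force constants (kcal/mol/Å², kcal/mol/Å⁴)
DEFAULT_R_CUT = 10.0
DEFAULT_K2 = 10.0
DEFAULT_K4 = 10.0


@dataclass
class ElasticNetwork:
    """Node set plus contact springs with (k2, k4) force constants.

    ``positions0`` is (N, d) with d = 3 for structures and d = 1 for
    model chains.  ``edge_shifts`` holds a per-edge image offset added to
    the bond vector, used to close periodic model chains; it is zero for
    networks built from structures.
    """

    positions0: np.ndarray  # (N, d) equilibrium coordinates, Å
    masses: np.ndarray  # (N,) amu
    edges: np.ndarray  # (E, 2) int, i < j
    r0: np.ndarray  # (E,) equilibrium bond lengths, Å
    k2: float
    k4: float
    r_cut: float
    edge_shifts: np.ndarray | None = None  # (E, d) Å
    structure: CoarseStructure | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions0 = np.atleast_2d(np.asarray(self.positions0, dtype=float))
        self.masses = np.asarray(self.masses, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if self.edge_shifts is None:
            self.edge_shifts = np.zeros((len(self.edges), self.dim))
        else:
            self.edge_shifts = np.asarray(self.edge_shifts, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.positions0.shape[0]

    @property
    def dim(self) -> int:
        return self.positions0.shape[1]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        """Number of contacts each node makes."""
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def bond_vectors(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        return coords[self.edges[:, 1]] - coords[self.edges[:, 0]] + self.edge_shifts

    def to_edge_table(self):
        """Tabular edge list (i, j, R0) for serialisation."""
        import pandas as pd

        return pd.DataFrame(
            {"i": self.edges[:, 0], "j": self.edges[:, 1], "r0": self.r0}
        )


def build_network(
    structure: CoarseStructure | np.ndarray,
    r_cut: float = DEFAULT_R_CUT,
    k2: float = DEFAULT_K2,
    k4: float = DEFAULT_K4,
    masses: np.ndarray | None = None,
) -> ElasticNetwork:
    """Connect every node pair strictly closer than ``r_cut``.

    Accepts a CoarseStructure or a raw (N, d) coordinate array (then
    ``masses`` defaults to 110 amu per node).  Uses a k-d tree for the
    neighbour search; the edge set is identical to the all-pairs rule
    ``dist(i, j) < r_cut``.
    """
    if isinstance(structure, CoarseStructure):
        coords = structure.positions
        masses = structure.masses
        struct_ref = structure
    else:
        coords = np.atleast_2d(np.asarray(structure, dtype=float))
        if masses is None:
            masses = np.full(coords.shape[0], 110.0)
        struct_ref = None
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 nodes to build a network")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_cut, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)
        keep = d < r_cut  # strict: ties at exactly R_c are not contacts
        pairs, d = pairs[keep], d[keep]
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, d = pairs[order], d[order]
    else:
        pairs = np.empty((0, 2), dtype=int)
        d = np.empty(0)

    return ElasticNetwork(
        positions0=coords,
        masses=np.asarray(masses, dtype=float),
        edges=pairs,
        r0=d,
        k2=k2,
        k4=k4,
        r_cut=r_cut,
        structure=struct_ref,
    )


def _check_coords(network: ElasticNetwork, coords: np.ndarray) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape != network.positions0.shape:
        raise ValueError(
            f"coords shape {coords.shape} != network shape {network.positions0.shape}"
        )
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    return coords


def edge_energies(network: ElasticNetwork, coords: np.ndarray) -> np.ndarray:
    """Potential energy of every spring, kcal/mol."""
    coords = _check_coords(network, coords)
    r = np.linalg.norm(network.bond_vectors(coords), axis=1)
    x = r - network.r0
    return 0.5 * network.k2 * x**2 + 0.25 * network.k4 * x**4


def potential_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Total potential energy, kcal/mol; zero at the input geometry."""
    return float(edge_energies(network, coords).sum())


def forces(network: ElasticNetwork, coords: np.ndarray) -> np.ndarray:
    """Force -∇V on every node, kcal/mol/Å, shape (N, d)."""
    coords = _check_coords(network, coords)
    d = network.bond_vectors(coords)
    r = np.linalg.norm(d, axis=1)
    x = r - network.r0
    # dv/dr per edge; bonds at exactly zero length carry no direction
    fmag = network.k2 * x + network.k4 * x**3
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r[:, None] > 0, d / np.where(r == 0, 1.0, r)[:, None], 0.0)
    f_edge = fmag[:, None] * u  # force on node i (pulls i toward j when x > 0)
    out = np.zeros_like(coords)
    np.add.at(out, network.edges[:, 0], f_edge)
    np.add.at(out, network.edges[:, 1], -f_edge)
    return out
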