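"""Synthetic fixtures: anharmonic chains, C3 toy trimers, toy PDB files
and small exciton systems.

These generators provide every input the pipeline needs for testing
without downloading a structure: 1-D FPU-type chains whose harmonic band
structure is known in closed form, C3-symmetric toy trimers that share
the symmetry properties of the real trimeric complex, minimal PDB
serialisations to exercise the coarse-graining path, and few-site
exciton systems with analytically known vibronic spectra.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ElasticNetwork
from .structure import PIGMENT_ATOMS, CoarseNode, CoarseStructure
from .units import omega_to_cm1
from .vibronic import ExcitonSystem


@dataclass
class FpuChainSpec:
    """A 1-D anharmonic chain — the classic discrete-breather testbed."""

    n_nodes: int = 64
    spacing: float = 5.0  # Å
    k2: float = 10.0
    k4: float = 10.0
    mass: float = 110.0  # amu
    boundary: str = "periodic"  # or "free"

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("chain needs at least 2 nodes")
        if min(self.spacing, self.k2, self.mass) <= 0 or self.k4 < 0:
            raise ValueError("spacing, k2 and mass must be positive; k4 ≥ 0")
        if self.boundary not in ("free", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")


def make_fpu_chain(spec: FpuChainSpec) -> ElasticNetwork:
    """Nearest-neighbour chain with equilibrium lengths equal to spacing.

    Positions are genuinely one-dimensional (shape (N, 1)).  A periodic
    chain is closed by a wrap edge carrying an image shift, so the
    analytic monatomic dispersion ω_k = 2√(k2/m)·|sin(πk/N)| holds
    exactly.
    """
    n, s = spec.n_nodes, spec.spacing
    positions = (np.arange(n) * s)[:, None]
    edges = [(i, i + 1) for i in range(n - 1)]
    shifts = [[0.0]] * (n - 1)
    if spec.boundary == "periodic":
        edges.append((0, n - 1))
        shifts.append([-n * s])  # image of node n-1 one period to the left
    return ElasticNetwork(
        positions0=positions,
        masses=np.full(n, spec.mass),
        edges=np.array(edges),
        r0=np.full(len(edges), s),
        k2=spec.k2,
        k4=spec.k4,
        r_cut=1.5 * s,
        edge_shifts=np.array(shifts),
        meta={"generator": "fpu_chain", "spec": vars(spec).copy()},
    )


def chain_dispersion_cm1(spec: FpuChainSpec) -> np.ndarray:
    """Analytic harmonic frequencies of the periodic chain, ascending (cm⁻¹)."""
    k = np.arange(spec.n_nodes)
    omega = 2.0 * math.sqrt(spec.k2 / spec.mass) * np.abs(
        np.sin(math.pi * k / spec.n_nodes)
    )
    return omega_to_cm1(np.sort(omega))


def chain_band_edge_cm1(spec: FpuChainSpec) -> float:
    """Top of the harmonic band, sqrt(4 k2 / m), in cm⁻¹."""
    return omega_to_cm1(math.sqrt(4.0 * spec.k2 / spec.mass))


@dataclass
class ToyTrimerSpec:
    """Three identical random monomer blobs related by exact 120° rotations.

    ``core_nodes`` sit on the rotation axis and contact all three
    monomers, mimicking the shielded core of the trimeric complex.
    """

    nodes_per_monomer: int = 20
    core_nodes: int = 3
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    seed: int = 0
    monomer_radius: float = 7.0  # Å, blob centre distance from the axis
    blob_sigma: float = 2.5  # Å, spread of nodes about the blob centre
    min_distance: float = 3.0  # Å, closest allowed node pair in a monomer
    core_spacing: float = 4.0  # Å, spacing of core nodes along the axis
    node_mass: float = 110.0

    def __post_init__(self):
        if self.nodes_per_monomer < 1 or self.core_nodes < 0:
            raise ValueError("invalid node counts")
        if np.linalg.norm(self.rotation_axis) < 1e-12:
            raise ValueError("degenerate rotation axis")


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def make_c3_trimer(spec: ToyTrimerSpec) -> CoarseStructure:
    """C3-symmetric toy structure: 3 rotated monomer copies plus a core.

    The three monomers are byte-identical copies rotated by exactly
    0/120/240° about the axis, so the node-position set is invariant
    under the 120° rotation (up to the monomer-label permutation) and
    the network Hessian commutes with the corresponding permutation-
    rotation operator.
    """
    rng = np.random.default_rng(spec.seed)
    # one monomer blob centred off-axis, with a minimum-distance rejection
    # so no accidental near-contact dominates the stiffness
    centre = np.array([spec.monomer_radius, 0.0, 0.0])
    pts: list[np.ndarray] = []
    while len(pts) < spec.nodes_per_monomer:
        cand = centre + rng.normal(0.0, spec.blob_sigma, 3)
        if all(np.linalg.norm(cand - p) >= spec.min_distance for p in pts):
            pts.append(cand)
    monomer = np.array(pts)

    axis = np.asarray(spec.rotation_axis, dtype=float)
    # build in the frame where the axis is z, then rotate the whole
    # structure so exact 120° copies stay exact
    frame = np.eye(3)
    z = axis / np.linalg.norm(axis)
    if not np.allclose(z, [0, 0, 1]):
        x = np.cross([0.0, 0.0, 1.0], z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        frame = np.column_stack([x, y, z])

    nodes: list[CoarseNode] = []

    def add(position, monomer_label, label):
        nodes.append(
            CoarseNode(
                index=len(nodes),
                position=frame @ position,
                mass=spec.node_mass,
                monomer=monomer_label,
                kind="residue",
                source_label=label,
            )
        )

    rot120 = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 2.0 * math.pi / 3.0)
    block = monomer
    for mono_i, mono_label in enumerate(["M1", "M2", "M3"]):
        for k, p in enumerate(block):
            add(p, mono_label, f"GLY {k + 1}")
        block = block @ rot120.T
    z0 = -0.5 * (spec.core_nodes - 1) * spec.core_spacing
    for k in range(spec.core_nodes):
        add(
            np.array([0.0, 0.0, z0 + k * spec.core_spacing]),
            "core",
            f"GLY {spec.nodes_per_monomer + k + 1}",
        )

    return CoarseStructure(
        nodes=nodes,
        provenance={"generator": "c3_trimer", "seed": spec.seed,
                    "spec": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in vars(spec).items()}},
    )


def write_toy_pdb(structure: CoarseStructure, path) -> None:
    """Serialise a coarse structure as a minimal fixed-column PDB file.

    Residue nodes become CA ATOM records; pigment nodes become HETATM
    records whose residue/atom names are taken from their source labels
    (e.g. "BCL 900 / MG"), so the file round-trips through the
    coarse-graining reader.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    monomers = structure.monomers
    chain_of = {m: chr(ord("A") + i) for i, m in enumerate(monomers)}
    lines = []
    serial = 0
    fallback_resid = {m: 0 for m in monomers}
    for node in structure.nodes:
        serial += 1
        chain = chain_of[node.monomer]
        if node.kind == "pigment":
            head, _, atom_name = node.source_label.partition(" / ")
            resname, _, resid_s = head.partition(" ")
            atom_name = atom_name.strip() or "MG"
            resid = int(resid_s) if resid_s.strip() else 9000 + serial
            record = "HETATM"
        else:
            parts = node.source_label.split()
            if len(parts) == 2 and parts[1].lstrip("-").isdigit():
                resname, resid = parts[0], int(parts[1])
            else:
                fallback_resid[node.monomer] += 1
                resname, resid = "GLY", fallback_resid[node.monomer]
            atom_name = "CA"
            record = "ATOM"
        x, y, z = node.position
        name_field = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
        lines.append(
            f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:>3.3s} "
            f"{chain}{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_toy_structure(
    n_residues: int = 5,
    n_pigments: int = 0,
    seed: int = 0,
    box: float = 20.0,
    min_distance: float = 3.0,
) -> CoarseStructure:
    """Random single-chain structure with optional 8-node pigments.

    Pigment nodes carry the standard atom labels so the structure
    round-trips through write_toy_pdb → read_pdb → coarse_grain.
    """
    rng = np.random.default_rng(seed)
    total = n_residues + 8 * n_pigments
    pts: list[np.ndarray] = []
    while len(pts) < total:
        cand = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(cand - p) >= min_distance for p in pts):
            pts.append(cand)
    nodes = []
    for k in range(n_residues):
        nodes.append(
            CoarseNode(
                index=len(nodes),
                position=pts[len(nodes)],
                mass=110.0,
                monomer="M1",
                kind="residue",
                source_label=f"GLY {k + 1}",
            )
        )
    for p in range(n_pigments):
        resid = 900 + p
        for atom in PIGMENT_ATOMS:
            nodes.append(
                CoarseNode(
                    index=len(nodes),
                    position=pts[len(nodes)],
                    mass=110.0,
                    monomer="M1",
                    kind="pigment",
                    source_label=f"BCL {resid} / {atom}",
                )
            )
    return CoarseStructure(nodes=nodes, provenance={"generator": "toy", "seed": seed})


def make_vibronic_fixture(kind: str, **params) -> ExcitonSystem:
    """Small exciton systems with analytically known limits.

    ``monomer``: one site plus the mode (displaced-oscillator closed
    form); ``dimer``: two sites and one coupling (2×2 exciton closed
    form); ``heptamer``: seven sites with a user-supplied or seeded
    random coupling matrix.
    """
    if kind == "monomer":
        eps = params.get("site_energy", 12300.0)
        return ExcitonSystem(
            site_energies=[eps],
            couplings=np.zeros((1, 1)),
            dipole_vectors=[[1.0, 0.0, 0.0]],
            mode_frequency=params.get("mode_frequency", 100.0),
            huang_rhys=params.get("huang_rhys", 0.3),
            n_levels=params.get("n_levels", 15),
        )
    if kind == "dimer":
        e1 = params.get("e1", 12300.0)
        e2 = params.get("e2", 12300.0)
        j = params.get("coupling", 50.0)
        J = np.array([[0.0, j], [j, 0.0]])
        dip = params.get("dipoles", [[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        pos = params.get("positions", [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        return ExcitonSystem(
            site_energies=[e1, e2],
            couplings=J,
            dipole_vectors=dip,
            positions=pos,
            mode_frequency=params.get("mode_frequency", 100.0),
            huang_rhys=params.get("huang_rhys", 0.0),
            coupled_sites=params.get("coupled_sites"),
            n_levels=params.get("n_levels", 15),
        )
    if kind == "heptamer":
        rng = np.random.default_rng(params.get("seed", 0))
        eps = np.asarray(
            params.get("site_energies", 12300.0 + rng.uniform(-150, 150, 7))
        )
        J = params.get("couplings")
        if J is None:
            J = rng.uniform(-60, 60, (7, 7))
            J = np.triu(J, 1)
            J = J + J.T
        dip = params.get("dipoles")
        if dip is None:
            dip = rng.normal(size=(7, 3))
            dip /= np.linalg.norm(dip, axis=1, keepdims=True)
        pos = params.get("positions")
        if pos is None:
            pos = rng.uniform(0.0, 30.0, (7, 3))
        return ExcitonSystem(
            site_energies=eps,
            couplings=np.asarray(J, dtype=float),
            dipole_vectors=np.asarray(dip, dtype=float),
            positions=np.asarray(pos, dtype=float),
            mode_frequency=params.get("mode_frequency", 100.0),
            huang_rhys=params.get("huang_rhys", 0.3),
            coupled_sites=params.get("coupled_sites", np.array([2, 3, 6])),
            n_levels=params.get("n_levels", 15),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
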