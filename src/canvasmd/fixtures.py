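"""Deterministic synthetic peptides with controlled geometry.

Every test input is generated here, never downloaded. The generator
builds chemically plausible backbone geometry (consecutive C-alpha
spacing ~0.38 nm, peptide C-N links ~0.15 nm) with synthetic 3-7-atom
side-chain stubs — controlled cell compositions, not real amino-acid
chemistry — and enumerates the full bonded topology (bonds, angles,
proper/improper dihedrals) plus 1-2/1-3/1-4 exclusions and 1-4 pairs
from the bond graph. Ground truth (term counts, net charge, total
mass, C-alpha distances) is recorded while the fixture is built, so
tests can compare against the generator's own declared values.

``make_planted_distances`` additionally repositions whole residues so
selected C-alpha (or minimum atom-atom) distances hit exact targets,
enabling threshold tests at the 1.4 nm spring cutoff and the 1 nm MG
shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .structure_io import (
    AngleTerm,
    AtomRecord,
    AtomisticTopology,
    BondTerm,
    DihedralTerm,
    Structure,
)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "FixtureError",
    "make_peptide",
    "make_planted_distances",
    "write_fixture_files",
]

CA_SPACING = 0.38  # nm between consecutive residue origins

# local geometry (nm), charges (e), LJ and masses for the backbone + stub
# (name, offset, charge, sigma, epsilon, mass, type)
_BACKBONE = [
    ("N", (0.00, 0.10, 0.00), -0.42, 0.325, 0.711, 14.007, "N"),
    ("HN", (-0.06, 0.18, 0.00), 0.27, 0.107, 0.066, 1.008, "H"),
    ("CA", (0.10, 0.00, 0.02), 0.02, 0.340, 0.458, 12.011, "CT"),
    ("HA", (0.10, -0.06, 0.11), 0.09, 0.265, 0.066, 1.008, "H1"),
    ("C", (0.24, 0.05, -0.02), 0.60, 0.340, 0.360, 12.011, "C"),
    ("O", (0.28, 0.16, -0.05), -0.57, 0.296, 0.879, 15.999, "O"),
]
_CB = ("CB", (0.12, -0.10, -0.11), 0.01, 0.340, 0.458, 12.011, "CT")

_RES_NAMES = ["ALA", "SER", "VAL", "LEU", "THR"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int
    geometry: str = "linear"  # linear | two-domain
    seed: int = 0


@dataclass
class GroundTruth:
    n_atoms: int = 0
    n_bonds: int = 0
    n_angles: int = 0
    n_proper_dihedrals: int = 0
    n_improper_dihedrals: int = 0
    n_pairs14: int = 0
    n_exclusions: int = 0
    net_charge: float = 0.0
    total_mass: float = 0.0
    ca_atom_ids: dict[int, int] = field(default_factory=dict)
    ca_consecutive_distances: list[float] = field(default_factory=list)
    planted: dict[tuple, float] = field(default_factory=dict)  # pair -> achieved


def _residue_origin(spec: FixtureSpec, i: int) -> np.ndarray:
    """Origin of residue i (0-based) for the requested geometry."""
    if spec.geometry == "linear":
        return np.array([CA_SPACING * i, 0.0, 0.0])
    if spec.geometry == "two-domain":
        half = spec.n_residues // 2
        if i < half:
            return np.array([CA_SPACING * i, 0.0, 0.0])
        return np.array([CA_SPACING * (half - 1) - CA_SPACING * (i - half), 0.9, 0.0])
    raise FixtureError(f"unknown geometry {spec.geometry!r}")


def make_peptide(spec: FixtureSpec) -> tuple[Structure, AtomisticTopology, GroundTruth]:
    """Generate a synthetic peptide; a pure function of the spec."""
    if spec.n_residues < 1:
        raise FixtureError("n_residues must be >= 1")
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    gt = GroundTruth()
    aid = 0
    res_atoms: dict[int, dict[str, int]] = {}

    for i in range(spec.n_residues):
        origin = _residue_origin(spec, i)
        names: dict[str, int] = {}
        rname = _RES_NAMES[i % len(_RES_NAMES)]
        n_extras = 2 + (i * 3 + spec.seed) % 5  # stub size 3..7 incl. CB
        template = list(_BACKBONE) + [_CB]
        prev = np.asarray(_CB[1])
        for k in range(1, n_extras + 1):
            jit = rng.uniform(-0.005, 0.005, size=3)
            off = prev + np.array([0.02 * k, -0.055 - 0.01 * k, 0.06 * (-1) ** k]) + jit
            q = 0.05 if k % 2 == 0 else -0.05
            template.append(
                (f"S{k}", tuple(off), q, 0.33 + 0.005 * k, 0.40 + 0.02 * k, 12.011, f"CS{k}")
            )
            prev = off
        for name, off, q, sig, eps, mass, tname in template:
            aid += 1
            atoms.append(
                AtomRecord(
                    atom_id=aid,
                    name=name,
                    residue_id=i + 1,
                    residue_name=rname,
                    coords=origin + np.asarray(off, dtype=float),
                    charge=q,
                    mass=mass,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                    type_name=tname,
                )
            )
            names[name] = aid
        res_atoms[i + 1] = names
        gt.ca_atom_ids[i + 1] = names["CA"]
        gt.net_charge += sum(t[2] for t in template)
        gt.total_mass += sum(t[5] for t in template)

    gt.n_atoms = aid
    box_pad = 2.0
    coords = np.array([a.coords for a in atoms])
    box = coords.max(axis=0) - coords.min(axis=0) + box_pad
    structure = Structure(atoms=atoms, box=np.maximum(box, 1.0))

    topology = _build_topology(structure, res_atoms, spec.n_residues)
    gt.n_bonds = len(topology.bonds)
    gt.n_angles = len(topology.angles)
    gt.n_proper_dihedrals = len(topology.proper_dihedrals)
    gt.n_improper_dihedrals = len(topology.improper_dihedrals)
    gt.n_pairs14 = len(topology.pairs14)
    gt.n_exclusions = len(topology.exclusions)

    for i in range(1, spec.n_residues):
        ca_a = structure.atom(gt.ca_atom_ids[i]).coords
        ca_b = structure.atom(gt.ca_atom_ids[i + 1]).coords
        gt.ca_consecutive_distances.append(float(np.linalg.norm(ca_a - ca_b)))
    return structure, topology, gt


def _measure_angle_deg(structure: Structure, i: int, j: int, k: int) -> float:
    a = structure.atom(i).coords - structure.atom(j).coords
    b = structure.atom(k).coords - structure.atom(j).coords
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _measure_dihedral_deg(structure: Structure, i, j, k, l) -> float:
    p = [structure.atom(x).coords for x in (i, j, k, l)]
    b0, b1, b2 = p[0] - p[1], p[2] - p[1], p[3] - p[2]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))
    )


def _build_topology(
    structure: Structure, res_atoms: dict[int, dict[str, int]], n_res: int
) -> AtomisticTopology:
    top = AtomisticTopology()
    dist = lambda i, j: float(
        np.linalg.norm(structure.atom(i).coords - structure.atom(j).coords)
    )

    def bond(i: int, j: int) -> None:
        top.bonds.append(BondTerm(min(i, j), max(i, j), 1, dist(i, j), 2.5e5))

    for r in range(1, n_res + 1):
        names = res_atoms[r]
        bond(names["N"], names["HN"])
        bond(names["N"], names["CA"])
        bond(names["CA"], names["HA"])
        bond(names["CA"], names["C"])
        bond(names["C"], names["O"])
        bond(names["CA"], names["CB"])
        prev = names["CB"]
        k = 1
        while f"S{k}" in names:
            bond(prev, names[f"S{k}"])
            prev = names[f"S{k}"]
            k += 1
        if r < n_res:
            bond(names["C"], res_atoms[r + 1]["N"])  # peptide link

    graph = nx.Graph()
    graph.add_nodes_from(a.atom_id for a in structure.atoms)
    graph.add_edges_from((b.i, b.j) for b in top.bonds)

    # angles: every 2-path of the bond graph, reference = measured geometry
    for j in sorted(graph.nodes):
        nbrs = sorted(graph.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                top.angles.append(
                    AngleTerm(i, j, k, 1, _measure_angle_deg(structure, i, j, k), 400.0)
                )

    # proper dihedrals: backbone phi/psi/omega-like plus one side torsion
    def proper(i, j, k, l, n, phi_s):
        top.proper_dihedrals.append(DihedralTerm(i, j, k, l, 9, (phi_s, 2.5, float(n))))

    for r in range(1, n_res + 1):
        names = res_atoms[r]
        if "S1" in names:
            proper(names["N"], names["CA"], names["CB"], names["S1"], 3, 0.0)
        if r < n_res:
            nxt = res_atoms[r + 1]
            proper(names["N"], names["CA"], names["C"], nxt["N"], 1, 0.0)  # psi
            proper(names["CA"], names["C"], nxt["N"], nxt["CA"], 2, 180.0)  # omega
            proper(names["C"], nxt["N"], nxt["CA"], nxt["C"], 3, 0.0)  # phi
            # improper keeping the carbonyl planar, reference = measured
            xi0 = _measure_dihedral_deg(
                structure, names["CA"], nxt["N"], names["C"], names["O"]
            )
            top.improper_dihedrals.append(
                DihedralTerm(names["CA"], nxt["N"], names["C"], names["O"], 2, (xi0, 40.0))
            )

    # 1-2/1-3/1-4 exclusions and 1-4 pairs from graph distance (nrexcl = 3)
    for i in sorted(graph.nodes):
        lengths = nx.single_source_shortest_path_length(graph, i, cutoff=3)
        for j, d in lengths.items():
            if j > i and d >= 1:
                top.exclusions.append((i, j))
                if d == 3:
                    top.pairs14.append((i, j))
    top.exclusions.sort()
    top.pairs14.sort()
    top.validate(structure)
    return top


# --------------------------------------------------------------------------
# planted exact distances
# --------------------------------------------------------------------------

_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0), (0, -1, 0), (0, 0, -1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, -1, 0), (-1, 1, 0), (1, 0, -1),
]


def make_planted_distances(
    pairs: list[tuple],
    seed: int = 0,
    n_residues: int | None = None,
    measure: str = "ca",
) -> tuple[Structure, AtomisticTopology, GroundTruth]:
    """Plant exact inter-residue distances by rigid residue translation.

    *pairs* holds ``(anchor, target, distance_nm)`` entries; *anchor* is
    a residue id (or a tuple of residue ids when ``measure='min'``), and
    the target residue is translated along a per-pair direction until the
    C-alpha-C-alpha (``measure='ca'``) or minimum atom-atom
    (``measure='min'``) distance equals the target to 1e-6 nm. A target
    whose constraints cannot all be realized raises
    :class:`FixtureError`.
    """
    if measure not in ("ca", "min"):
        raise FixtureError(f"unknown measure {measure!r}")
    res_mentioned: set[int] = set()
    norm_pairs: list[tuple[tuple[int, ...], int, float]] = []
    for anchor, target, d in pairs:
        anchors = tuple(anchor) if isinstance(anchor, (tuple, list)) else (int(anchor),)
        norm_pairs.append((anchors, int(target), float(d)))
        res_mentioned.update(anchors)
        res_mentioned.add(int(target))
    n = n_residues or max(res_mentioned)
    if max(res_mentioned) > n:
        raise FixtureError("pair references residue beyond n_residues")

    spec = FixtureSpec(n_residues=n, geometry="linear", seed=seed)
    structure, _, gt = make_peptide(spec)

    placed: set[int] = set()
    for idx, (anchors, target, d) in enumerate(norm_pairs):
        if target in placed or any(a == target for a in anchors):
            # over-constrained: verify below instead of re-placing
            continue
        u = np.asarray(_DIRECTIONS[idx % len(_DIRECTIONS)], dtype=float)
        u /= np.linalg.norm(u)
        anchor_ids = [aid for a in anchors for aid in structure.residue_atom_ids(a)]
        anchor_coords = np.array([structure.atom(i).coords for i in anchor_ids])
        ca_anchor = structure.atom(gt.ca_atom_ids[anchors[0]]).coords.copy()
        target_ids = structure.residue_atom_ids(target)
        ca_target = structure.atom(gt.ca_atom_ids[target]).coords.copy()

        if measure == "ca":
            shift = ca_anchor + d * u - ca_target
        else:
            rel = np.array(
                [structure.atom(i).coords - ca_target for i in target_ids]
            )

            def min_dist(s: float) -> float:
                pos = rel + ca_anchor + s * u
                return float(cdist(anchor_coords, pos).min())

            lo, hi = 1e-3, d + 5.0
            if min_dist(lo) - d > 0 or min_dist(hi) - d < 0:
                raise FixtureError(f"cannot bracket planted distance {d} for pair {idx}")
            s_star = brentq(lambda s: min_dist(s) - d, lo, hi, xtol=1e-12)
            shift = ca_anchor + s_star * u - ca_target
        for i in target_ids:
            structure.atom(i).coords += shift
        placed.add(target)

    # verify every constraint on the final geometry
    for anchors, target, d in norm_pairs:
        if measure == "ca":
            achieved = float(
                np.linalg.norm(
                    structure.atom(gt.ca_atom_ids[anchors[0]]).coords
                    - structure.atom(gt.ca_atom_ids[target]).coords
                )
            )
        else:
            a_coords = np.array(
                [structure.atom(i).coords
                 for a in anchors for i in structure.residue_atom_ids(a)]
            )
            t_coords = np.array(
                [structure.atom(i).coords for i in structure.residue_atom_ids(target)]
            )
            achieved = float(cdist(a_coords, t_coords).min())
        if abs(achieved - d) > 1e-6:
            raise FixtureError(
                f"infeasible planted-distance set: pair {anchors}->{target} "
                f"achieved {achieved:.6f} nm, wanted {d:.6f} nm"
            )
        gt.planted[(anchors, target)] = achieved

    # rebuild with updated coordinates so bond references stay measured
    res_atoms = {
        r: {structure.atom(i).name: i for i in structure.residue_atom_ids(r)}
        for r in structure.residue_ids
    }
    coords = structure.coords_array()
    structure.box = np.maximum(coords.max(axis=0) - coords.min(axis=0) + 2.0, 1.0)
    topology = _build_topology(structure, res_atoms, n)
    gt.n_bonds = len(topology.bonds)
    gt.n_angles = len(topology.angles)
    gt.n_proper_dihedrals = len(topology.proper_dihedrals)
    gt.n_improper_dihedrals = len(topology.improper_dihedrals)
    gt.n_pairs14 = len(topology.pairs14)
    gt.n_exclusions = len(topology.exclusions)
    return structure, topology, gt


# --------------------------------------------------------------------------
# file emission in the dialects consumed by structure_io
# --------------------------------------------------------------------------

def write_fixture_files(
    structure: Structure, topology: AtomisticTopology, outdir, name: str = "fixture"
) -> dict[str, str]:
    """Write .gro/.top files for CLI tests and examples."""
    import os

    from .structure_io import write_gro

    os.makedirs(outdir, exist_ok=True)
    gro_path = os.path.join(outdir, f"{name}.gro")
    top_path = os.path.join(outdir, f"{name}.top")
    write_gro(structure, gro_path, title="synthetic fixture")

    types: dict[str, tuple[float, float, float]] = {}
    for a in structure.atoms:
        types.setdefault(a.type_name, (a.mass, a.lj_sigma, a.lj_epsilon))
    with open(top_path, "w") as fh:
        fh.write("; synthetic fixture topology\n")
        fh.write("[ defaults ]\n1 2 no 0.500000 0.833333\n")
        fh.write("[ atomtypes ]\n")
        for tname, (mass, sig, eps) in sorted(types.items()):
            fh.write(f"{tname} 0 {mass:.6f} 0.000000 A {sig:.9e} {eps:.9e}\n")
        fh.write("[ moleculetype ]\nFIX 3\n")
        fh.write("[ atoms ]\n")
        for a in structure.atoms:
            fh.write(
                f"{a.atom_id} {a.type_name} {a.residue_id} {a.residue_name} "
                f"{a.name} {a.atom_id} {a.charge:.6f} {a.mass:.6f}\n"
            )
        fh.write("[ bonds ]\n")
        for b in topology.bonds:
            fh.write(f"{b.i} {b.j} 1 {b.r0:.9e} {b.k:.9e}\n")
        fh.write("[ pairs ]\n")
        for i, j in topology.pairs14:
            fh.write(f"{i} {j} 1\n")
        fh.write("[ angles ]\n")
        for t in topology.angles:
            fh.write(f"{t.i} {t.j} {t.k_atom} 1 {t.theta0:.9e} {t.k:.9e}\n")
        fh.write("[ dihedrals ]\n")
        for t in topology.proper_dihedrals:
            p = " ".join(f"{v:.9e}" for v in t.params)
            fh.write(f"{t.i} {t.j} {t.k_atom} {t.l_atom} {t.funct} {p}\n")
        fh.write("[ dihedrals ]\n")
        for t in topology.improper_dihedrals:
            p = " ".join(f"{v:.9e}" for v in t.params)
            fh.write(f"{t.i} {t.j} {t.k_atom} {t.l_atom} {t.funct} {p}\n")
        fh.write("[ exclusions ]\n")
        for i, j in topology.exclusions:
            fh.write(f"{i} {j}\n")
        fh.write("[ system ]\nfixture\n[ molecules ]\nFIX 1\n")
    return {"gro": gro_path, "top": top_path}
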