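"""Reading and writing of the all-atom inputs.

Coordinates travel in a fixed-width ``.gro`` dialect (nm, three decimals);
force-field parameters travel in a restricted GROMACS ``.top``/``.itp``
dialect in which every bonded term carries explicit inline parameters.
Nothing chemical is inferred: charges, masses and Lennard-Jones
parameters all come from the files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "AtomisticTopology",
    "GroParseError",
    "StructureError",
    "TopologyError",
    "read_gro",
    "write_gro",
    "read_topology",
]


class GroParseError(ValueError):
    """A ``.gro`` line could not be parsed; the message names the line."""


class StructureError(ValueError):
    """The file parsed but is structurally inconsistent (e.g. atom count)."""


class TopologyError(ValueError):
    """Unsupported topology dialect or a dangling atom reference."""


@dataclass
class AtomRecord:
    """One atomistic particle: identity, coordinates and FF parameters.

    Coordinates are in nm, charge in elementary charges, mass in amu,
    ``lj_sigma`` in nm and ``lj_epsilon`` in kJ/mol.
    """

    atom_id: int
    name: str
    residue_id: int
    residue_name: str
    coords: np.ndarray
    chain_id: str = "A"
    charge: float = 0.0
    mass: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    type_name: str = ""

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.atom_id}: non-finite coordinates")
        if self.mass < 0:
            raise StructureError(f"atom {self.atom_id}: negative mass")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise StructureError(f"atom {self.atom_id}: negative LJ parameter")


@dataclass
class Structure:
    """Ordered atom collection plus the box, with a residue index."""

    atoms: list[AtomRecord]
    box: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a in self.atoms:
            if a.atom_id in seen:
                raise StructureError(f"duplicate atom_id {a.atom_id}")
            seen.add(a.atom_id)
        self._by_id = {a.atom_id: a for a in self.atoms}
        self._residue_atoms: dict[int, list[int]] = {}
        for a in self.atoms:
            self._residue_atoms.setdefault(a.residue_id, []).append(a.atom_id)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self._residue_atoms)

    def atom(self, atom_id: int) -> AtomRecord:
        return self._by_id[atom_id]

    def residue_atom_ids(self, residue_id: int) -> list[int]:
        return self._residue_atoms[residue_id]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    funct: int
    r0: float  # nm
    k: float  # kJ/mol/nm^2

    @property
    def atom_ids(self) -> tuple[int, ...]:
        return (self.i, self.j)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k_atom: int
    funct: int
    theta0: float  # degrees
    k: float  # kJ/mol/rad^2

    @property
    def atom_ids(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k_atom)


@dataclass(frozen=True)
class DihedralTerm:
    """Proper (funct 1/9, periodic) or improper (funct 2 harmonic, 4 periodic)."""

    i: int
    j: int
    k_atom: int
    l_atom: int
    funct: int
    params: tuple[float, ...]  # periodic: (phi_s deg, k, n); harmonic: (xi0 deg, k)

    @property
    def atom_ids(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k_atom, self.l_atom)

    @property
    def improper(self) -> bool:
        return self.funct in (2, 4)


@dataclass
class AtomisticTopology:
    """Bonded-term lists plus 1-4 pairs and explicit nonbonded exclusions."""

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    proper_dihedrals: list[DihedralTerm] = field(default_factory=list)
    improper_dihedrals: list[DihedralTerm] = field(default_factory=list)
    pairs14: list[tuple[int, int]] = field(default_factory=list)
    exclusions: list[tuple[int, int]] = field(default_factory=list)
    fudge_lj: float = 0.5
    fudge_qq: float = 0.833333

    def validate(self, structure: Structure) -> None:
        ids = {a.atom_id for a in structure.atoms}
        for group in (
            self.bonds,
            self.angles,
            self.proper_dihedrals,
            self.improper_dihedrals,
        ):
            for term in group:
                for aid in term.atom_ids:
                    if aid not in ids:
                        raise TopologyError(
                            f"bonded term references atom {aid} absent from [atoms]"
                        )
        for i, j in list(self.pairs14) + list(self.exclusions):
            if i not in ids or j not in ids:
                raise TopologyError(
                    f"pair ({i},{j}) references an atom absent from [atoms]"
                )
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.pair in seen:
                raise TopologyError(f"duplicate bond {b.pair}")
            seen.add(b.pair)

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {b.pair for b in self.bonds}


# --------------------------------------------------------------------------
# .gro reading / writing
# --------------------------------------------------------------------------

def read_gro(path: str | os.PathLike) -> Structure:
    """Parse a fixed-width ``.gro`` file (nm units, last line = box).

    Raises :class:`GroParseError` naming the offending line on malformed
    fixed-width records and :class:`StructureError` when the atom count
    declared on line 2 disagrees with the records present.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise StructureError(f"{path}: too short to be a .gro file")
    try:
        declared = int(lines[1].strip())
    except ValueError as exc:
        raise GroParseError(f"{path}, line 2: atom count not an integer") from exc
    body = lines[2:-1]
    if len(body) != declared:
        raise StructureError(
            f"{path}: declares {declared} atoms but contains {len(body)}"
        )
    atoms: list[AtomRecord] = []
    for n, line in enumerate(body, start=3):
        if len(line) < 44:
            raise GroParseError(f"{path}, line {n}: record shorter than 44 columns")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            atom_id = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError as exc:
            raise GroParseError(f"{path}, line {n}: malformed fixed-width fields") from exc
        atoms.append(
            AtomRecord(
                atom_id=atom_id,
                name=name,
                residue_id=resid,
                residue_name=resname,
                coords=np.array([x, y, z]),
            )
        )
    box_fields = lines[-1].split()
    if len(box_fields) < 3:
        raise GroParseError(f"{path}, line {len(lines)}: box line needs 3 components")
    box = np.array([float(v) for v in box_fields[:3]])
    if np.any(box <= 0):
        raise StructureError(f"{path}: non-positive box vector")
    return Structure(atoms=atoms, box=box)


def write_gro(structure: Structure, path: str | os.PathLike, title: str = "canvas") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{structure.n_atoms:5d}\n")
        for a in structure.atoms:
            fh.write(
                "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
                % (
                    a.residue_id % 100000,
                    a.residue_name[:5],
                    a.name[:5],
                    a.atom_id % 100000,
                    a.coords[0],
                    a.coords[1],
                    a.coords[2],
                )
            )
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(structure.box))


# --------------------------------------------------------------------------
# restricted GROMACS topology dialect
# --------------------------------------------------------------------------

def _strip(line: str) -> str:
    return line.split(";", 1)[0].strip()


def _read_top_lines(path: str | os.PathLike, depth: int = 0) -> list[str]:
    """Read a topology, resolving one literal ``#include`` level."""
    out: list[str] = []
    base = os.path.dirname(os.fspath(path))
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("#include"):
                if depth >= 1:
                    raise TopologyError(
                        f"{path}: nested #include beyond one level is unsupported"
                    )
                inc = stripped.split(None, 1)[1].strip().strip('"<>')
                out.extend(_read_top_lines(os.path.join(base, inc), depth + 1))
                continue
            if stripped.startswith("#"):
                raise TopologyError(f"{path}: preprocessor directive {stripped!r} unsupported")
            out.append(line)
    return out


def _c6c12_to_sigma_eps(c6: float, c12: float) -> tuple[float, float]:
    if c6 <= 0 or c12 <= 0:
        return 0.0, 0.0
    sigma = (c12 / c6) ** (1.0 / 6.0)
    eps = c6 * c6 / (4.0 * c12)
    return sigma, eps


def read_topology(
    path: str | os.PathLike, structure: Structure | None = None
) -> AtomisticTopology:
    """Parse the restricted ``.top`` dialect; optionally merge per-atom
    force-field fields (charge, mass, sigma, epsilon, type) into *structure*.

    Supported sections: ``[defaults]``, ``[atomtypes]``, ``[moleculetype]``,
    ``[atoms]``, ``[bonds]``, ``[pairs]``, ``[angles]``, ``[dihedrals]``,
    ``[exclusions]``, ``[system]``, ``[molecules]``.  Bonded terms must
    carry explicit inline parameters; anything else fails loudly.
    """
    lines = _read_top_lines(path)
    section = None
    comb_rule = 2
    fudge_lj, fudge_qq = 0.5, 0.833333
    atomtypes: dict[str, tuple[float, float, float]] = {}  # name -> (mass, sigma, eps)
    atoms: dict[int, dict] = {}
    top = AtomisticTopology()

    for line in lines:
        text = _strip(line)
        if not text:
            continue
        if text.startswith("["):
            section = text.strip("[] ").lower()
            continue
        fields = text.split()
        if section == "defaults":
            comb_rule = int(fields[1])
            if len(fields) >= 5:
                fudge_lj, fudge_qq = float(fields[3]), float(fields[4])
        elif section == "atomtypes":
            name = fields[0]
            try:
                ptype_idx = next(
                    i for i, f in enumerate(fields) if f in ("A", "S", "V", "D")
                )
            except StopIteration as exc:
                raise TopologyError(f"[atomtypes] line lacks a particle type: {text!r}") from exc
            mass = float(fields[ptype_idx - 2])
            v, w = float(fields[ptype_idx + 1]), float(fields[ptype_idx + 2])
            if comb_rule == 1:
                sigma, eps = _c6c12_to_sigma_eps(v, w)
            else:
                sigma, eps = v, w
            atomtypes[name] = (mass, sigma, eps)
        elif section == "atoms":
            if len(fields) < 7:
                raise TopologyError(f"[atoms] line too short: {text!r}")
            nr = int(fields[0])
            type_name = fields[1]
            charge = float(fields[6])
            mass = float(fields[7]) if len(fields) > 7 else None
            atoms[nr] = {"type": type_name, "charge": charge, "mass": mass}
        elif section == "bonds":
            if len(fields) < 5:
                raise TopologyError(f"[bonds] line lacks inline parameters: {text!r}")
            i, j, funct = int(fields[0]), int(fields[1]), int(fields[2])
            if funct != 1:
                raise TopologyError(f"bond funct {funct} unsupported")
            top.bonds.append(BondTerm(i, j, funct, float(fields[3]), float(fields[4])))
        elif section == "pairs":
            top.pairs14.append((int(fields[0]), int(fields[1])))
        elif section == "angles":
            if len(fields) < 6:
                raise TopologyError(f"[angles] line lacks inline parameters: {text!r}")
            funct = int(fields[3])
            if funct != 1:
                raise TopologyError(f"angle funct {funct} unsupported")
            top.angles.append(
                AngleTerm(
                    int(fields[0]), int(fields[1]), int(fields[2]),
                    funct, float(fields[4]), float(fields[5]),
                )
            )
        elif section == "dihedrals":
            if len(fields) < 6:
                raise TopologyError(f"[dihedrals] line lacks inline parameters: {text!r}")
            ids = tuple(int(f) for f in fields[:4])
            funct = int(fields[4])
            if funct in (1, 9):
                term = DihedralTerm(*ids, funct, (float(fields[5]), float(fields[6]), float(fields[7])))
                top.proper_dihedrals.append(term)
            elif funct == 2:
                term = DihedralTerm(*ids, funct, (float(fields[5]), float(fields[6])))
                top.improper_dihedrals.append(term)
            elif funct == 4:
                term = DihedralTerm(*ids, funct, (float(fields[5]), float(fields[6]), float(fields[7])))
                top.improper_dihedrals.append(term)
            else:
                raise TopologyError(f"dihedral funct {funct} unsupported")
        elif section == "exclusions":
            first = int(fields[0])
            for other in fields[1:]:
                top.exclusions.append((first, int(other)))
        elif section in ("moleculetype", "system", "molecules", None):
            continue
        else:
            raise TopologyError(f"unsupported topology section [{section}]")

    top.fudge_lj, top.fudge_qq = fudge_lj, fudge_qq

    if structure is not None:
        for a in structure.atoms:
            if a.atom_id not in atoms:
                raise TopologyError(f"atom {a.atom_id} missing from [atoms]")
            meta = atoms[a.atom_id]
            tname = meta["type"]
            if tname not in atomtypes:
                raise TopologyError(f"atom type {tname!r} missing from [atomtypes]")
            tmass, sigma, eps = atomtypes[tname]
            a.type_name = tname
            a.charge = meta["charge"]
            a.mass = meta["mass"] if meta["mass"] is not None else tmass
            a.lj_sigma = sigma
            a.lj_epsilon = eps
            a.validate()
        top.validate(structure)
    else:
        ids = set(atoms)
        for group in (top.bonds, top.angles, top.proper_dihedrals, top.improper_dihedrals):
            for term in group:
                for aid in term.atom_ids:
                    if aid not in ids:
                        raise TopologyError(
                            f"bonded term references atom {aid} absent from [atoms]"
                        )
    return top
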