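"""Per-residue resolution labels, the survived-atom set and the Voronoi map.

Three resolution levels are supported. An all-atom (AT) residue keeps
every atom; a medium-grained (MG) residue keeps the four backbone atoms
N, CA, C, O; a coarse-grained (CG) residue keeps only its C-alpha.
Every decimated atom is then assigned to the nearest surviving
coarse site by Euclidean distance in the reference coordinates — a
Voronoi tessellation of the molecule onto the survivors. Cells may
freely cross residue boundaries; a bead is not necessarily
representative of atoms from a single residue.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "AT", "MG", "CG",
    "ResolutionAssignment",
    "Survivor",
    "SurvivorSet",
    "CellMap",
    "ResolutionError",
    "assign_resolution",
    "select_survivors",
    "voronoi_assign",
    "write_survivor_list",
    "read_survivor_list",
]

AT, MG, CG = "at", "mg", "cg"
BACKBONE_NAMES = ("N", "CA", "C", "O")

# tolerance below which two survivor distances count as an exact tie
_TIE_TOL = 1e-9


class ResolutionError(ValueError):
    pass


@dataclass
class ResolutionAssignment:
    """Label (at/mg/cg) and provenance (user / auto-MG / auto-CG) per residue."""

    labels: dict[int, str]
    provenance: dict[int, str] = field(default_factory=dict)

    def label(self, residue_id: int) -> str:
        return self.labels[residue_id]

    def residues(self, label: str) -> list[int]:
        return sorted(r for r, lab in self.labels.items() if lab == label)


@dataclass(frozen=True)
class Survivor:
    atom_id: int
    label: str  # at | mg | cg
    role: str  # e.g. "CA_cg", "N_mg", "CB_at"


class SurvivorSet:
    """Ordered survived atoms with their resolution labels."""

    def __init__(self, survivors: list[Survivor]):
        self.survivors = survivors
        self._by_id = {s.atom_id: s for s in survivors}
        if len(self._by_id) != len(survivors):
            raise ResolutionError("duplicate survivor atom ids")

    @property
    def atom_ids(self) -> list[int]:
        return [s.atom_id for s in self.survivors]

    def __len__(self) -> int:
        return len(self.survivors)

    def __iter__(self):
        return iter(self.survivors)

    def __contains__(self, atom_id: int) -> bool:
        return atom_id in self._by_id

    def label_of(self, atom_id: int) -> str:
        return self._by_id[atom_id].label


@dataclass
class CellMap:
    """Voronoi partition: survivor id -> member atom ids (incl. itself)."""

    members: dict[int, list[int]]
    survivor_of: dict[int, int]

    def validate(self, structure: Structure) -> None:
        all_ids = {a.atom_id for a in structure.atoms}
        seen: set[int] = set()
        for sid, cell in self.members.items():
            if sid not in cell:
                raise ResolutionError(f"survivor {sid} not a member of its own cell")
            for aid in cell:
                if aid in seen:
                    raise ResolutionError(f"atom {aid} appears in two cells")
                seen.add(aid)
        if seen != all_ids:
            raise ResolutionError("cells do not cover the full atom set")


def assign_resolution(
    structure: Structure,
    at_residues: set[int] | list[int],
    mg_residues: set[int] | list[int] | None = None,
    mg_shell: float = 1.0,
) -> ResolutionAssignment:
    """Label every residue AT, MG or CG.

    If *mg_residues* is given the user's labels are taken verbatim.
    Otherwise the MG region is built automatically from every non-AT
    residue whose minimum atom-atom distance to the AT region is below
    *mg_shell* (default 1 nm, strict ``<``); the rest becomes CG.
    """
    at_set = set(at_residues)
    all_res = set(structure.residue_ids)
    if not at_set:
        raise ResolutionError("at_residues must be non-empty")
    unknown = at_set - all_res
    if unknown:
        raise ResolutionError(f"unknown residue ids in at_residues: {sorted(unknown)}")

    labels: dict[int, str] = {r: AT for r in at_set}
    provenance: dict[int, str] = {r: "user" for r in at_set}

    if mg_residues is not None:
        mg_set = set(mg_residues)
        if mg_set & at_set:
            raise ResolutionError(
                f"residues in both AT and MG sets: {sorted(mg_set & at_set)}"
            )
        unknown = mg_set - all_res
        if unknown:
            raise ResolutionError(f"unknown residue ids in mg_residues: {sorted(unknown)}")
        for r in mg_set:
            labels[r], provenance[r] = MG, "user"
        for r in all_res - at_set - mg_set:
            labels[r], provenance[r] = CG, "user"
        return ResolutionAssignment(labels, provenance)

    at_atom_ids = [aid for r in at_set for aid in structure.residue_atom_ids(r)]
    at_coords = np.array([structure.atom(aid).coords for aid in at_atom_ids])
    tree = cKDTree(at_coords)
    for r in sorted(all_res - at_set):
        res_coords = np.array(
            [structure.atom(aid).coords for aid in structure.residue_atom_ids(r)]
        )
        dmin = float(np.min(tree.query(res_coords, k=1)[0]))
        if dmin < mg_shell:
            labels[r], provenance[r] = MG, "auto-MG"
        else:
            labels[r], provenance[r] = CG, "auto-CG"
    return ResolutionAssignment(labels, provenance)


def select_survivors(
    structure: Structure, assignment: ResolutionAssignment
) -> SurvivorSet:
    """Apply the survived-atom taxonomy: AT keeps all atoms, MG keeps the
    backbone N/CA/C/O, CG keeps the C-alpha only.

    Backbone atoms are identified by name within the residue; terminal
    variants (OXT, H1-H3, ...) count as side-group atoms and are
    decimated in MG/CG residues.
    """
    missing = set(structure.residue_ids) - set(assignment.labels)
    if missing:
        raise ResolutionError(f"residues without a resolution label: {sorted(missing)}")
    survivors: list[Survivor] = []
    for atom in structure.atoms:
        lab = assignment.labels[atom.residue_id]
        if lab == AT:
            survivors.append(Survivor(atom.atom_id, AT, f"{atom.name}_at"))
        elif lab == MG and atom.name in BACKBONE_NAMES:
            survivors.append(Survivor(atom.atom_id, MG, f"{atom.name}_mg"))
        elif lab == CG and atom.name == "CA":
            survivors.append(Survivor(atom.atom_id, CG, "CA_cg"))
    # contract check: MG needs all four backbone atoms, CG needs a CA
    per_res: dict[int, set[str]] = {}
    for s in survivors:
        atom = structure.atom(s.atom_id)
        per_res.setdefault(atom.residue_id, set()).add(atom.name)
    for rid in structure.residue_ids:
        lab = assignment.labels[rid]
        names = per_res.get(rid, set())
        if lab == MG and not set(BACKBONE_NAMES) <= names:
            raise ResolutionError(
                f"MG residue {rid} lacks backbone atom(s) "
                f"{sorted(set(BACKBONE_NAMES) - names)}"
            )
        if lab == CG and "CA" not in names:
            raise ResolutionError(f"CG residue {rid} lacks an atom named CA")
    return SurvivorSet(survivors)


def voronoi_assign(structure: Structure, survivors: SurvivorSet) -> CellMap:
    """Map every decimated atom onto its nearest surviving coarse site.

    Candidate sites are the MG/CG survivors: atoms of the all-atom
    region are retained as themselves and never absorb decimated atoms,
    so bead parameters in the AT region stay pristine and total charge
    and mass are conserved. Exact distance ties are broken toward the
    lowest survivor atom_id, which makes the output deterministic and
    independent of file order.
    """
    if len(survivors) == 0:
        raise ResolutionError("survivor set is empty")
    surv_ids = set(survivors.atom_ids)
    decimated = [a for a in structure.atoms if a.atom_id not in surv_ids]
    members: dict[int, list[int]] = {sid: [sid] for sid in survivors.atom_ids}
    survivor_of: dict[int, int] = {sid: sid for sid in survivors.atom_ids}

    if decimated:
        cand = sorted(
            (s.atom_id for s in survivors if s.label != AT),
        )
        if not cand:
            cand = sorted(surv_ids)
        cand_coords = np.array([structure.atom(cid).coords for cid in cand])
        tree = cKDTree(cand_coords)
        k = min(2, len(cand))
        dists, idx = tree.query(
            np.array([a.coords for a in decimated]), k=k
        )
        if k == 1:
            dists = dists[:, None]
            idx = idx[:, None]
        for row, atom in enumerate(decimated):
            best = int(idx[row, 0])
            if k > 1 and dists[row, 1] - dists[row, 0] < _TIE_TOL:
                ball = tree.query_ball_point(atom.coords, dists[row, 0] + _TIE_TOL)
                best = min(ball)
            sid = cand[best]
            members[sid].append(atom.atom_id)
            survivor_of[atom.atom_id] = sid

    for cell in members.values():
        cell.sort()
    cm = CellMap(members=members, survivor_of=survivor_of)
    cm.validate(structure)
    return cm


# --------------------------------------------------------------------------
# survived-atom list interchange format
# --------------------------------------------------------------------------

def write_survivor_list(
    structure: Structure, survivors: SurvivorSet, path: str | os.PathLike
) -> None:
    """One line per survivor: atom_id, atom name, residue_id, label."""
    with open(path, "w") as fh:
        fh.write("; survived atoms: atom_id name residue_id label\n")
        for s in survivors:
            atom = structure.atom(s.atom_id)
            fh.write(f"{s.atom_id} {atom.name} {atom.residue_id} {s.label}\n")


def read_survivor_list(
    path: str | os.PathLike, structure: Structure
) -> tuple[SurvivorSet, ResolutionAssignment]:
    """Read the interchange list back and reconstruct per-residue labels."""
    survivors: list[Survivor] = []
    res_labels: dict[int, str] = {}
    with open(path) as fh:
        for n, raw in enumerate(fh, start=1):
            text = raw.split(";", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 4:
                raise ResolutionError(f"{path}, line {n}: expected 4 fields")
            atom_id, name, rid, label = (
                int(fields[0]), fields[1], int(fields[2]), fields[3].lower(),
            )
            if label not in (AT, MG, CG):
                raise ResolutionError(f"{path}, line {n}: unknown label {label!r}")
            if atom_id not in {a.atom_id for a in structure.atoms}:
                raise ResolutionError(f"{path}, line {n}: unknown atom id {atom_id}")
            suffix = {AT: "at", MG: "mg", CG: "cg"}[label]
            survivors.append(Survivor(atom_id, label, f"{name}_{suffix}"))
            prev = res_labels.setdefault(rid, label)
            if prev != label:
                raise ResolutionError(
                    f"{path}: residue {rid} carries conflicting labels"
                )
    for rid in structure.residue_ids:
        res_labels.setdefault(rid, CG)
    assignment = ResolutionAssignment(
        labels=res_labels, provenance={r: "user" for r in res_labels}
    )
    return SurvivorSet(survivors), assignment
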