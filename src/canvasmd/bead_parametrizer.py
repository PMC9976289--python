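"""Effective nonbonded parameters of the coarse sites.

Each surviving atom becomes a bead whose properties are computed from
its Voronoi cell: the charge is the algebraic sum of the member
charges, the diameter is twice the cell's radius of gyration about its
(unweighted) centre of geometry, the dispersion epsilon is the
geometric mean of the member epsilons, and the mass is the member-mass
sum so that total system mass is conserved. All-atom survivors keep
their pristine atomistic parameters. Inter-bead Lennard-Jones
interactions follow the Lorentz-Berthelot combination rules inherited
from the atomistic force field, so only per-bead sigma/epsilon are
emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .resolution_mapper import AT, CellMap, SurvivorSet
from .structure_io import AtomRecord, Structure

__all__ = [
    "Bead",
    "bead_charge",
    "bead_sigma",
    "bead_epsilon",
    "bead_mass",
    "parametrize_beads",
]


@dataclass
class Bead:
    """A survived site endowed with effective nonbonded parameters."""

    atom_id: int  # original atomistic id of the survivor
    name: str
    residue_id: int
    residue_name: str
    label: str  # at | mg | cg
    coords: np.ndarray  # nm, the survivor's reference coordinates
    charge: float  # e
    sigma: float  # nm
    epsilon: float  # kJ/mol
    mass: float  # amu
    member_ids: list[int] = field(default_factory=list)
    type_name: str = ""  # original FF type, kept for AT beads


def bead_charge(cell: list[AtomRecord]) -> float:
    """Algebraic sum of the member charges."""
    if not cell:
        raise ValueError("empty cell")
    return float(sum(a.charge for a in cell))


def bead_sigma(cell: list[AtomRecord]) -> float:
    """Bead diameter: twice the radius of gyration of the cell members
    about their unweighted centre of geometry.

    A single-member cell has zero gyration radius; it falls back to the
    member's own atomistic sigma so the bead keeps its steric volume.
    """
    if not cell:
        raise ValueError("empty cell")
    if len(cell) == 1:
        return float(cell[0].lj_sigma)
    coords = np.array([a.coords for a in cell], dtype=float)
    cog = coords.mean(axis=0)
    rg2 = float(np.mean(np.sum((coords - cog) ** 2, axis=1)))
    return 2.0 * np.sqrt(rg2)


def bead_epsilon(cell: list[AtomRecord]) -> float:
    """Geometric mean of the member epsilons (computed in log space)."""
    if not cell:
        raise ValueError("empty cell")
    eps = np.array([a.lj_epsilon for a in cell], dtype=float)
    if np.any(eps < 0):
        raise ValueError("negative epsilon in cell")
    if len(eps) == 1:
        return float(eps[0])
    if np.any(eps == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(eps))))


def bead_mass(cell: list[AtomRecord]) -> float:
    """Sum of the member masses (total mass conserved)."""
    if not cell:
        raise ValueError("empty cell")
    return float(sum(a.mass for a in cell))


def parametrize_beads(
    structure: Structure, survivors: SurvivorSet, cellmap: CellMap
) -> list[Bead]:
    """One bead per survivor, in survivor order.

    AT survivors keep their atomistic charge/sigma/epsilon/mass and
    represent only themselves; MG/CG survivors get cell-averaged
    parameters.
    """
    beads: list[Bead] = []
    for s in survivors:
        atom = structure.atom(s.atom_id)
        cell_ids = cellmap.members[s.atom_id]
        if s.label == AT:
            if cell_ids != [s.atom_id]:
                raise ValueError(f"AT survivor {s.atom_id} has a non-singleton cell")
            q, sig, eps, m = atom.charge, atom.lj_sigma, atom.lj_epsilon, atom.mass
        else:
            cell = [structure.atom(aid) for aid in cell_ids]
            q = bead_charge(cell)
            sig = bead_sigma(cell)
            eps = bead_epsilon(cell)
            m = bead_mass(cell)
        beads.append(
            Bead(
                atom_id=s.atom_id,
                name=atom.name,
                residue_id=atom.residue_id,
                residue_name=atom.residue_name,
                label=s.label,
                coords=atom.coords.copy(),
                charge=q,
                sigma=sig,
                epsilon=eps,
                mass=m,
                member_ids=list(cell_ids),
                type_name=atom.type_name if s.label == AT else "",
            )
        )
    return beads
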