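"""Assembly of the complete multiresolution model and file emission.

The assembled model renumbers beads contiguously (1..N) while keeping a
map back to the original atom ids, computes sigma_max and the
recommended nonbonded cutoff 2.5*sigma_max, and serializes to either a
GROMACS ``.top``/``.gro`` pair (plus an advisory ``.mdp`` with
reaction-field settings, dielectric 80) or a LAMMPS data + settings
pair in "real" units. Output is deterministic: identical inputs and
configuration produce byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import units
from .bead_parametrizer import Bead
from .bonded_builder import (
    TIER_CONSECUTIVE,
    RetainedBondedSet,
    SpringTerm,
)
from .config import CanvasConfig
from .structure_io import (
    AngleTerm,
    AtomRecord,
    BondTerm,
    DihedralTerm,
    Structure,
    read_gro,
    read_topology,
    write_gro,
)

__all__ = [
    "CanvasModel",
    "AssemblyError",
    "assemble_model",
    "write_gromacs",
    "read_gromacs_model",
    "write_lammps",
]

TIER_COVALENT = "covalent"


class AssemblyError(ValueError):
    pass


@dataclass
class CanvasModel:
    """Beads + retained bonded terms + springs + exclusions, in contiguous
    bead numbering (1-based). ``orig_atom_ids[i-1]`` recovers the source
    atom of bead i."""

    beads: list[Bead]
    retained: RetainedBondedSet
    springs: list[SpringTerm]
    exclusions: list[tuple[int, int]]
    pairs14: list[tuple[int, int]]
    box: np.ndarray
    config: CanvasConfig = field(default_factory=CanvasConfig)
    profile_id: str = "exp"
    fudge_lj: float = 0.5
    fudge_qq: float = 0.833333
    orig_atom_ids: list[int] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def sigma_max(self) -> float:
        return max(b.sigma for b in self.beads)

    @property
    def recommended_cutoff(self) -> float:
        return self.config.cutoff_factor * self.sigma_max

    @property
    def epsilon_rf(self) -> float:
        return self.config.epsilon_rf

    def coords_array(self) -> np.ndarray:
        return np.array([b.coords for b in self.beads], dtype=float)

    def spring_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.springs:
            counts[s.tier] = counts.get(s.tier, 0) + 1
        return counts

    def validate(self) -> None:
        n = self.n_beads
        for group in (
            self.retained.bonds,
            self.retained.angles,
            self.retained.proper_dihedrals,
            self.retained.improper_dihedrals,
        ):
            for term in group:
                for aid in term.atom_ids:
                    if not 1 <= aid <= n:
                        raise AssemblyError(f"dangling bead reference {aid}")
        for s in self.springs:
            if not (1 <= s.i <= n and 1 <= s.j <= n):
                raise AssemblyError(f"dangling spring reference {s.i},{s.j}")
        for i, j in list(self.exclusions) + list(self.pairs14):
            if not (1 <= i <= n and 1 <= j <= n):
                raise AssemblyError(f"dangling pair reference {i},{j}")


def _remap_term(term, mapping):
    if isinstance(term, BondTerm):
        return BondTerm(mapping[term.i], mapping[term.j], term.funct, term.r0, term.k)
    if isinstance(term, AngleTerm):
        return AngleTerm(
            mapping[term.i], mapping[term.j], mapping[term.k_atom],
            term.funct, term.theta0, term.k,
        )
    if isinstance(term, DihedralTerm):
        return DihedralTerm(
            mapping[term.i], mapping[term.j], mapping[term.k_atom],
            mapping[term.l_atom], term.funct, term.params,
        )
    raise TypeError(type(term))


def assemble_model(
    structure: Structure,
    beads: list[Bead],
    retained: RetainedBondedSet,
    springs: list[SpringTerm],
    exclusions: list[tuple[int, int]],
    pairs14: list[tuple[int, int]],
    config: CanvasConfig | None = None,
    profile_id: str = "exp",
    fudge_lj: float = 0.5,
    fudge_qq: float = 0.833333,
) -> CanvasModel:
    """Renumber everything onto contiguous bead ids and validate."""
    config = config or CanvasConfig()
    mapping = _Checked({b.atom_id: i for i, b in enumerate(beads, start=1)})
    retained2 = RetainedBondedSet(
        bonds=[_remap_term(t, mapping) for t in retained.bonds],
        angles=[_remap_term(t, mapping) for t in retained.angles],
        proper_dihedrals=[_remap_term(t, mapping) for t in retained.proper_dihedrals],
        improper_dihedrals=[_remap_term(t, mapping) for t in retained.improper_dihedrals],
    )
    springs2 = [
        SpringTerm(mapping[s.i], mapping[s.j], s.r0, s.k, s.tier) for s in springs
    ]
    excl2 = sorted(
        (min(mapping[i], mapping[j]), max(mapping[i], mapping[j]))
        for i, j in exclusions
    )
    pairs2 = sorted(
        (min(mapping[i], mapping[j]), max(mapping[i], mapping[j]))
        for i, j in pairs14
    )
    model = CanvasModel(
        beads=beads,
        retained=retained2,
        springs=springs2,
        exclusions=excl2,
        pairs14=pairs2,
        box=np.asarray(structure.box, dtype=float),
        config=config,
        profile_id=profile_id,
        fudge_lj=fudge_lj,
        fudge_qq=fudge_qq,
        orig_atom_ids=[b.atom_id for b in beads],
    )
    model.validate()
    return model


class _Checked:
    """Mapping wrapper that raises :class:`AssemblyError` on misses."""

    def __init__(self, mapping: dict[int, int]):
        self._m = mapping

    def __getitem__(self, aid: int) -> int:
        try:
            return self._m[aid]
        except KeyError:
            raise AssemblyError(
                f"term references atom {aid} which is not a bead"
            ) from None


# --------------------------------------------------------------------------
# GROMACS emission
# --------------------------------------------------------------------------

def _bead_types(model: CanvasModel) -> tuple[dict[int, str], list[tuple[str, float, float, float]]]:
    """One type per distinct (mass, sigma, epsilon); AT beads keep their
    original force-field type name, coarse beads get generated CVSn names."""
    type_of: dict[int, str] = {}
    types: list[tuple[str, float, float, float]] = []
    seen: dict[tuple, str] = {}
    used_names: set[str] = set()
    counter = 0
    for i, b in enumerate(model.beads, start=1):
        if b.label == "at":
            # pristine atomistic type; disambiguate name clashes with
            # differing parameters (same input type name, distinct LJ)
            key = ("at", b.type_name or f"AT_{b.name}", round(b.mass, 9),
                   round(b.sigma, 12), round(b.epsilon, 12))
            name = key[1]
        else:
            key = ("cvs", round(b.mass, 9), round(b.sigma, 12), round(b.epsilon, 12))
            name = None
        if key not in seen:
            if name is None:
                counter += 1
                name = f"CVS{counter}"
            else:
                base, suffix = name, 1
                while name in used_names:
                    name = f"{base}v{suffix}"
                    suffix += 1
            seen[key] = name
            used_names.add(name)
            types.append((name, b.mass, b.sigma, b.epsilon))
        type_of[i] = seen[key]
    return type_of, types


def write_gromacs(model: CanvasModel, outdir: str | os.PathLike, name: str = "canvas") -> dict[str, str]:
    """Emit ``<name>.top``, ``<name>.gro`` and an advisory ``<name>.mdp``.

    Springs are written as harmonic bonds (GROMACS bond function 1)
    tagged with a ``; tier=`` comment so the model round-trips through
    :func:`read_gromacs_model`.
    """
    os.makedirs(outdir, exist_ok=True)
    top_path = os.path.join(outdir, f"{name}.top")
    gro_path = os.path.join(outdir, f"{name}.gro")
    mdp_path = os.path.join(outdir, f"{name}.mdp")

    type_of, types = _bead_types(model)
    cfg = model.config.as_dict()
    cfg_line = " ".join(f"{k}={v:g}" for k, v in sorted(cfg.items()))

    with open(top_path, "w") as fh:
        fh.write("; CANVAS multiresolution model topology\n")
        fh.write(f"; config: {cfg_line}\n")
        fh.write(f"; profile: {model.profile_id}\n")
        fh.write("\n[ defaults ]\n; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ\n")
        fh.write(f"1 2 no {model.fudge_lj:.6f} {model.fudge_qq:.6f}\n")
        fh.write("\n[ atomtypes ]\n; name at.num mass charge ptype sigma epsilon\n")
        for tname, mass, sigma, eps in types:
            fh.write(f"{tname} 0 {mass:.6f} 0.000000 A {sigma:.9e} {eps:.9e}\n")
        fh.write("\n[ moleculetype ]\n; name nrexcl\nCANVAS 0\n")
        fh.write("\n[ atoms ]\n; nr type resnr residue atom cgnr charge mass\n")
        for i, b in enumerate(model.beads, start=1):
            fh.write(
                f"{i} {type_of[i]} {b.residue_id} {b.residue_name} {b.name} {i} "
                f"{b.charge:.6f} {b.mass:.6f} ; label={b.label}\n"
            )
        fh.write("\n[ bonds ]\n; i j funct b0 kb\n")
        for t in model.retained.bonds:
            fh.write(f"{t.i} {t.j} 1 {t.r0:.9e} {t.k:.9e} ; tier={TIER_COVALENT}\n")
        for s in model.springs:
            fh.write(f"{s.i} {s.j} 1 {s.r0:.9e} {s.k:.9e} ; tier={s.tier}\n")
        fh.write("\n[ pairs ]\n; i j funct\n")
        for i, j in model.pairs14:
            fh.write(f"{i} {j} 1\n")
        fh.write("\n[ angles ]\n; i j k funct th0 cth\n")
        for t in model.retained.angles:
            fh.write(f"{t.i} {t.j} {t.k_atom} 1 {t.theta0:.9e} {t.k:.9e}\n")
        fh.write("\n[ dihedrals ]\n; proper\n")
        for t in model.retained.proper_dihedrals:
            p = " ".join(f"{v:.9e}" for v in t.params)
            fh.write(f"{t.i} {t.j} {t.k_atom} {t.l_atom} {t.funct} {p}\n")
        fh.write("\n[ dihedrals ]\n; improper\n")
        for t in model.retained.improper_dihedrals:
            p = " ".join(f"{v:.9e}" for v in t.params)
            fh.write(f"{t.i} {t.j} {t.k_atom} {t.l_atom} {t.funct} {p}\n")
        fh.write("\n[ exclusions ]\n")
        for i, j in model.exclusions:
            fh.write(f"{i} {j}\n")
        fh.write("\n[ system ]\nCANVAS model\n\n[ molecules ]\nCANVAS 1\n")

    atoms = [
        AtomRecord(
            atom_id=i,
            name=b.name,
            residue_id=b.residue_id,
            residue_name=b.residue_name,
            coords=np.asarray(b.coords, dtype=float),
        )
        for i, b in enumerate(model.beads, start=1)
    ]
    write_gro(Structure(atoms=atoms, box=model.box), gro_path, title="CANVAS model")

    with open(mdp_path, "w") as fh:
        rc = model.recommended_cutoff
        fh.write(
            "; advisory run settings for the CANVAS model\n"
            "integrator      = md\n"
            "coulombtype     = Reaction-Field\n"
            f"epsilon_rf      = {model.epsilon_rf:g}\n"
            f"rlist           = {rc:.6f}\n"
            f"rcoulomb        = {rc:.6f}\n"
            f"rvdw            = {rc:.6f}\n"
        )
    return {"top": top_path, "gro": gro_path, "mdp": mdp_path}


def read_gromacs_model(outdir: str | os.PathLike, name: str = "canvas") -> CanvasModel:
    """Reconstruct a :class:`CanvasModel` from the emitted GROMACS files."""
    top_path = os.path.join(outdir, f"{name}.top")
    gro_path = os.path.join(outdir, f"{name}.gro")
    structure = read_gro(gro_path)
    topology = read_topology(top_path, structure)

    config_kwargs: dict[str, float] = {}
    profile_id = "exp"
    labels: dict[int, str] = {}
    tiers: list[str] = []
    with open(top_path) as fh:
        section = None
        atom_line = 0
        for raw in fh:
            text = raw.strip()
            if text.startswith("; config:"):
                for tok in text.split(":", 1)[1].split():
                    k, v = tok.split("=")
                    config_kwargs[k] = float(v)
            elif text.startswith("; profile:"):
                profile_id = text.split(":", 1)[1].strip()
            code = raw.split(";", 1)[0].strip()
            if code.startswith("["):
                section = code.strip("[] ").lower()
                continue
            if not code:
                continue
            if section == "atoms":
                atom_line += 1
                if "label=" in raw:
                    labels[atom_line] = raw.rsplit("label=", 1)[1].strip()
            elif section == "bonds" and "tier=" in raw:
                tiers.append(raw.rsplit("tier=", 1)[1].strip())

    config = CanvasConfig(**config_kwargs) if config_kwargs else CanvasConfig()

    beads: list[Bead] = []
    for i, a in enumerate(structure.atoms, start=1):
        beads.append(
            Bead(
                atom_id=i,
                name=a.name,
                residue_id=a.residue_id,
                residue_name=a.residue_name,
                label=labels.get(i, "at"),
                coords=a.coords,
                charge=a.charge,
                sigma=a.lj_sigma,
                epsilon=a.lj_epsilon,
                mass=a.mass,
                member_ids=[i],
            )
        )

    retained = RetainedBondedSet(
        angles=list(topology.angles),
        proper_dihedrals=list(topology.proper_dihedrals),
        improper_dihedrals=list(topology.improper_dihedrals),
    )
    springs: list[SpringTerm] = []
    if len(tiers) != len(topology.bonds):
        raise AssemblyError(f"{top_path}: bond tier annotations incomplete")
    for bond, tier in zip(topology.bonds, tiers):
        if tier == TIER_COVALENT:
            retained.bonds.append(bond)
        else:
            springs.append(SpringTerm(bond.i, bond.j, bond.r0, bond.k, tier))

    model = CanvasModel(
        beads=beads,
        retained=retained,
        springs=springs,
        exclusions=sorted((min(i, j), max(i, j)) for i, j in topology.exclusions),
        pairs14=sorted((min(i, j), max(i, j)) for i, j in topology.pairs14),
        box=structure.box,
        config=config,
        profile_id=profile_id,
        fudge_lj=topology.fudge_lj,
        fudge_qq=topology.fudge_qq,
        orig_atom_ids=list(range(1, len(beads) + 1)),
    )
    model.validate()
    return model


# --------------------------------------------------------------------------
# LAMMPS emission ("real" units: kcal/mol, Angstrom)
# --------------------------------------------------------------------------

def write_lammps(model: CanvasModel, outdir: str | os.PathLike, name: str = "canvas") -> dict[str, str]:
    """Emit a LAMMPS data file (atom_style full) and a settings file with
    per-type pair/bond/angle/dihedral/improper coefficients in real units."""
    os.makedirs(outdir, exist_ok=True)
    data_path = os.path.join(outdir, f"{name}.data")
    settings_path = os.path.join(outdir, f"{name}.settings")

    # deduplicated type tables
    atom_key = lambda b: (round(b.mass, 9), round(b.sigma, 12), round(b.epsilon, 12))
    atom_types: dict[tuple, int] = {}
    for b in model.beads:
        atom_types.setdefault(atom_key(b), len(atom_types) + 1)

    all_bonds = [(t.i, t.j, t.r0, t.k) for t in model.retained.bonds] + [
        (s.i, s.j, s.r0, s.k) for s in model.springs
    ]
    bond_types: dict[tuple, int] = {}
    for _, _, r0, k in all_bonds:
        bond_types.setdefault((round(r0, 12), round(k, 9)), len(bond_types) + 1)

    angle_types: dict[tuple, int] = {}
    for t in model.retained.angles:
        angle_types.setdefault((round(t.theta0, 9), round(t.k, 9)), len(angle_types) + 1)

    dih_types: dict[tuple, int] = {}
    for t in model.retained.proper_dihedrals:
        dih_types.setdefault(t.params, len(dih_types) + 1)

    imp_types: dict[tuple, int] = {}
    for t in model.retained.improper_dihedrals:
        imp_types.setdefault((t.funct, t.params), len(imp_types) + 1)

    box_a = model.box * units.A_PER_NM
    with open(data_path, "w") as fh:
        fh.write("CANVAS multiresolution model (real units)\n\n")
        fh.write(f"{model.n_beads} atoms\n")
        fh.write(f"{len(all_bonds)} bonds\n")
        fh.write(f"{len(model.retained.angles)} angles\n")
        fh.write(f"{len(model.retained.proper_dihedrals)} dihedrals\n")
        fh.write(f"{len(model.retained.improper_dihedrals)} impropers\n\n")
        fh.write(f"{len(atom_types)} atom types\n")
        fh.write(f"{len(bond_types)} bond types\n")
        fh.write(f"{len(angle_types)} angle types\n")
        fh.write(f"{len(dih_types)} dihedral types\n")
        fh.write(f"{len(imp_types)} improper types\n\n")
        fh.write(f"0.0 {box_a[0]:.6f} xlo xhi\n")
        fh.write(f"0.0 {box_a[1]:.6f} ylo yhi\n")
        fh.write(f"0.0 {box_a[2]:.6f} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for key, t in sorted(atom_types.items(), key=lambda kv: kv[1]):
            fh.write(f"{t} {key[0]:.6f}\n")
        fh.write("\nAtoms # full\n\n")
        for i, b in enumerate(model.beads, start=1):
            x, y, z = (np.asarray(b.coords) * units.A_PER_NM)
            fh.write(
                f"{i} {b.residue_id} {atom_types[atom_key(b)]} {b.charge:.6f} "
                f"{x:.6f} {y:.6f} {z:.6f}\n"
            )
        if all_bonds:
            fh.write("\nBonds\n\n")
            for n, (i, j, r0, k) in enumerate(all_bonds, start=1):
                t = bond_types[(round(r0, 12), round(k, 9))]
                fh.write(f"{n} {t} {i} {j}\n")
        if model.retained.angles:
            fh.write("\nAngles\n\n")
            for n, t in enumerate(model.retained.angles, start=1):
                tt = angle_types[(round(t.theta0, 9), round(t.k, 9))]
                fh.write(f"{n} {tt} {t.i} {t.j} {t.k_atom}\n")
        if model.retained.proper_dihedrals:
            fh.write("\nDihedrals\n\n")
            for n, t in enumerate(model.retained.proper_dihedrals, start=1):
                fh.write(f"{n} {dih_types[t.params]} {t.i} {t.j} {t.k_atom} {t.l_atom}\n")
        if model.retained.improper_dihedrals:
            fh.write("\nImpropers\n\n")
            for n, t in enumerate(model.retained.improper_dihedrals, start=1):
                fh.write(
                    f"{n} {imp_types[(t.funct, t.params)]} {t.i} {t.j} {t.k_atom} {t.l_atom}\n"
                )

    with open(settings_path, "w") as fh:
        rc_a = units.nm_to_angstrom(model.recommended_cutoff)
        fh.write("# CANVAS model coefficients, LAMMPS real units\n")
        fh.write("# nonbonded exclusions beyond special_bonds must be imposed separately\n")
        fh.write("units real\n")
        fh.write(f"pair_style lj/cut/coul/cut {rc_a:.6f}\n")
        for key, t in sorted(atom_types.items(), key=lambda kv: kv[1]):
            _, sigma, eps = key
            fh.write(
                f"pair_coeff {t} {t} {units.kj_to_kcal(eps):.9e} "
                f"{units.nm_to_angstrom(sigma):.9e}\n"
            )
        if bond_types:
            fh.write("bond_style harmonic\n")
            for (r0, k), t in sorted(bond_types.items(), key=lambda kv: kv[1]):
                fh.write(
                    f"bond_coeff {t} {units.bond_k_to_lammps(k):.9e} "
                    f"{units.nm_to_angstrom(r0):.9e}\n"
                )
        if angle_types:
            fh.write("angle_style harmonic\n")
            for (th0, k), t in sorted(angle_types.items(), key=lambda kv: kv[1]):
                fh.write(f"angle_coeff {t} {units.angle_k_to_lammps(k):.9e} {th0:.6f}\n")
        if dih_types:
            fh.write("dihedral_style charmm\n")
            for params, t in sorted(dih_types.items(), key=lambda kv: kv[1]):
                phi_s, k, n = params
                fh.write(
                    f"dihedral_coeff {t} {units.dihedral_k_to_lammps(k):.9e} "
                    f"{int(round(n))} {int(round(phi_s))} 0.0\n"
                )
        if imp_types:
            fh.write("improper_style harmonic\n")
            for (funct, params), t in sorted(imp_types.items(), key=lambda kv: kv[1]):
                xi0, k = params[0], params[1]
                fh.write(
                    f"improper_coeff {t} {units.improper_k_to_lammps(k):.9e} {xi0:.6f}\n"
                )
    return {"data": data_path, "settings": settings_path}
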