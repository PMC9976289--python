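"""Bonded interactions of the multiresolution model.

Two sources only. First, atomistic bonded terms (bonds, angles, proper
and improper dihedrals) survive unchanged whenever *all* of their member
atoms survive the decimation — a Heaviside selection over the input
topology; nothing is ever re-parametrized. Second, a three-tier network
of harmonic springs connects the coarse sites:

(1) a stiff spring k_b between the C-alphas of consecutive residues
    when at least one residue is coarse and no retained covalent bond
    already links survivors of the two residues (a surviving covalent
    bond always takes precedence over a spring);
(2) a distance-dependent spring k_nb(d) between nonconsecutive coarse
    C-alphas (CA_cg/CA_mg pairs) closer than the creation cutoff
    (1.4 nm), softer at larger separation;
(3) a soft interface spring k_if between an atomistic C-alpha and a
    nonconsecutive coarse C-alpha within the same cutoff.

Every spring's reference length is the pair distance in the starting
structure. Distance-based springs (tiers 2 and 3) are never created
across distinct structural domains of a user-supplied partition, which
preserves inter-domain flexibility in multidomain proteins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .config import CanvasConfig
from .resolution_mapper import AT, CellMap, ResolutionAssignment, SurvivorSet
from .structure_io import (
    AngleTerm,
    AtomisticTopology,
    BondTerm,
    DihedralTerm,
    Structure,
)

__all__ = [
    "TIER_CONSECUTIVE",
    "TIER_NONCONSECUTIVE",
    "TIER_INTERFACE",
    "SpringTerm",
    "KnbProfile",
    "DomainPartition",
    "RetainedBondedSet",
    "SpringError",
    "retain_atomistic_bonded",
    "knb_lookup",
    "build_spring_network",
    "build_exclusions",
]

TIER_CONSECUTIVE = "consecutive"
TIER_NONCONSECUTIVE = "nonconsecutive"
TIER_INTERFACE = "interface"


class SpringError(ValueError):
    pass


@dataclass(frozen=True)
class SpringTerm:
    i: int
    j: int
    r0: float  # nm, distance in the reference structure
    k: float  # kJ/mol/nm^2
    tier: str

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


class KnbProfile:
    """Distance dependence of the nonconsecutive spring constant.

    Either a parametric exponential decay k0 * exp(-(d - d_min)/lambda)
    (clamped at k0 below d_min) or a user-supplied table linearly
    interpolated between knots. The profile must be positive and
    non-increasing over (0, cutoff].
    """

    def __init__(self, kind: str, **params):
        self.kind = kind
        self.params = params
        if kind == "exponential":
            k0, lam = params["k0"], params["lam"]
            if k0 <= 0 or lam <= 0:
                raise SpringError("exponential profile needs k0 > 0 and lambda > 0")
        elif kind == "tabulated":
            d = np.asarray(params["distances"], dtype=float)
            k = np.asarray(params["values"], dtype=float)
            if d.ndim != 1 or d.shape != k.shape or len(d) < 2:
                raise SpringError("tabulated profile needs matching 1-d knot arrays")
            if np.any(np.diff(d) <= 0):
                raise SpringError("tabulated knots must be strictly increasing")
            if np.any(k <= 0):
                raise SpringError("tabulated k_nb values must be positive")
            if np.any(np.diff(k) > 0):
                raise SpringError("k_nb(d) must be non-increasing")
            self.params = {"distances": d, "values": k}
        else:
            raise SpringError(f"unknown profile kind {kind!r}")

    @classmethod
    def exponential(cls, k0: float, d_min: float, lam: float) -> "KnbProfile":
        return cls("exponential", k0=k0, d_min=d_min, lam=lam)

    @classmethod
    def tabulated(cls, distances, values) -> "KnbProfile":
        return cls("tabulated", distances=distances, values=values)

    @classmethod
    def from_config(cls, config: CanvasConfig) -> "KnbProfile":
        return cls.exponential(config.knb_k0, config.knb_dmin, config.knb_lambda)

    @classmethod
    def from_table_file(cls, path: str | os.PathLike) -> "KnbProfile":
        data = np.loadtxt(path, ndmin=2)
        return cls.tabulated(data[:, 0], data[:, 1])

    def __call__(self, d: float) -> float:
        if self.kind == "exponential":
            k0 = self.params["k0"]
            d_min = self.params["d_min"]
            lam = self.params["lam"]
            x = max(float(d) - d_min, 0.0)
            return float(k0 * np.exp(-x / lam))
        d_knots = self.params["distances"]
        k_knots = self.params["values"]
        return float(np.interp(d, d_knots, k_knots))

    def describe(self) -> str:
        if self.kind == "exponential":
            p = self.params
            return f"exp:{p['k0']:g}:{p['d_min']:g}:{p['lam']:g}"
        d, k = self.params["distances"], self.params["values"]
        return "table:" + ",".join(f"{a:g}@{b:g}" for a, b in zip(k, d))


def knb_lookup(profile: KnbProfile, d: float, cutoff: float = 1.4) -> float:
    """k_nb at separation *d*; *d* must lie inside (0, cutoff)."""
    if d <= 0 or d >= cutoff:
        raise SpringError(f"k_nb requested at d = {d} outside (0, {cutoff})")
    return profile(d)


class DomainPartition:
    """Residue -> rigid-domain label; default is one domain for everything."""

    def __init__(self, domains: dict[int, int] | None = None):
        self.domains = domains or {}

    def domain_of(self, residue_id: int) -> int:
        return self.domains.get(residue_id, 0)

    def same_domain(self, res_a: int, res_b: int) -> bool:
        return self.domain_of(res_a) == self.domain_of(res_b)

    @classmethod
    def from_file(cls, path: str | os.PathLike, structure: Structure) -> "DomainPartition":
        """One domain per line; tokens are residue ids or ``a-b`` ranges.

        A provided file must cover every residue of the structure
        exactly once.
        """
        domains: dict[int, int] = {}
        with open(path) as fh:
            label = 0
            for n, raw in enumerate(fh, start=1):
                text = raw.split("#", 1)[0].split(";", 1)[0].strip()
                if not text:
                    continue
                label += 1
                for token in text.replace(",", " ").split():
                    if "-" in token:
                        lo, hi = (int(t) for t in token.split("-", 1))
                        rng = range(lo, hi + 1)
                    else:
                        rng = range(int(token), int(token) + 1)
                    for rid in rng:
                        if rid in domains:
                            raise SpringError(
                                f"{path}, line {n}: residue {rid} in two domains"
                            )
                        domains[rid] = label
        missing = set(structure.residue_ids) - set(domains)
        if missing:
            raise SpringError(
                f"{path}: residues not assigned to any domain: {sorted(missing)}"
            )
        return cls(domains)


@dataclass
class RetainedBondedSet:
    """Atomistic terms that survive the decimation, parameters untouched."""

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    proper_dihedrals: list[DihedralTerm] = field(default_factory=list)
    improper_dihedrals: list[DihedralTerm] = field(default_factory=list)

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {b.pair for b in self.bonds}


def retain_atomistic_bonded(
    topology: AtomisticTopology, survivors: SurvivorSet
) -> RetainedBondedSet:
    """Heaviside selection: a term survives iff all of its atoms survive."""
    ids = set(survivors.atom_ids)
    keep = lambda term: all(aid in ids for aid in term.atom_ids)
    return RetainedBondedSet(
        bonds=[t for t in topology.bonds if keep(t)],
        angles=[t for t in topology.angles if keep(t)],
        proper_dihedrals=[t for t in topology.proper_dihedrals if keep(t)],
        improper_dihedrals=[t for t in topology.improper_dihedrals if keep(t)],
    )


def _ca_survivors(
    structure: Structure, survivors: SurvivorSet, assignment: ResolutionAssignment
) -> dict[int, int]:
    """residue_id -> atom_id of its surviving C-alpha.

    Every MG/CG residue must expose a CA survivor; an AT residue without
    a CA (e.g. a non-peptide group) simply takes no part in C-alpha
    springs.
    """
    cas: dict[int, int] = {}
    for s in survivors:
        atom = structure.atom(s.atom_id)
        if atom.name == "CA":
            cas[atom.residue_id] = s.atom_id
    for rid, lab in assignment.labels.items():
        if lab != AT and rid not in cas:
            raise SpringError(f"non-AT residue {rid} has no surviving C-alpha")
    return cas


def build_spring_network(
    structure: Structure,
    survivors: SurvivorSet,
    assignment: ResolutionAssignment,
    cellmap: CellMap,
    partition: DomainPartition | None = None,
    profile: KnbProfile | None = None,
    config: CanvasConfig | None = None,
    topology: AtomisticTopology | None = None,
) -> list[SpringTerm]:
    """Build the three spring tiers from the reference geometry.

    *topology* supplies the atomistic bond list used for covalent
    precedence; without it no pair is considered covalently linked.
    """
    config = config or CanvasConfig()
    profile = profile or KnbProfile.from_config(config)
    partition = partition or DomainPartition()
    cutoff = config.spring_cutoff

    springs: list[SpringTerm] = []
    seen_pairs: set[tuple[int, int]] = set()

    def dist(a: int, b: int) -> float:
        return float(
            np.linalg.norm(structure.atom(a).coords - structure.atom(b).coords)
        )

    cas = _ca_survivors(structure, survivors, assignment)
    chain_of = {a.residue_id: a.chain_id for a in structure.atoms}

    # ---- tier 1: consecutive residues ------------------------------------
    res_ids = structure.residue_ids
    surv_by_res: dict[int, list[int]] = {}
    for s in survivors:
        surv_by_res.setdefault(structure.atom(s.atom_id).residue_id, []).append(
            s.atom_id
        )
    covalent_pairs = _retained_covalent_pairs(topology, survivors)
    for ra, rb in zip(res_ids, res_ids[1:]):
        if rb != ra + 1 or chain_of[ra] != chain_of[rb]:
            continue  # chain break: never consecutive
        la, lb = assignment.labels[ra], assignment.labels[rb]
        if la == AT and lb == AT:
            continue
        linked = any(
            (min(i, j), max(i, j)) in covalent_pairs
            for i in surv_by_res.get(ra, [])
            for j in surv_by_res.get(rb, [])
        )
        if linked:
            continue  # the surviving covalent bond replaces the spring
        if ra not in cas or rb not in cas:
            raise SpringError(
                f"cannot place consecutive spring: residue {ra} or {rb} lacks a C-alpha"
            )
        i, j = cas[ra], cas[rb]
        pair = (min(i, j), max(i, j))
        springs.append(SpringTerm(*pair, r0=dist(i, j), k=config.k_b, tier=TIER_CONSECUTIVE))
        seen_pairs.add(pair)

    # ---- tiers 2 and 3: nonconsecutive C-alpha pairs within the cutoff ----
    ca_res = sorted(cas)
    ca_ids = [cas[r] for r in ca_res]
    coords = np.array([structure.atom(i).coords for i in ca_ids])
    if len(ca_ids) > 1:
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(coords))
        for a in range(len(ca_ids)):
            for b in range(a + 1, len(ca_ids)):
                ra, rb = ca_res[a], ca_res[b]
                consecutive = abs(ra - rb) == 1 and chain_of[ra] == chain_of[rb]
                if consecutive:
                    continue
                la, lb = assignment.labels[ra], assignment.labels[rb]
                if la == AT and lb == AT:
                    continue
                d = float(dmat[a, b])
                if not d < cutoff:
                    continue
                if not partition.same_domain(ra, rb):
                    continue
                pair = (min(ca_ids[a], ca_ids[b]), max(ca_ids[a], ca_ids[b]))
                if pair in seen_pairs or pair in covalent_pairs:
                    continue
                if la != AT and lb != AT:
                    k = knb_lookup(profile, d, cutoff)
                    if k > config.k_b:
                        raise SpringError("k_nb profile exceeds k_b")
                    tier = TIER_NONCONSECUTIVE
                else:
                    k = config.k_if
                    tier = TIER_INTERFACE
                springs.append(SpringTerm(*pair, r0=d, k=k, tier=tier))
                seen_pairs.add(pair)

    if len(seen_pairs) != len(springs):
        raise SpringError("duplicate spring pair produced")
    return springs


def _retained_covalent_pairs(
    topology: AtomisticTopology | None, survivors: SurvivorSet
) -> set[tuple[int, int]]:
    if topology is None:
        return set()
    ids = set(survivors.atom_ids)
    return {b.pair for b in topology.bonds if b.i in ids and b.j in ids}


def build_exclusions(
    retained: RetainedBondedSet,
    springs: list[SpringTerm],
    topology: AtomisticTopology,
    survivors: SurvivorSet,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Nonbonded exclusions and rescaled 1-4 pairs of the coarse model.

    The atomistic exclusion and 1-4 lists survive only between pairs of
    all-atom survivors; rescaled 1-4 interactions exist solely in the AT
    region. Retained covalent bonds and consecutive (k_b) springs are
    excluded like chemical bonds. Pairs linked only by distance-based
    k_nb/k_if springs keep their full nonbonded interaction alongside
    the spring.
    """
    at_ids = {s.atom_id for s in survivors if s.label == AT}
    excl: set[tuple[int, int]] = set()
    for i, j in topology.exclusions:
        if i in at_ids and j in at_ids:
            excl.add((min(i, j), max(i, j)))
    pairs14 = sorted(
        {(min(i, j), max(i, j)) for i, j in topology.pairs14 if i in at_ids and j in at_ids}
    )
    excl.update(p for p in pairs14)
    excl.update(b.pair for b in retained.bonds)
    excl.update(s.pair for s in springs if s.tier == TIER_CONSECUTIVE)
    return sorted(excl), pairs14
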