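"""Single-point energy of the multiresolution model.

A verification surface, not an MD engine: evaluates the four-term
potential — retained atomistic bonded terms (E_AA), the harmonic spring
network (E_harmonic), 12-6 Lennard-Jones with Lorentz-Berthelot
combination (E_VdW), and Coulomb electrostatics under either a plain
cutoff or the Barker-Watts reaction field with dielectric 80
(E_coulomb) — on one set of bead coordinates.

Conventions: harmonic bonds and angles are V = 1/2 k (x - x0)^2 (the
GROMACS functional form, in which k_b = 5e4 kJ/mol/nm^2 is meaningful);
periodic torsions are k (1 + cos(n phi - phi_s)). No periodic-image
wrapping is applied — the model targets a single whole molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_writers import CanvasModel
from .units import F_COULOMB

__all__ = ["EnergyBreakdown", "single_point_energy"]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies in kJ/mol; ``total`` is their exact sum."""

    e_aa: float
    e_harmonic: float
    e_vdw: float
    e_coulomb: float

    @property
    def total(self) -> float:
        return self.e_aa + self.e_harmonic + self.e_vdw + self.e_coulomb

    def __str__(self) -> str:
        return (
            f"E_AA       = {self.e_aa:14.6f} kJ/mol\n"
            f"E_harmonic = {self.e_harmonic:14.6f} kJ/mol\n"
            f"E_VdW      = {self.e_vdw:14.6f} kJ/mol\n"
            f"E_coulomb  = {self.e_coulomb:14.6f} kJ/mol\n"
            f"total      = {self.total:14.6f} kJ/mol"
        )


def _dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in radians (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def _angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _bonded_energy(model: CanvasModel, xyz: np.ndarray) -> tuple[float, float]:
    e_aa = 0.0
    for t in model.retained.bonds:
        r = np.linalg.norm(xyz[t.i - 1] - xyz[t.j - 1])
        e_aa += 0.5 * t.k * (r - t.r0) ** 2
    for t in model.retained.angles:
        th = _angle(xyz[t.i - 1], xyz[t.j - 1], xyz[t.k_atom - 1])
        e_aa += 0.5 * t.k * (th - np.deg2rad(t.theta0)) ** 2
    for t in model.retained.proper_dihedrals:
        phi_s, k, n = t.params
        phi = _dihedral_angle(
            xyz[t.i - 1], xyz[t.j - 1], xyz[t.k_atom - 1], xyz[t.l_atom - 1]
        )
        e_aa += k * (1.0 + np.cos(n * phi - np.deg2rad(phi_s)))
    for t in model.retained.improper_dihedrals:
        xi = _dihedral_angle(
            xyz[t.i - 1], xyz[t.j - 1], xyz[t.k_atom - 1], xyz[t.l_atom - 1]
        )
        if t.funct == 2:
            xi0, k = t.params
            dxi = xi - np.deg2rad(xi0)
            # wrap into (-pi, pi] so near-planar impropers stay harmonic
            dxi = (dxi + np.pi) % (2 * np.pi) - np.pi
            e_aa += 0.5 * k * dxi**2
        else:  # funct 4: periodic improper
            phi_s, k, n = t.params
            e_aa += k * (1.0 + np.cos(n * xi - np.deg2rad(phi_s)))
    e_harm = 0.0
    for s in model.springs:
        r = np.linalg.norm(xyz[s.i - 1] - xyz[s.j - 1])
        e_harm += 0.5 * s.k * (r - s.r0) ** 2
    return float(e_aa), float(e_harm)


def single_point_energy(
    model: CanvasModel,
    coords: np.ndarray | None = None,
    coulomb: str = "reaction-field",
    cutoff: float | None = None,
) -> EnergyBreakdown:
    """Evaluate the potential at *coords* (default: the model's reference
    coordinates).

    *coulomb* selects ``"reaction-field"`` (Barker-Watts, dielectric
    from the model config, zero at the cutoff) or ``"cutoff"`` (plain
    truncation). The van der Waals term is always plainly truncated at
    *cutoff* (default: the model's recommended 2.5*sigma_max cutoff).
    Rescaled 1-4 pairs are evaluated with plain Coulomb and the fudge
    factors carried by the model.
    """
    xyz = model.coords_array() if coords is None else np.asarray(coords, dtype=float)
    if xyz.shape != (model.n_beads, 3):
        raise ValueError(
            f"coords shape {xyz.shape} does not match {model.n_beads} beads"
        )
    if coulomb not in ("reaction-field", "cutoff"):
        raise ValueError(f"unknown coulomb scheme {coulomb!r}")
    rc = model.recommended_cutoff if cutoff is None else float(cutoff)
    if rc <= 0:
        raise ValueError("cutoff must be positive")

    e_aa, e_harm = _bonded_energy(model, xyz)

    n = model.n_beads
    q = np.array([b.charge for b in model.beads])
    sig = np.array([b.sigma for b in model.beads])
    eps = np.array([b.epsilon for b in model.beads])

    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(n, k=1)
    rr = r[iu]

    excluded = np.zeros(len(rr), dtype=bool)
    if model.exclusions:
        pair_index = {(i, j): idx for idx, (i, j) in enumerate(zip(iu[0] + 1, iu[1] + 1))}
        for i, j in model.exclusions:
            excluded[pair_index[(min(i, j), max(i, j))]] = True

    within = (rr < rc) & (rr > 0) & ~excluded
    sij = 0.5 * (sig[iu[0]] + sig[iu[1]])
    eij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    qq = q[iu[0]] * q[iu[1]]

    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(within, (sij / np.where(rr > 0, rr, 1.0)) ** 6, 0.0)
    e_vdw = float(np.sum(4.0 * eij * (sr6**2 - sr6) * within))

    if coulomb == "reaction-field":
        eps_rf = model.epsilon_rf
        k_rf = (eps_rf - 1.0) / (2.0 * eps_rf + 1.0) / rc**3
        c_rf = 1.0 / rc + k_rf * rc**2
        with np.errstate(divide="ignore"):
            pot = np.where(within, 1.0 / np.where(rr > 0, rr, 1.0) + k_rf * rr**2 - c_rf, 0.0)
    else:
        with np.errstate(divide="ignore"):
            pot = np.where(within, 1.0 / np.where(rr > 0, rr, 1.0), 0.0)
    e_coul = float(F_COULOMB * np.sum(qq * pot))

    # rescaled 1-4 pairs: plain interactions with fudge factors
    for i, j in model.pairs14:
        rij = float(np.linalg.norm(xyz[i - 1] - xyz[j - 1]))
        if rij <= 0:
            continue
        s14 = 0.5 * (sig[i - 1] + sig[j - 1])
        e14 = np.sqrt(eps[i - 1] * eps[j - 1])
        sr6 = (s14 / rij) ** 6
        e_vdw += model.fudge_lj * 4.0 * e14 * (sr6**2 - sr6)
        e_coul += model.fudge_qq * F_COULOMB * q[i - 1] * q[j - 1] / rij

    return EnergyBreakdown(e_aa=e_aa, e_harmonic=e_harm, e_vdw=e_vdw, e_coulomb=e_coul)
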