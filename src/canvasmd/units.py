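"""Unit conversions between GROMACS-style (kJ/mol, nm, deg) and LAMMPS
"real" units (kcal/mol, Angstrom, deg).

Harmonic prefactor conventions differ between the engines: GROMACS
bond/angle potentials are V = 1/2 k (x - x0)^2 while LAMMPS harmonic
styles are V = K (x - x0)^2, so K = k/2 in addition to the unit change.
"""

from __future__ import annotations

KJ_PER_KCAL = 4.184
A_PER_NM = 10.0

# Coulomb conversion factor 1/(4 pi eps0) in kJ mol^-1 nm e^-2
F_COULOMB = 138.935458


def kj_to_kcal(e: float) -> float:
    return e / KJ_PER_KCAL


def kcal_to_kj(e: float) -> float:
    return e * KJ_PER_KCAL


def nm_to_angstrom(x: float) -> float:
    return x * A_PER_NM


def angstrom_to_nm(x: float) -> float:
    return x / A_PER_NM


def bond_k_to_lammps(k: float) -> float:
    """kJ/mol/nm^2 (1/2 k convention) -> kcal/mol/A^2 (K convention)."""
    return k / KJ_PER_KCAL / A_PER_NM**2 / 2.0


def bond_k_from_lammps(K: float) -> float:
    return K * KJ_PER_KCAL * A_PER_NM**2 * 2.0


def angle_k_to_lammps(k: float) -> float:
    """kJ/mol/rad^2 (1/2 k) -> kcal/mol/rad^2 (K)."""
    return k / KJ_PER_KCAL / 2.0


def angle_k_from_lammps(K: float) -> float:
    return K * KJ_PER_KCAL * 2.0


def dihedral_k_to_lammps(k: float) -> float:
    """Periodic torsion barrier: kJ/mol -> kcal/mol (same 1+cos form)."""
    return k / KJ_PER_KCAL


def dihedral_k_from_lammps(K: float) -> float:
    return K * KJ_PER_KCAL


def improper_k_to_lammps(k: float) -> float:
    """Harmonic improper: kJ/mol/rad^2 (1/2 k) -> kcal/mol/rad^2 (K)."""
    return k / KJ_PER_KCAL / 2.0


def improper_k_from_lammps(K: float) -> float:
    return K * KJ_PER_KCAL * 2.0
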