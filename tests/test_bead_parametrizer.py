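"""Bead parameters: cell charge sums, 2*Rg diameters, geometric-mean
epsilon, mass conservation, and rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canvasmd import (
    assign_resolution,
    parametrize_beads,
    select_survivors,
    voronoi_assign,
)
from canvasmd.bead_parametrizer import (
    bead_charge,
    bead_epsilon,
    bead_mass,
    bead_sigma,
)
from canvasmd.resolution_mapper import ResolutionAssignment, CG
from canvasmd.structure_io import AtomRecord, Structure


def atom(aid, coords, q=0.0, sigma=0.3, eps=0.4, mass=12.0):
    return AtomRecord(
        atom_id=aid, name="X", residue_id=1, residue_name="ALA",
        coords=np.asarray(coords, dtype=float),
        charge=q, mass=mass, lj_sigma=sigma, lj_epsilon=eps,
    )


class TestPerPropertyRules:
    def test_charge_is_algebraic_sum(self):
        cell = [atom(1, [0, 0, 0], q=0.5), atom(2, [1, 0, 0], q=-0.5),
                atom(3, [0, 1, 0], q=0.1)]
        assert bead_charge(cell) == pytest.approx(0.1)
        assert bead_charge([atom(1, [0, 0, 0], q=0.0)]) == 0.0

    def test_sigma_symmetric_pair(self):
        cell = [atom(1, [0, 0, 0]), atom(2, [0.2, 0, 0])]
        assert bead_sigma(cell) == pytest.approx(0.2)

    def test_sigma_three_collinear(self):
        # Rg^2 = mean of squared deviations from the centroid = 0.02/3
        cell = [atom(1, [0, 0, 0]), atom(2, [0.1, 0, 0]), atom(3, [0.2, 0, 0])]
        expected = 2 * np.sqrt(0.02 / 3)
        assert bead_sigma(cell) == pytest.approx(expected, rel=1e-12)
        assert bead_sigma(cell) == pytest.approx(0.1633, abs=5e-5)

    def test_sigma_singleton_falls_back_to_atomistic(self):
        assert bead_sigma([atom(1, [0, 0, 0], sigma=0.271)]) == pytest.approx(0.271)

    @pytest.mark.parametrize(
        "eps_values, expected",
        [([0.4, 0.1], 0.2), ([0.3], 0.3), ([0.2, 0.2, 0.2], 0.2), ([0.5, 0.0], 0.0)],
    )
    def test_epsilon_geometric_mean(self, eps_values, expected):
        cell = [atom(i, [i * 0.1, 0, 0], eps=e) for i, e in enumerate(eps_values, 1)]
        assert bead_epsilon(cell) == pytest.approx(expected, rel=1e-12)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            bead_epsilon([atom(1, [0, 0, 0], eps=-0.1)])

    def test_mass_is_sum(self):
        cell = [atom(1, [0, 0, 0], mass=12.011), atom(2, [0.1, 0, 0], mass=1.008),
                atom(3, [0, 0.1, 0], mass=1.008)]
        assert bead_mass(cell) == pytest.approx(14.027)


def _pipeline(structure, at_residues=None, labels=None):
    if labels is not None:
        assignment = ResolutionAssignment(labels)
    else:
        assignment = assign_resolution(structure, at_residues)
    survivors = select_survivors(structure, assignment)
    cellmap = voronoi_assign(structure, survivors)
    return survivors, cellmap, parametrize_beads(structure, survivors, cellmap)


class TestParametrizeBeads:
    def test_full_at_beads_identical_to_atoms(self, penta):
        structure, _, _ = penta
        _, _, beads = _pipeline(structure, set(structure.residue_ids))
        assert len(beads) == structure.n_atoms
        for b, a in zip(beads, structure.atoms):
            assert b.charge == a.charge
            assert b.sigma == a.lj_sigma
            assert b.epsilon == a.lj_epsilon
            assert b.mass == a.mass
            assert b.member_ids == [a.atom_id]

    def test_cg_beads_match_independent_recomputation(self, tripeptide):
        structure, _, _ = tripeptide
        _, cellmap, beads = _pipeline(
            structure, labels={r: CG for r in structure.residue_ids}
        )
        for bead in beads:
            cell = [structure.atom(i) for i in cellmap.members[bead.atom_id]]
            # straight re-evaluation of the defining formulas
            assert bead.charge == pytest.approx(sum(a.charge for a in cell), abs=1e-12)
            coords = np.array([a.coords for a in cell])
            rg = np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1)))
            assert bead.sigma == pytest.approx(2 * rg, rel=1e-10)
            log_eps = np.mean([np.log(a.lj_epsilon) for a in cell])
            assert bead.epsilon == pytest.approx(np.exp(log_eps), rel=1e-10)
            assert bead.mass == pytest.approx(sum(a.mass for a in cell), rel=1e-12)

    def test_charge_and_mass_conservation(self, peptide40):
        structure, _, _ = peptide40
        _, _, beads = _pipeline(structure, {1, 2})
        total_q = sum(a.charge for a in structure.atoms)
        total_m = sum(a.mass for a in structure.atoms)
        assert abs(sum(b.charge for b in beads) - total_q) < 1e-9
        assert abs(sum(b.mass for b in beads) - total_m) < 1e-9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_rigid_motion_invariance(self, tripeptide, shift, angle):
        """Translating + rotating the structure changes no bead parameter."""
        structure, _, _ = tripeptide
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = Structure(
            [
                AtomRecord(
                    a.atom_id, a.name, a.residue_id, a.residue_name,
                    rot @ a.coords + np.asarray(shift),
                    charge=a.charge, mass=a.mass,
                    lj_sigma=a.lj_sigma, lj_epsilon=a.lj_epsilon,
                )
                for a in structure.atoms
            ],
            box=structure.box + 10.0,
        )
        labels = {r: CG for r in structure.residue_ids}
        _, _, beads0 = _pipeline(structure, labels=labels)
        _, _, beads1 = _pipeline(moved, labels=labels)
        for b0, b1 in zip(beads0, beads1):
            assert b0.charge == pytest.approx(b1.charge, abs=1e-12)
            assert b0.sigma == pytest.approx(b1.sigma, abs=1e-9)
            assert b0.epsilon == pytest.approx(b1.epsilon, abs=1e-12)
            assert b0.mass == pytest.approx(b1.mass, abs=1e-12)

    def test_file_order_permutation_invariance(self, tripeptide):
        """Reversing atom file order (ids remapped consistently) leaves
        bead parameters unchanged."""
        structure, _, _ = tripeptide
        n = structure.n_atoms
        remap = {a.atom_id: n - i for i, a in enumerate(structure.atoms)}
        reversed_atoms = [
            AtomRecord(
                remap[a.atom_id], a.name, a.residue_id, a.residue_name,
                a.coords.copy(), charge=a.charge, mass=a.mass,
                lj_sigma=a.lj_sigma, lj_epsilon=a.lj_epsilon,
            )
            for a in reversed(structure.atoms)
        ]
        permuted = Structure(reversed_atoms, box=structure.box)
        labels = {r: CG for r in structure.residue_ids}
        _, _, beads0 = _pipeline(structure, labels=labels)
        _, _, beads1 = _pipeline(permuted, labels=labels)
        by_res0 = {b.residue_id: b for b in beads0}
        by_res1 = {b.residue_id: b for b in beads1}
        for rid in by_res0:
            b0, b1 = by_res0[rid], by_res1[rid]
            assert b0.charge == pytest.approx(b1.charge, abs=1e-12)
            assert b0.sigma == pytest.approx(b1.sigma, abs=1e-12)
            assert b0.epsilon == pytest.approx(b1.epsilon, abs=1e-12)
            assert b0.mass == pytest.approx(b1.mass, abs=1e-12)
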