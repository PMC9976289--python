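import numpy as np
import pytest

from canvasmd import assign_resolution, build_model
from canvasmd.fixtures import FixtureSpec, make_peptide


@pytest.fixture(scope="session")
def penta():
    """5-residue synthetic peptide: (structure, topology, ground_truth)."""
    return make_peptide(FixtureSpec(n_residues=5, seed=7))


@pytest.fixture(scope="session")
def tripeptide():
    return make_peptide(FixtureSpec(n_residues=3, seed=1))


@pytest.fixture(scope="session")
def peptide40():
    """Larger fixture (~440 atoms) for Voronoi / conservation checks."""
    return make_peptide(FixtureSpec(n_residues=40, seed=11))


@pytest.fixture(scope="session")
def mixed_model(penta):
    """AT core (residues 1-2), automatic MG/CG for the rest."""
    structure, topology, _ = penta
    assignment = assign_resolution(structure, {1, 2})
    return build_model(structure, topology, assignment)


def brute_force_min_residue_distance(structure, residue_id, at_residues):
    """Exhaustive min atom-atom distance from one residue to the AT region."""
    at_coords = np.array(
        [structure.atom(i).coords for r in at_residues
         for i in structure.residue_atom_ids(r)]
    )
    res_coords = np.array(
        [structure.atom(i).coords for i in structure.residue_atom_ids(residue_id)]
    )
    return min(
        float(np.linalg.norm(a - b)) for a in res_coords for b in at_coords
    )
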