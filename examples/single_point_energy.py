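"""Evaluate the four-term potential energy of a freshly built model.

At the reference structure every spring sits at its rest length, so the
harmonic term is exactly zero; displacing one bead shows the quadratic
spring response.
"""

import numpy as np

from canvasmd import assign_resolution, build_model
from canvasmd.energy_oracle import single_point_energy
from canvasmd.fixtures import FixtureSpec, make_peptide

structure, topology, _ = make_peptide(FixtureSpec(n_residues=8, seed=1))
model = build_model(structure, topology, assign_resolution(structure, {1, 2}))

print("single-point energy at the reference structure:")
print(single_point_energy(model))
# E_harmonic = 0 here because every spring's reference length is the
# pair distance in this very structure.

# quadratic response on a minimal two-residue coarse model whose single
# spring makes the prediction exact
from canvasmd.resolution_mapper import CG, ResolutionAssignment

s2, t2, _ = make_peptide(FixtureSpec(n_residues=2, seed=1))
m2 = build_model(s2, t2, ResolutionAssignment({1: CG, 2: CG}))
(spring,) = m2.springs
xyz = m2.coords_array()
axis = xyz[spring.j - 1] - xyz[spring.i - 1]
axis /= np.linalg.norm(axis)
delta = 0.01  # nm
xyz[spring.j - 1] += delta * axis
perturbed = single_point_energy(m2, coords=xyz)
print(f"\ntwo-bead model, one {spring.tier} spring stretched by {delta} nm:")
print(f"E_harmonic = {perturbed.e_harmonic:.6f} kJ/mol "
      f"(= 1/2 k delta^2 = {0.5 * spring.k * delta**2:.6f})")
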