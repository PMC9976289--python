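# Methods

## Model and assumptions

The package builds a static, three-level multiresolution representation
of a single biomolecule from one reference conformation. The resolution
assignment is time-independent: the AT/MG/CG split is chosen once and
the model never adapts it. Because the atom-to-bead map is a Voronoi
tessellation of the *reference* coordinates, the quality of the model
depends on that structure being minimized and equilibrated; side-chain
orientations in the reference directly shape the cells, and the spring
network (rest lengths = reference distances) biases the model toward the
reference arrangement of secondary elements. Large conformational
changes are only possible across domain boundaries declared in the
partition file, where no distance-based springs are created.

No periodic-image wrapping is applied anywhere: coordinates are taken as
they stand in the input, on the assumption of a single whole molecule in
the box. This is a documented contract of both the builder and the
energy evaluator, not a limitation discovered downstream.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `k_b` | 5·10⁴ | kJ·mol⁻¹·nm⁻² | stiff spring between consecutive-residue C-alphas involving a coarse bead |
| `k_if` | 50 | kJ·mol⁻¹·nm⁻² | soft spring between an AT C-alpha and a nonconsecutive coarse C-alpha |
| `spring_cutoff` | 1.4 | nm | creation threshold (strict `<`) for the two distance-based tiers |
| `mg_shell` | 1.0 | nm | automatic MG shell: min atom–atom distance to the AT region, strict `<` |
| `knb_k0`, `knb_dmin`, `knb_lambda` | 10⁴, 0.4, 0.5 | kJ·mol⁻¹·nm⁻², nm, nm | default k_nb(d) profile (below) |
| `epsilon_rf` | 80 | – | reaction-field dielectric |
| `cutoff_factor` | 2.5 | – | recommended nonbonded cutoff = 2.5·σ_max |

**The k_nb(d) profile.** The only hard constraints on the
nonconsecutive spring constant are that it decays with the C-alpha
separation, stays positive up to the 1.4 nm cutoff, and never exceeds
k_b. The default is an exponential decay
k_nb(d) = k0·exp(−(d − d_min)/λ), clamped at k0 below d_min = 0.4 nm
(roughly the consecutive C-alpha spacing, below which no nonconsecutive
pair occurs in practice). k0 = 10⁴ kJ·mol⁻¹·nm⁻² places the stiffest
nonconsecutive contact a factor 5 below the covalent-scale k_b, and
λ = 0.5 nm leaves k_nb(1.4) ≈ 1.4·10³, still a meaningful restraint at
the cutoff. These are modelling defaults, not fitted values; any
profile derived from reference simulations can be supplied as a
two-column table (`--knb-table`, linearly interpolated) and overrides
the parametric form.

## Design choices where the design was open

- **Voronoi candidates are the MG/CG survivors only.** Decimated atoms
  exist only in coarse regions, but near a region boundary their
  nearest survivor could be an atomistic atom. Absorbing them there
  would either corrupt the pristine AT parameters or delete charge and
  mass from the model. Restricting candidate sites to coarse survivors
  keeps AT beads exactly atomistic and makes total charge and mass
  conservation exact identities.
- **Tie-breaking.** An atom exactly equidistant (within 10⁻⁹ nm) from
  two candidate survivors joins the one with the lower atom id:
  deterministic and independent of file order.
- **Survivor's own cell.** Each survivor is a member of its own cell, so
  the charge/size/dispersion averages include it; hydrogens in coarse
  regions are decimated and averaged like heavy atoms.
- **Single-member cells** have zero gyration radius; the bead falls back
  to the survivor's atomistic σ (its ε already comes out of the
  geometric mean) rather than emitting a zero-diameter particle with no
  steric volume.
- **"Consecutive"** means residue ids adjacent within the same chain;
  chain breaks are never consecutive. The k_b spring connects the two
  C-alphas, and only when no retained covalent bond already links
  survivors of the two residues — so MG–MG and AT–MG neighbours keep
  their C–N peptide bond instead of a spring, while any pair involving
  a CG residue (whose backbone C/N were decimated) is spring-linked.
- **Exclusion bookkeeping.** Atomistic exclusion and 1–4 pair lists
  survive only between AT survivors; rescaled 1–4 interactions exist
  solely in the AT region, with the fudge factors read from the input
  topology's `[defaults]`. Retained covalent bonds and k_b springs are
  excluded like chemical bonds. Pairs linked only by distance-based
  springs keep their full nonbonded interaction. A consequence worth
  knowing: coarse backbone sites have no 1–3 exclusions, so a
  single-point energy of a freshly built model can show a large
  positive E_VdW from overlapping bonded neighbours — this is a feature
  of the interaction bookkeeping, not a bug in the evaluator.
- **Harmonic convention** is V = ½k(r − r0)² throughout (the GROMACS
  bond-function-1 form, in which the k_b value is meaningful). LAMMPS
  `harmonic` styles use K(x − x0)², so emitted LAMMPS coefficients are
  K = k/2 after the kJ/nm → kcal/Å unit change; all conversions are
  invertible and tested bidirectionally.
- **Bead typing in the writers**: one synthetic type per distinct
  (mass, σ, ε) tuple for coarse beads (`CVS1`, `CVS2`, …); AT beads keep
  their original type names, disambiguated if the same name ever
  carries different parameters.
- **Reaction field** uses the standard Barker–Watts form with the
  potential shifted to zero at the cutoff.

## Input dialects

Coordinates are fixed-width `.gro` (nm, three decimals). Topologies are
a restricted GROMACS dialect: `[defaults]`, `[atomtypes]` (σ/ε or,
under combination rule 1, c6/c12 converted on read), `[moleculetype]`,
`[atoms]`, `[bonds]` (function 1), `[pairs]`, `[angles]` (function 1),
`[dihedrals]` (functions 1/9 periodic, 2 harmonic improper, 4 periodic
improper), `[exclusions]`, with explicit inline parameters and at most
one literal `#include` level. Anything outside this grammar fails
loudly — a silently misparsed force field is worse than a rejection.
Chains are not encoded in `.gro`, so multi-chain inputs with repeated
residue ids are out of scope; residue-id gaps act as chain breaks for
the consecutive rule.

## The synthetic-data generator

All tests run on generated peptides: a zig-zag backbone with exact
0.38 nm consecutive C-alpha spacing, a 0.15 nm peptide C–N link, and
synthetic 3–7-atom side-chain stubs whose charges, LJ parameters and
small seeded jitter give heterogeneous, tie-free Voronoi cells. Bond
and angle reference values equal the generated geometry (so bonded
energies vanish at the reference), torsion parameters do not (so the
dihedral machinery is exercised with nonzero energies). Exclusions and
1–4 pairs follow the three-bond convention on the bond graph. The
planted-distance variant rigidly translates whole residues along
well-separated directions until a C-alpha–C-alpha or minimum atom–atom
distance hits its target to 10⁻⁶ nm (bracketed root-finding), which is
what makes exact threshold tests at 1.4 nm and 1.0 nm possible;
infeasible target sets are detected and rejected.

What the generator does **not** emulate: real amino-acid chemistry and
rotamers, hydrogens bonded with constraint algorithms, multiple chains,
solvent, and force-field-specific parameter correlations. Passing tests
therefore demonstrate the correctness of the construction rules and the
file formats, not the thermodynamic fidelity of any particular coarse
model of a real protein.

## Problem sizes and numerics

The suite checks the Voronoi map against a brute-force nearest-survivor
scan on fixtures up to ~500 atoms, and the spring network against an
independent O(N²) rule evaluation on 60–80-residue fixtures (the rules
are size-independent; these sizes exercise every branch, including the
two-domain geometry). Charge/mass conservation is asserted to 10⁻⁹,
spring-energy identities to 10⁻⁸ relative, and writer round trips to
the precision each format carries (coordinates: 10⁻³ nm from the .gro
fixed width; parameters: ~10⁻⁹ relative from the `%.9e` fields). The
acceptance script scans the MG shell on a 0.01 nm grid from 0.8 to
1.2 nm; with the strict `<` threshold the reported midpoint between the
last MG and first CG probe is 0.995 nm.

## Known limitations

- Springs are emitted as plain harmonic bonds; engines that cannot
  express per-pair exclusions beyond `special_bonds` (LAMMPS) need the
  exclusion list imposed separately, as noted in the settings file.
- The energy evaluator is a verification surface: O(N²) nonbonded
  loops, no forces, no minimization, no PBC.
- Solvation, ions, and run control beyond the advisory `.mdp` template
  are out of scope.
- Automatic rigid-domain decomposition is not provided; the partition
  file is the user's statement of domain knowledge.
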