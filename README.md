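# canvasmd

Builder for **three-level multiresolution protein models**: part of a
biomolecule is kept at full atomistic (AT) detail, a surrounding shell is
medium-grained (MG, backbone atoms N/CA/C/O only), and the remainder is
coarse-grained (CG, one C-alpha bead per residue). The output is a
simulation-ready model — beads with effective nonbonded parameters,
retained atomistic bonded terms, and a harmonic spring network — emitted
as GROMACS (`.top`/`.gro`/`.mdp`) or LAMMPS (data + settings) input
files, with a built-in single-point energy evaluator for verification.

It is aimed at structural-bioinformatics and molecular-simulation users
who want chemical detail only where it matters (a binding site, a hinge)
while the rest of the protein is represented cheaply but still
mechanically coupled.

## The model

Starting from an equilibrated all-atom structure, its topology, and a
per-residue resolution request, construction proceeds in four steps.

**Decimation and Voronoi mapping.** AT residues keep all atoms, MG
residues keep the four backbone atoms, CG residues keep the C-alpha.
Every decimated atom is assigned to its nearest surviving coarse site by
Euclidean distance in the reference coordinates (a Voronoi tessellation);
cells freely cross residue boundaries. If the MG region is not given
explicitly, every non-AT residue whose minimum atom–atom distance to the
AT region is below 1 nm becomes MG, the rest CG.

**Bead parameters.** For a bead *I* representing cell members *i*:

- charge: Q_I = Σ q_i (algebraic sum)
- diameter: σ_I = 2 R_g, with R_g² = (1/n) Σ |r_i − r_cog|² about the
  unweighted centre of geometry
- dispersion: ε_I = (Π ε_i)^(1/n) (geometric mean)
- mass: Σ m_i (total mass conserved)

AT beads keep their pristine force-field parameters. Inter-bead
Lennard-Jones interactions follow the Lorentz–Berthelot rules inherited
from the atomistic force field.

**Bonded terms.** Atomistic bonds, angles and proper/improper dihedrals
survive unchanged iff *all* their member atoms survive (a Heaviside
selection — nothing is re-parametrized). On top of that, three spring
tiers connect the coarse sites, each with its reference length taken
from the starting structure:

1. **k_b = 5·10⁴ kJ·mol⁻¹·nm⁻²** between C-alphas of consecutive
   residues when at least one is coarse and no retained covalent bond
   already links the two residues (a surviving covalent bond always
   takes precedence);
2. **k_nb(d)** between nonconsecutive coarse C-alphas closer than
   **1.4 nm**, decaying with distance (configurable profile, tabulated
   or exponential);
3. **k_if = 50 kJ·mol⁻¹·nm⁻²** between an atomistic C-alpha and a
   nonconsecutive coarse C-alpha within the same 1.4 nm cutoff.

Distance-based springs are never created across distinct rigid domains
of an optional user partition, preserving inter-domain flexibility.
Recommended nonbonded settings (written to the advisory `.mdp`):
reaction-field electrostatics with dielectric 80 and cutoff 2.5·σ_max.

## Worked example

```bash
python examples/build_multiresolution_model.py
```

builds a 12-residue synthetic peptide with an AT core (residues 1–3)
and prints:

```
resolution labels: {1: 'at', 2: 'at', 3: 'at', 4: 'mg', 5: 'mg', 6: 'mg',
                    7: 'cg', 8: 'cg', 9: 'cg', 10: 'cg', 11: 'cg', 12: 'cg'}
131 atoms -> 49 beads
springs per tier: {'consecutive': 6, 'interface': 5, 'nonconsecutive': 13}
sigma_max = 0.5609 nm; recommended nonbonded cutoff = 1.4022 nm (2.5 * sigma_max), reaction-field dielectric = 80
```

Residues 4–6 were promoted to MG automatically because they sit within
1 nm of the core; 131 atoms collapse to 49 beads; the spring counts show
the elastic network tying the coarse regions together. The same pipeline
is available from the shell:

```bash
canvas map   --gro protein.gro --at-residues 1-30 --out survivors.txt
canvas build --gro protein.gro --top protein.top --survivors survivors.txt \
             --engine gromacs --out model/
canvas energy --model model/
```

`examples/single_point_energy.py` verifies the energy surface: at the
reference structure `E_harmonic = 0.000000 kJ/mol` exactly (all springs
at rest length), and stretching the single spring of a two-bead model by
0.01 nm gives `E_harmonic = 2.500000 kJ/mol = ½ k δ²`.
`examples/domain_partition_springs.py` shows the domain rule removing
all 43 cross-strand springs of a two-domain dumbbell.

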