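"""canvasmd — builder for three-level (AT/MG/CG) multiresolution protein
models: decimation mapping with a Voronoi atom-to-bead assignment,
cell-averaged bead parameters, retained atomistic bonded terms, a
three-tier harmonic spring network, and GROMACS/LAMMPS file emission
with a built-in single-point energy evaluator."""

from __future__ import annotations

from .bead_parametrizer import (
    Bead,
    bead_charge,
    bead_epsilon,
    bead_mass,
    bead_sigma,
    parametrize_beads,
)
from .bonded_builder import (
    DomainPartition,
    KnbProfile,
    RetainedBondedSet,
    SpringTerm,
    build_exclusions,
    build_spring_network,
    knb_lookup,
    retain_atomistic_bonded,
)
from .config import CanvasConfig
from .energy_oracle import EnergyBreakdown, single_point_energy
from .model_writers import (
    CanvasModel,
    assemble_model,
    read_gromacs_model,
    write_gromacs,
    write_lammps,
)
from .resolution_mapper import (
    CellMap,
    ResolutionAssignment,
    SurvivorSet,
    assign_resolution,
    read_survivor_list,
    select_survivors,
    voronoi_assign,
    write_survivor_list,
)
from .structure_io import (
    AtomisticTopology,
    AtomRecord,
    Structure,
    read_gro,
    read_topology,
    write_gro,
)

__version__ = "0.1.0"


def build_model(
    structure: Structure,
    topology: AtomisticTopology,
    assignment: ResolutionAssignment,
    partition: DomainPartition | None = None,
    profile: KnbProfile | None = None,
    config: CanvasConfig | None = None,
) -> CanvasModel:
    """Run the whole construction pipeline on in-memory inputs.

    Selects the survived atoms, partitions the decimated atoms onto them
    (Voronoi), computes bead parameters, filters the retained atomistic
    bonded terms, builds the three-tier spring network and the exclusion
    lists, and assembles the final model.
    """
    config = config or CanvasConfig()
    profile = profile or KnbProfile.from_config(config)
    survivors = select_survivors(structure, assignment)
    cellmap = voronoi_assign(structure, survivors)
    beads = parametrize_beads(structure, survivors, cellmap)
    retained = retain_atomistic_bonded(topology, survivors)
    springs = build_spring_network(
        structure, survivors, assignment, cellmap,
        partition=partition, profile=profile, config=config, topology=topology,
    )
    exclusions, pairs14 = build_exclusions(retained, springs, topology, survivors)
    return assemble_model(
        structure, beads, retained, springs, exclusions, pairs14,
        config=config, profile_id=profile.describe(),
        fudge_lj=topology.fudge_lj, fudge_qq=topology.fudge_qq,
    )
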