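"""Heaviside term retention, the k_nb profile, the three spring tiers,
the domain rule, and exclusion bookkeeping."""

import numpy as np
import pytest

from canvasmd import assign_resolution, select_survivors, voronoi_assign
from canvasmd.bonded_builder import (
    TIER_CONSECUTIVE,
    TIER_INTERFACE,
    TIER_NONCONSECUTIVE,
    DomainPartition,
    KnbProfile,
    SpringError,
    build_exclusions,
    build_spring_network,
    knb_lookup,
    retain_atomistic_bonded,
)
from canvasmd.config import CanvasConfig
from canvasmd.fixtures import FixtureSpec, make_peptide, make_planted_distances
from canvasmd.resolution_mapper import AT, CG, MG, ResolutionAssignment


def pipeline(structure, topology, assignment, partition=None, config=None):
    config = config or CanvasConfig()
    survivors = select_survivors(structure, assignment)
    cellmap = voronoi_assign(structure, survivors)
    springs = build_spring_network(
        structure, survivors, assignment, cellmap,
        partition=partition, config=config, topology=topology,
    )
    return survivors, cellmap, springs


class TestRetention:
    def test_full_at_retains_everything(self, penta):
        structure, topology, _ = penta
        assignment = assign_resolution(structure, set(structure.residue_ids))
        survivors = select_survivors(structure, assignment)
        retained = retain_atomistic_bonded(topology, survivors)
        assert len(retained.bonds) == len(topology.bonds)
        assert len(retained.angles) == len(topology.angles)
        assert len(retained.proper_dihedrals) == len(topology.proper_dihedrals)
        assert len(retained.improper_dihedrals) == len(topology.improper_dihedrals)
        assert retained.bonds[0] is topology.bonds[0]  # parameters untouched

    def test_term_with_decimated_member_dropped(self, penta):
        structure, topology, _ = penta
        assignment = ResolutionAssignment({r: CG for r in structure.residue_ids})
        survivors = select_survivors(structure, assignment)
        retained = retain_atomistic_bonded(topology, survivors)
        # only C-alphas survive and no two are covalently bonded
        assert retained.bonds == []
        assert retained.angles == []

    def test_mg_backbone_retention_matches_mask_enumeration(self, penta):
        """MG residues keep N-CA, CA-C, C-O and the inter-residue C-N
        peptide bond; CA-CB and everything touching a decimated atom go."""
        structure, topology, _ = penta
        assignment = ResolutionAssignment({r: MG for r in structure.residue_ids})
        survivors = select_survivors(structure, assignment)
        retained = retain_atomistic_bonded(topology, survivors)
        surv = set(survivors.atom_ids)
        expected = [b for b in topology.bonds if b.i in surv and b.j in surv]
        assert retained.bonds == expected
        names = {a.atom_id: a.name for a in structure.atoms}
        kept_name_pairs = {frozenset((names[b.i], names[b.j])) for b in retained.bonds}
        assert kept_name_pairs == {
            frozenset(p) for p in (("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "N"))
        }
        assert not any(
            frozenset((names[b.i], names[b.j])) == frozenset(("CA", "CB"))
            for b in retained.bonds
        )


class TestKnbProfile:
    def test_tabulated_linear_interpolation(self):
        profile = KnbProfile.tabulated([0.5, 1.0], [1000.0, 500.0])
        assert knb_lookup(profile, 0.75) == pytest.approx(750.0)

    def test_monotone_and_bounded(self):
        config = CanvasConfig()
        profile = KnbProfile.from_config(config)
        ds = np.linspace(0.05, 1.39, 100)
        ks = [knb_lookup(profile, d) for d in ds]
        assert all(a >= b for a, b in zip(ks, ks[1:]))  # non-increasing
        assert all(0 < k <= config.k_b for k in ks)

    def test_out_of_domain_rejected(self):
        profile = KnbProfile.from_config(CanvasConfig())
        with pytest.raises(SpringError):
            knb_lookup(profile, 1.4)
        with pytest.raises(SpringError):
            knb_lookup(profile, 0.0)

    def test_increasing_table_rejected(self):
        with pytest.raises(SpringError):
            KnbProfile.tabulated([0.5, 1.0], [500.0, 1000.0])


class TestSpringNetwork:
    def test_consecutive_cg_pair_gets_kb(self):
        structure, topology, gt = make_peptide(FixtureSpec(2, seed=5))
        assignment = ResolutionAssignment({1: CG, 2: CG})
        _, _, springs = pipeline(structure, topology, assignment)
        consec = [s for s in springs if s.tier == TIER_CONSECUTIVE]
        assert len(consec) == 1
        (spring,) = consec
        assert spring.k == pytest.approx(5.0e4)
        assert spring.r0 == pytest.approx(gt.ca_consecutive_distances[0], abs=1e-9)

    def test_covalent_bond_replaces_consecutive_spring(self, penta):
        """MG-MG neighbours are linked by the retained C-N peptide bond,
        so no k_b spring appears between them."""
        structure, topology, _ = penta
        assignment = ResolutionAssignment({r: MG for r in structure.residue_ids})
        _, _, springs = pipeline(structure, topology, assignment)
        assert not any(s.tier == TIER_CONSECUTIVE for s in springs)

    def test_cutoff_threshold_on_planted_pairs(self):
        """Nonconsecutive pairs at 1.39 nm get a spring, 1.41 nm do not."""
        structure, topology, _ = make_planted_distances(
            [(1, 3, 1.39), (1, 5, 1.41)], n_residues=5
        )
        assignment = ResolutionAssignment({r: CG for r in structure.residue_ids})
        _, _, springs = pipeline(structure, topology, assignment)
        cas = {r: next(a.atom_id for a in structure.atoms
                       if a.residue_id == r and a.name == "CA")
               for r in structure.residue_ids}
        pairs = {s.pair: s for s in springs if s.tier == TIER_NONCONSECUTIVE}
        near = (min(cas[1], cas[3]), max(cas[1], cas[3]))
        far = (min(cas[1], cas[5]), max(cas[1], cas[5]))
        assert near in pairs
        assert pairs[near].r0 == pytest.approx(1.39, abs=1e-6)
        profile = KnbProfile.from_config(CanvasConfig())
        assert pairs[near].k == pytest.approx(profile(1.39), rel=1e-9)
        assert far not in pairs

    def test_interface_tier_between_at_and_coarse(self):
        structure, topology, _ = make_planted_distances(
            [(1, 3, 1.0)], n_residues=3
        )
        assignment = ResolutionAssignment({1: AT, 2: MG, 3: CG})
        _, _, springs = pipeline(structure, topology, assignment)
        interface = [s for s in springs if s.tier == TIER_INTERFACE]
        assert len(interface) == 1
        assert interface[0].k == pytest.approx(50.0)

    def test_domain_rule_suppresses_cross_domain_springs(self):
        structure, topology, _ = make_planted_distances([(1, 3, 1.0)], n_residues=3)
        assignment = ResolutionAssignment({1: CG, 2: CG, 3: CG})
        partition = DomainPartition({1: 1, 2: 1, 3: 2})
        _, _, springs = pipeline(structure, topology, assignment, partition=partition)
        cas = {r: next(a.atom_id for a in structure.atoms
                       if a.residue_id == r and a.name == "CA")
               for r in structure.residue_ids}
        cross = (min(cas[1], cas[3]), max(cas[1], cas[3]))
        assert cross not in {s.pair for s in springs if s.tier != TIER_CONSECUTIVE}

    def test_full_at_produces_no_springs(self, penta):
        structure, topology, _ = penta
        assignment = assign_resolution(structure, set(structure.residue_ids))
        _, _, springs = pipeline(structure, topology, assignment)
        assert springs == []

    def test_no_duplicate_spring_pairs_and_cutoff_respected(self, peptide40):
        structure, topology, _ = peptide40
        assignment = assign_resolution(structure, {1, 2, 3})
        _, _, springs = pipeline(structure, topology, assignment)
        pairs = [s.pair for s in springs]
        assert len(pairs) == len(set(pairs))
        for s in springs:
            if s.tier in (TIER_NONCONSECUTIVE, TIER_INTERFACE):
                assert s.r0 < 1.4

    @pytest.mark.parametrize("geometry", ["linear", "two-domain"])
    def test_matches_quadratic_rule_oracle(self, geometry):
        """Spring set equals an independent O(N^2) evaluation of the
        three tier rules on a mixed-resolution fixture."""
        structure, topology, _ = make_peptide(
            FixtureSpec(60, geometry=geometry, seed=13)
        )
        assignment = assign_resolution(structure, {1, 2, 3, 4, 5})
        config = CanvasConfig()
        survivors, _, springs = pipeline(structure, topology, assignment,
                                         config=config)
        profile = KnbProfile.from_config(config)

        cas = {r: next(a.atom_id for a in structure.atoms
                       if a.residue_id == r and a.name == "CA")
               for r in structure.residue_ids}
        surv = set(survivors.atom_ids)
        bonded = {b.pair for b in topology.bonds if b.i in surv and b.j in surv}
        surv_by_res = {}
        for a in structure.atoms:
            if a.atom_id in surv:
                surv_by_res.setdefault(a.residue_id, []).append(a.atom_id)

        expected = {}
        res = structure.residue_ids
        for ra in res:
            for rb in res:
                if rb <= ra:
                    continue
                la, lb = assignment.labels[ra], assignment.labels[rb]
                ca_a, ca_b = cas[ra], cas[rb]
                d = float(np.linalg.norm(structure.atom(ca_a).coords
                                         - structure.atom(ca_b).coords))
                pair = (min(ca_a, ca_b), max(ca_a, ca_b))
                if rb == ra + 1:
                    if la == AT and lb == AT:
                        continue
                    linked = any(
                        (min(i, j), max(i, j)) in bonded
                        for i in surv_by_res[ra] for j in surv_by_res[rb]
                    )
                    if not linked:
                        expected[pair] = (TIER_CONSECUTIVE, config.k_b, d)
                    continue
                if d >= config.spring_cutoff or (la == AT and lb == AT):
                    continue
                if la != AT and lb != AT:
                    expected[pair] = (TIER_NONCONSECUTIVE, profile(d), d)
                else:
                    expected[pair] = (TIER_INTERFACE, config.k_if, d)

        got = {s.pair: (s.tier, s.k, s.r0) for s in springs}
        assert set(got) == set(expected)
        for pair, (tier, k, d) in expected.items():
            assert got[pair][0] == tier
            assert got[pair][1] == pytest.approx(k, rel=1e-12)
            assert got[pair][2] == pytest.approx(d, rel=1e-12)


class TestExclusions:
    def test_at_region_lists_filtered_by_survival(self, penta):
        structure, topology, _ = penta
        assignment = assign_resolution(structure, {1, 2})
        survivors = select_survivors(structure, assignment)
        cellmap = voronoi_assign(structure, survivors)
        retained = retain_atomistic_bonded(topology, survivors)
        springs = build_spring_network(
            structure, survivors, assignment, cellmap, topology=topology
        )
        excl, pairs14 = build_exclusions(retained, springs, topology, survivors)
        at_ids = {s.atom_id for s in survivors if s.label == AT}
        expected14 = sorted(
            {(min(i, j), max(i, j)) for i, j in topology.pairs14
             if i in at_ids and j in at_ids}
        )
        assert pairs14 == expected14
        # one atom decimated -> 1-4 pair dropped
        assert any(
            (i in at_ids) != (j in at_ids) for i, j in topology.pairs14
        )  # the fixture does exercise the dropped case

    def test_knb_pairs_not_excluded(self):
        """Distance-tier spring partners keep full nonbonded interactions."""
        structure, topology, _ = make_planted_distances([(1, 3, 1.0)], n_residues=3)
        assignment = ResolutionAssignment({r: CG for r in structure.residue_ids})
        survivors = select_survivors(structure, assignment)
        cellmap = voronoi_assign(structure, survivors)
        retained = retain_atomistic_bonded(topology, survivors)
        springs = build_spring_network(
            structure, survivors, assignment, cellmap, topology=topology
        )
        excl, _ = build_exclusions(retained, springs, topology, survivors)
        knb_pairs = {s.pair for s in springs if s.tier == TIER_NONCONSECUTIVE}
        assert knb_pairs
        assert not (knb_pairs & set(excl))

    def test_consecutive_springs_excluded_like_bonds(self):
        structure, topology, _ = make_peptide(FixtureSpec(2, seed=5))
        assignment = ResolutionAssignment({1: CG, 2: CG})
        survivors = select_survivors(structure, assignment)
        cellmap = voronoi_assign(structure, survivors)
        retained = retain_atomistic_bonded(topology, survivors)
        springs = build_spring_network(
            structure, survivors, assignment, cellmap, topology=topology
        )
        excl, _ = build_exclusions(retained, springs, topology, survivors)
        kb_pairs = {s.pair for s in springs if s.tier == TIER_CONSECUTIVE}
        assert kb_pairs and kb_pairs <= set(excl)
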