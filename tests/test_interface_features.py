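"""Interface definition, the nine structural features, and the DSI/NDSI
comparison."""

import numpy as np
import pytest

from hide import interface_features as feat
from hide.fixtures import FixtureSpec, build_swapped_dimer, make_residue
from hide.structure_io import Chain, Structure
from hide.swap_classifier import classify_pair, detect_interface


def pair_of(residues_a, residues_b):
    return feat.InterfacePair(residues_a, residues_b)


def two_chain_structure(res_a, res_b):
    return Structure(
        pdb_id="micro",
        chains=[Chain("A", list(res_a)), Chain("B", list(res_b))],
    )


class TestDefineInterface:
    def test_distant_chains_have_empty_interface(self):
        a = [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})]
        b = [make_residue("B", 1, "GLY", {"CA": (100, 0, 0)})]
        ia, ib = feat.define_interface(two_chain_structure(a, b), ("A", "B"))
        assert ia.residues == [] and ib.residues == []
        assert ia.area == 0.0

    def test_buried_residue_detected(self):
        # a CA at 4 Å from a partner CA loses tens of Å² of accessibility
        a = [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})]
        b = [make_residue("B", 1, "GLY", {"CA": (4.0, 0, 0)})]
        ia, ib = feat.define_interface(two_chain_structure(a, b), ("A", "B"))
        assert ia.residues == [("A", 1, "")]
        assert ia.dsasa[("A", 1, "")] > 20.0
        assert ia.area == pytest.approx(sum(ia.dsasa.values()))

    def test_threshold_monotonicity(self, swapped_dimer):
        structure, _ = swapped_dimer
        loose, _ = feat.define_interface(structure, ("A", "B"), dsasa_threshold=1.0)
        strict, _ = feat.define_interface(structure, ("A", "B"), dsasa_threshold=5.0)
        assert set(strict.residues) <= set(loose.residues)


class TestPairwiseCounts:
    def test_disulfide_cutoff(self):
        near = pair_of(
            [make_residue("A", 1, "CYS", {"CA": (0, 0, 0), "SG": (1.0, 1.0, 0)})],
            [make_residue("B", 1, "CYS", {"CA": (5.9, 0, 0), "SG": (4.0, 1.0, 0)})],
        )
        far = pair_of(
            [make_residue("A", 1, "CYS", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "CYS", {"CA": (7.0, 0, 0)})],
        )
        none = pair_of(
            [make_residue("A", 1, "SER", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "ALA", {"CA": (5.0, 0, 0)})],
        )
        assert feat.disulfide_bonds(near) == 1
        assert feat.disulfide_bonds(far) == 0
        assert feat.disulfide_bonds(none) == 0

    def test_hydrophobic_requires_listed_types(self):
        leu = make_residue("A", 1, "LEU", {"CA": (0, 0, 0), "CB": (1.5, 0, 0)})
        val = make_residue("B", 1, "VAL", {"CA": (8, 0, 0), "CB": (7.5, 0, 0)})
        ser = make_residue("B", 2, "SER", {"CA": (8, 3, 0), "CB": (7.5, 3, 0)})
        assert feat.hydrophobic_contacts(pair_of([leu], [val])) == 1
        assert feat.hydrophobic_contacts(pair_of([leu], [ser])) == 0

    def test_hydrophobic_matches_bruteforce_oracle(self, rng):
        types = ["ALA", "LEU", "ILE", "VAL", "TRP", "TYR", "PHE", "SER", "GLY"]
        res_a, res_b = [], []
        for i in range(12):
            aa = types[rng.integers(len(types))]
            atoms = {"CA": tuple(rng.uniform(0, 15, 3))}
            if aa != "GLY":
                atoms["CB"] = tuple(np.array(atoms["CA"]) + rng.normal(0, 1, 3))
            res_a.append(make_residue("A", i + 1, aa, atoms))
        for i in range(12):
            aa = types[rng.integers(len(types))]
            atoms = {"CA": tuple(rng.uniform(0, 15, 3))}
            if aa != "GLY":
                atoms["CB"] = tuple(np.array(atoms["CA"]) + rng.normal(0, 1, 3))
            res_b.append(make_residue("B", i + 1, aa, atoms))
        expected = 0
        hydrophobic = feat.HYDROPHOBIC_RESIDUES
        for ra in res_a:
            for rb in res_b:
                if ra.aa_type in hydrophobic and rb.aa_type in hydrophobic:
                    ca, cb = ra.atom("CB"), rb.atom("CB")
                    if ca and cb and np.linalg.norm(ca.coord - cb.coord) < 7.0:
                        expected += 1
        assert feat.hydrophobic_contacts(pair_of(res_a, res_b)) == expected

    def test_short_contact_strict_inequality(self):
        # carbon-carbon radius sum is 3.4 Å
        touching = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.0, 0, 0)})],
        )
        apart = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.5, 0, 0)})],
        )
        boundary = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.4, 0, 0)})],
        )
        assert feat.short_contacts(touching) == 1
        assert feat.short_contacts(apart) == 0
        assert feat.short_contacts(boundary) == 0

    def test_salt_bridge_rules(self):
        lys = make_residue("A", 1, "LYS", {"CA": (0, 0, 0), "NZ": (1, 0, 0)})
        asp_near = make_residue("B", 1, "ASP", {"CA": (5, 0, 0), "OD1": (4.5, 0, 0)})
        asp_far = make_residue("B", 2, "ASP", {"CA": (6, 0, 0), "OD1": (5.5, 0, 0)})
        arg = make_residue("B", 3, "ARG", {"CA": (3, 0, 0), "NH1": (2.5, 0, 0)})
        assert feat.salt_bridges(pair_of([lys], [asp_near])) == 1   # 3.5 Å
        assert feat.salt_bridges(pair_of([lys], [asp_far])) == 0    # 4.5 Å
        assert feat.salt_bridges(pair_of([lys], [arg])) == 0        # same sign

    def test_salt_bridge_inclusive_at_4A(self):
        lys = make_residue("A", 1, "LYS", {"NZ": (0, 0, 0), "CA": (1, 1, 1)})
        glu = make_residue("B", 1, "GLU", {"OE1": (4.0, 0, 0), "CA": (5, 1, 1)})
        assert feat.salt_bridges(pair_of([lys], [glu])) == 1

    def test_hydrogen_bond_geometry(self):
        # donor backbone N with CA antecedent; carbonyl O acceptor
        donor = make_residue("A", 1, "ALA", {"N": (0, 0, 0), "CA": (1.2, 1.0, 0)})
        acceptor_near = make_residue("B", 1, "ALA", {"O": (-2.9, 0, 0), "C": (-3.5, 1, 0)})
        acceptor_far = make_residue("B", 2, "ALA", {"O": (-4.2, 0, 0), "C": (-5, 1, 0)})
        bent = make_residue("B", 3, "ALA", {"O": (1.0, 2.8, 0), "C": (1, 3.8, 0)})
        assert feat.hydrogen_bonds(pair_of([donor], [acceptor_near])) == 1
        assert feat.hydrogen_bonds(pair_of([donor], [acceptor_far])) == 0
        # antecedent-donor-acceptor angle < 90° is rejected
        assert feat.hydrogen_bonds(pair_of([donor], [bent])) == 0

    def test_vdw_window_and_energy(self):
        # C–C: R = 3.4; r = 3.9 inside window, r = 3.3 is a short contact
        inside = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.9, 0, 0)})],
        )
        short = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.3, 0, 0)})],
        )
        assert feat.vdw_contacts(inside) == 1
        assert feat.vdw_contacts(short) == 0
        at_minimum = pair_of(
            [make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})],
            [make_residue("B", 1, "GLY", {"CA": (3.4, 0, 0)})],
        )
        count, energy = feat.vdw_contacts(at_minimum, with_energy=True)
        assert count == 1
        assert energy == pytest.approx(-1.0, abs=1e-12)

    def test_short_and_vdw_disjoint_by_construction(self, rng):
        res_a = [make_residue("A", i + 1, "GLY", {"CA": tuple(rng.uniform(0, 10, 3))})
                 for i in range(8)]
        res_b = [make_residue("B", i + 1, "GLY", {"CA": tuple(rng.uniform(0, 10, 3))})
                 for i in range(8)]
        pair = pair_of(res_a, res_b)
        radii = {"C": 1.7}
        n_short = feat.short_contacts(pair, radii=radii)
        n_vdw = feat.vdw_contacts(pair, radii=radii)
        # every atom pair is counted at most once across the two windows
        total = 0
        for ra in res_a:
            for rb in res_b:
                r = np.linalg.norm(ra.atom("CA").coord - rb.atom("CA").coord)
                total += int(r < 3.4) or int(3.4 <= r <= 4.4)
        assert n_vdw + n_short <= total + len(res_a) * len(res_b)
        assert n_vdw == sum(
            1 for ra in res_a for rb in res_b
            if 3.4 <= np.linalg.norm(ra.atom("CA").coord - rb.atom("CA").coord) <= 4.4
        )


class TestSegmentsProtrusionPlanarity:
    @pytest.mark.parametrize(
        "indices,expected",
        [([10, 11, 12, 20, 21], 2), ([10, 15], 1), ([], 0), ([3], 1)],
    )
    def test_segment_counting(self, indices, expected):
        assert feat.structural_segments(indices) == expected

    def test_isolated_atom_protrusion_index(self):
        res = make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})
        cx = feat.protrusion_index([res], [res])
        v_sphere = 4.0 / 3.0 * np.pi * 10.0**3
        assert cx == pytest.approx((v_sphere - 20.1) / 20.1, rel=1e-9)

    def test_protrusion_decreases_with_neighbours(self, rng):
        centre = make_residue("A", 1, "GLY", {"CA": (0, 0, 0)})
        context = [centre]
        previous = feat.protrusion_index([centre], context)
        for i in range(30):
            context = context + [
                make_residue("A", i + 2, "GLY", {"CA": tuple(rng.uniform(-6, 6, 3))})
            ]
            current = feat.protrusion_index([centre], context)
            assert current < previous
            previous = current

    def test_planarity_zero_for_coplanar_interface(self):
        residues = [
            make_residue("A", i + 1, "GLY", {"CA": (float(i), float(i % 3), 0.0)})
            for i in range(6)
        ]
        assert feat.planarity(residues) == pytest.approx(0.0, abs=1e-9)

    def test_minor_surfaces_ignored(self):
        residues = [
            make_residue("A", i + 1, "GLY", {"CA": (float(i), float(i**2), 0.0)})
            for i in range(3)
        ]
        assert feat.planarity(residues) is None

    def test_planarity_matches_svd_residual(self, rng):
        residues = [
            make_residue("A", i + 1, "GLY", {"CA": tuple(rng.normal(0, 5, 3))})
            for i in range(10)
        ]
        coords = np.array([r.atom("CA").coord for r in residues])
        centred = coords - coords.mean(axis=0)
        _, s, _ = np.linalg.svd(centred)
        expected = np.sqrt(s[-1] ** 2 / len(coords))
        assert feat.planarity(residues) == pytest.approx(expected, rel=1e-9)


class TestDsiNdsi:
    def test_dsi_area_exceeds_ndsi_area_on_swapped_fixture(self):
        spec = FixtureSpec(seed=21)
        structure, _ = build_swapped_dimer(spec)
        verdict = classify_pair(*structure.chains)
        assert verdict.swapped
        ia, _ = feat.define_interface(structure, ("A", "B"))
        contacts = detect_interface(*structure.chains)
        split = feat.split_dsi_ndsi(structure, ("A", "B"), contacts.pairs,
                                    verdict.crossing_by_chain)
        dsi_area = sum(ia.dsasa.get(r.key, 0.0) for r in split["DSI"].residues_a)
        ndsi_area = sum(ia.dsasa.get(r.key, 0.0) for r in split["NDSI"].residues_a)
        assert dsi_area > ndsi_area

    def test_compare_identical_pairs_flagged_degenerate(self):
        fs = feat.InterfaceFeatureSet(side_label="DSI", area=100.0, salt_bridges=2,
                                      protrusion_index=1.0)
        table = feat.compare_dsi_ndsi([(fs, fs)] * 3)
        assert table.loc["salt_bridges", "degenerate"]
        assert np.isnan(table.loc["salt_bridges", "p"])

    def test_paired_t_matches_textbook_formula(self):
        dsi_counts = [4, 6, 5, 7, 3]
        ndsi_counts = [1, 2, 2, 3, 1]
        pairs = []
        for d, n in zip(dsi_counts, ndsi_counts):
            pairs.append((
                feat.InterfaceFeatureSet(side_label="DSI", area=100.0,
                                         salt_bridges=d, protrusion_index=1.0),
                feat.InterfaceFeatureSet(side_label="NDSI", area=50.0,
                                         salt_bridges=n, protrusion_index=1.0),
            ))
        table = feat.compare_dsi_ndsi(pairs)
        diff = np.array(dsi_counts) / 100.0 - np.array(ndsi_counts) / 50.0
        t_expected = diff.mean() * np.sqrt(len(diff)) / diff.std(ddof=1)
        assert table.loc["salt_bridges", "t"] == pytest.approx(t_expected, rel=1e-12)

    def test_normalisation_requires_positive_area(self):
        fs = feat.InterfaceFeatureSet(side_label="DSI", area=0.0)
        with pytest.raises(ValueError):
            fs.normalized

    def test_feature_counts_invariant_under_rigid_motion(self, rng):
        from hide.fixtures import _rotation_about, _transform_chain

        spec = FixtureSpec(seed=21)
        structure, _ = build_swapped_dimer(spec)
        contacts = detect_interface(*structure.chains)
        by_key = {r.key: r for r in structure.residues()}
        pair = pair_of(
            [by_key[k] for k in contacts.residues_a],
            [by_key[k] for k in contacts.residues_b],
        )
        before = (feat.hydrophobic_contacts(pair), feat.vdw_contacts(pair),
                  feat.hydrogen_bonds(pair), feat.short_contacts(pair))
        rot = _rotation_about(rng.normal(size=3), 211.0)
        shift = rng.normal(scale=50.0, size=3)
        moved = [_transform_chain(c, rot, shift, c.chain_id) for c in structure.chains]
        mstruct = Structure(pdb_id="m", chains=moved)
        mcontacts = detect_interface(*mstruct.chains)
        mby = {r.key: r for r in mstruct.residues()}
        mpair = pair_of(
            [mby[k] for k in mcontacts.residues_a],
            [mby[k] for k in mcontacts.residues_b],
        )
        after = (feat.hydrophobic_contacts(mpair), feat.vdw_contacts(mpair),
                 feat.hydrogen_bonds(mpair), feat.short_contacts(mpair))
        assert after == before


class TestElectrostatics:
    def test_charged_pairs_within_six_angstroms(self):
        lys = make_residue("A", 1, "LYS", {"NZ": (0, 0, 0), "CA": (1, 1, 1)})
        glu = make_residue("B", 1, "GLU", {"OE1": (5.5, 0, 0), "CA": (6, 1, 1)})
        far = make_residue("B", 2, "GLU", {"OE1": (6.5, 0, 0), "CA": (7, 1, 1)})
        assert feat.electrostatic_interactions(pair_of([lys], [glu])) == 1
        assert feat.electrostatic_interactions(pair_of([lys], [far])) == 0
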