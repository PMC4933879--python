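"""Geometry suite: parsing, superposition, interfaces, SASA, B-factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from darpflex.structure import (
    ATOM_COLUMNS,
    PdbParseError,
    Selection,
    SelectionError,
    StructureModel,
    apply_transform,
    buried_surface,
    compute_sasa,
    count_close_contacts,
    interface_residues,
    motif_rotation,
    parse_pdb,
    region_mean_bfactor,
    superpose,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134   1.000  1.00 20.00           N
ATOM      2  CA  ALA A   1      12.560   6.234   1.100  1.00 30.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1      11.000   6.000   1.000  0.60 20.00           C
ATOM      2  CA BALA A   1      11.500   6.000   1.000  0.40 25.00           C
ATOM      3  CA  GLY A   2      14.000   6.000   1.000  1.00 15.00           C
END
"""


def model_from(records):
    """Build a StructureModel from (chain, resnum, atomname, element, xyz, occ, b)."""
    rows = []
    for chain, resnum, name, element, xyz, occ, b in records:
        rows.append(
            {
                "chain": chain, "resnum": resnum, "icode": "", "resname": "GLY",
                "atomname": name, "element": element,
                "x": xyz[0], "y": xyz[1], "z": xyz[2],
                "occupancy": occ, "bfactor": b, "altloc": "",
                "het": False, "water": False,
            }
        )
    return StructureModel(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


class TestParsePdb:
    def test_minimal_records_read_exactly(self):
        model = parse_pdb(MINIMAL_PDB)
        assert model.n_atoms == 2
        ca = model.atoms[model.atoms["atomname"] == "CA"].iloc[0]
        assert ca["x"] == pytest.approx(12.560)
        assert ca["bfactor"] == pytest.approx(30.0)
        assert ca["element"] == "C"
        assert ca["chain"] == "A"

    def test_altloc_highest_occupancy_kept(self):
        model = parse_pdb(ALTLOC_PDB)
        res1 = model.atoms[model.atoms["resnum"] == 1]
        assert len(res1) == 1
        assert res1.iloc[0]["altloc"] == "A"
        assert res1.iloc[0]["occupancy"] == pytest.approx(0.60)
        assert model.meta["n_altloc_discarded"] == 1

    def test_altloc_tie_breaks_alphabetically(self):
        tie = ALTLOC_PDB.replace("0.60", "0.40")
        model = parse_pdb(tie)
        assert model.atoms[model.atoms["resnum"] == 1].iloc[0]["altloc"] == "A"

    def test_malformed_coordinates_report_line_number(self):
        bad = MINIMAL_PDB.replace("  12.560", "  xx.560")
        with pytest.raises(PdbParseError, match="line 2"):
            parse_pdb(bad)

    def test_write_parse_round_trip(self, toy_complex):
        text = write_pdb(toy_complex.bound)
        back = parse_pdb(text)
        assert back.n_atoms == toy_complex.bound.n_atoms
        np.testing.assert_allclose(back.coords, toy_complex.bound.coords, atol=1e-3)


class TestSuperpose:
    def test_identical_structures_zero(self, toy_complex):
        sel = Selection(chains=("B",))
        res = superpose(toy_complex.bound, toy_complex.bound, sel, sel)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.rotation_angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_rotation_recovered(self, toy_complex):
        rot = Rotation.from_euler("xyz", [10.0, -5.0, 25.0], degrees=True)
        moved = toy_complex.bound.with_coords(
            rot.apply(toy_complex.bound.coords) + np.array([3.0, -2.0, 7.0])
        )
        sel = Selection(chains=("B",))
        res = superpose(moved, toy_complex.bound, sel, sel)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.rotation_angle == pytest.approx(rot.magnitude() * 180 / math.pi, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        a = model_from([("A", 1, "CA", "C", (0, 0, 0), 1, 10),
                        ("A", 2, "CA", "C", (3, 0, 0), 1, 10)])
        with pytest.raises(SelectionError):
            superpose(a, a, Selection(), Selection())

    def test_rigid_transform_invariance(self, toy_complex, rng):
        """rmsd and angle are unchanged when both inputs move together."""
        sel_ref = Selection(chains=("B",), residue_ranges=(toy_complex.reference_range,))
        sel_mot = Selection(chains=("B",), residue_ranges=(toy_complex.motif_range,))
        base = motif_rotation(toy_complex.apo_binder, toy_complex.bound, sel_ref, sel_mot)
        for _ in range(5):
            rot = Rotation.from_rotvec(rng.normal(size=3))
            shift = rng.normal(scale=20.0, size=3)
            apo2 = toy_complex.apo_binder.with_coords(
                rot.apply(toy_complex.apo_binder.coords) + shift
            )
            bound2 = toy_complex.bound.with_coords(
                rot.apply(toy_complex.bound.coords) + shift
            )
            res = motif_rotation(apo2, bound2, sel_ref, sel_mot)
            assert res.rotation_angle == pytest.approx(base.rotation_angle, abs=1e-9)
            assert res.rmsd == pytest.approx(base.rmsd, abs=1e-9)


class TestMotifRotation:
    def test_self_comparison_is_zero(self, toy_complex):
        sel_ref = Selection(chains=("B",), residue_ranges=(toy_complex.reference_range,))
        sel_mot = Selection(chains=("B",), residue_ranges=(toy_complex.motif_range,))
        res = motif_rotation(toy_complex.bound, toy_complex.bound, sel_ref, sel_mot)
        assert res.rotation_angle == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [0.0, 25.0, 60.0, 120.0])
    def test_constructed_angles_recovered(self, angle):
        from darpflex.synth import gen_toy_complex

        toy = gen_toy_complex(seed=2, motif_rotation_deg=angle)
        sel_ref = Selection(chains=("B",), residue_ranges=(toy.reference_range,))
        sel_mot = Selection(chains=("B",), residue_ranges=(toy.motif_range,))
        res = motif_rotation(toy.apo_binder, toy.bound, sel_ref, sel_mot)
        assert res.rotation_angle == pytest.approx(angle, abs=1e-6)


class TestInterface:
    def test_distant_chains_empty(self):
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
             ("B", 1, "CA", "C", (100, 0, 0), 1, 10)]
        )
        rep = interface_residues(m, Selection(chains=("A",)), Selection(chains=("B",)))
        assert rep.residues_a == [] and rep.residues_b == []

    @pytest.mark.parametrize("gap,expected", [(3.5, 1), (4.5, 0)])
    def test_cutoff_boundary(self, gap, expected):
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
             ("B", 1, "CA", "C", (gap, 0, 0), 1, 10)]
        )
        rep = interface_residues(m, Selection(chains=("A",)), Selection(chains=("B",)), 4.0)
        assert len(rep.residues_a) == expected
        assert len(rep.contact_pairs) == expected

    def test_overlapping_sides_rejected(self, toy_complex):
        sel = Selection(chains=("B",))
        with pytest.raises(SelectionError):
            interface_residues(toy_complex.bound, sel, sel)

    def test_binning_equals_brute_force_on_random_structures(self, rng):
        """k-d-tree neighbor search must equal the all-pairs scan."""
        for _ in range(100):
            n_a, n_b = rng.integers(5, 25), rng.integers(5, 25)
            xyz_a = rng.uniform(0, 20, size=(n_a, 3))
            xyz_b = rng.uniform(0, 20, size=(n_b, 3))
            cutoff = float(rng.uniform(2.0, 6.0))
            records = [
                ("A", i + 1, "CA", "C", tuple(xyz_a[i]), 1, 10) for i in range(n_a)
            ] + [
                ("B", j + 1, "CA", "C", tuple(xyz_b[j]), 1, 10) for j in range(n_b)
            ]
            m = model_from(records)
            rep = interface_residues(
                m, Selection(chains=("A",)), Selection(chains=("B",)), cutoff
            )
            brute_a = {
                ("A", i + 1, "GLY")
                for i in range(n_a)
                for j in range(n_b)
                if np.linalg.norm(xyz_a[i] - xyz_b[j]) <= cutoff
            }
            brute_b = {
                ("B", j + 1, "GLY")
                for j in range(n_b)
                for i in range(n_a)
                if np.linalg.norm(xyz_a[i] - xyz_b[j]) <= cutoff
            }
            assert set(rep.residues_a) == brute_a
            assert set(rep.residues_b) == brute_b


class TestCloseContacts:
    def test_zero_threshold_empty(self, toy_complex):
        assert count_close_contacts(toy_complex.apo_binder, toy_complex.receptor, 0.0) == []

    def test_constructed_clash_count(self, toy_complex):
        pairs = count_close_contacts(toy_complex.apo_binder, toy_complex.receptor, 2.0)
        assert len(pairs) == 5
        assert all(d < 2.0 for _, _, d in pairs)
        assert [d for _, _, d in pairs] == sorted(d for _, _, d in pairs)

    def test_rotation_relieves_clashes(self, toy_complex):
        bound_binder = toy_complex.bound.subset(
            toy_complex.bound.atoms["chain"] == "B"
        )
        assert count_close_contacts(bound_binder, toy_complex.receptor, 2.0) == []


def grid_sasa_two_spheres(c1, c2, r1, r2, n_theta=400, n_phi=800):
    """Independent lat-long grid integration of two fused spheres' area."""
    total = 0.0
    for center, radius, other_c, other_r in (
        (c1, r1, c2, r2), (c2, r2, c1, r1),
    ):
        theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
        phi = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        pts = center + radius * np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        )
        patch = radius**2 * np.sin(tt) * (math.pi / n_theta) * (2 * math.pi / n_phi)
        outside = np.linalg.norm(pts - other_c, axis=-1) >= other_r
        total += float((patch * outside).sum())
    return total


class TestSasa:
    def test_isolated_carbon_analytic(self):
        m = model_from([("A", 1, "CA", "C", (0, 0, 0), 1, 10)])
        area = compute_sasa(m).sum()
        assert area == pytest.approx(4 * math.pi * 3.1**2, rel=0.002)

    def test_distant_atoms_sum_of_spheres(self):
        records = [("A", i + 1, "CA", "C", (50.0 * i, 0, 0), 1, 10) for i in range(4)]
        area = compute_sasa(model_from(records)).sum()
        assert area == pytest.approx(4 * 4 * math.pi * 3.1**2, rel=1e-3)

    def test_fused_pair_matches_grid_oracle(self):
        d = 3.0  # centers closer than the 6.2 A extended-radius sum
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
             ("A", 2, "CA", "C", (d, 0, 0), 1, 10)]
        )
        area = compute_sasa(m).sum()
        oracle = grid_sasa_two_spheres(
            np.zeros(3), np.array([d, 0, 0]), 3.1, 3.1
        )
        assert area == pytest.approx(oracle, rel=0.01)

    def test_unknown_element_warns_missing_element_raises(self):
        m = model_from([("A", 1, "FE", "FE", (0, 0, 0), 1, 10)])
        with pytest.warns(UserWarning, match="not in radii table"):
            compute_sasa(m)
        m2 = model_from([("A", 1, "CA", "", (0, 0, 0), 1, 10)])
        with pytest.raises(ValueError, match="no element"):
            compute_sasa(m2)


class TestBuriedSurface:
    def test_distant_parts_bury_nothing(self):
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
             ("B", 1, "CA", "C", (100, 0, 0), 1, 10)]
        )
        bsa = buried_surface(m, Selection(chains=("A",)), Selection(chains=("B",)))
        assert bsa == pytest.approx(0.0, abs=0.5)

    def test_symmetry_and_grid_oracle(self):
        d = 4.0
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
             ("B", 1, "CA", "C", (d, 0, 0), 1, 10)]
        )
        sel_a, sel_b = Selection(chains=("A",)), Selection(chains=("B",))
        bsa_ab = buried_surface(m, sel_a, sel_b)
        bsa_ba = buried_surface(m, sel_b, sel_a)
        assert bsa_ab == pytest.approx(bsa_ba, rel=1e-12)
        isolated = 2 * 4 * math.pi * 3.1**2
        fused = grid_sasa_two_spheres(np.zeros(3), np.array([d, 0, 0]), 3.1, 3.1)
        assert bsa_ab == pytest.approx(isolated - fused, rel=0.02)

    def test_monotone_under_separation(self):
        sel_a, sel_b = Selection(chains=("A",)), Selection(chains=("B",))
        previous = math.inf
        for d in (3.0, 4.0, 5.0, 6.0, 8.0):
            m = model_from(
                [("A", 1, "CA", "C", (0, 0, 0), 1, 10),
                 ("B", 1, "CA", "C", (d, 0, 0), 1, 10)]
            )
            bsa = buried_surface(m, sel_a, sel_b)
            assert bsa <= previous + 0.5
            previous = bsa


class TestBfactor:
    def test_uniform_value(self):
        m = model_from([("A", i, "CA", "C", (4.0 * i, 0, 0), 1.0, 50.0) for i in range(1, 5)])
        assert region_mean_bfactor(m, Selection(chains=("A",))) == pytest.approx(50.0)

    def test_occupancy_weighted_mean(self):
        m = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 1.0, 10.0),
             ("A", 2, "CA", "C", (4, 0, 0), 1.0, 30.0)]
        )
        assert region_mean_bfactor(m, Selection(chains=("A",))) == pytest.approx(20.0)
        m2 = model_from(
            [("A", 1, "CA", "C", (0, 0, 0), 0.25, 10.0),
             ("A", 2, "CA", "C", (4, 0, 0), 0.75, 30.0)]
        )
        assert region_mean_bfactor(m2, Selection(chains=("A",))) == pytest.approx(25.0)

    def test_toy_motif_contrast(self, toy_complex):
        # the generator assigns mobile-motif atoms B = 75, the rest 47
        motif = Selection(chains=("B",), residue_ranges=(toy_complex.motif_range,))
        ref = Selection(chains=("B",), residue_ranges=(toy_complex.reference_range,))
        assert region_mean_bfactor(toy_complex.bound, motif) == pytest.approx(75.0)
        assert region_mean_bfactor(toy_complex.bound, ref) == pytest.approx(47.0)

    def test_empty_selection_rejected(self, toy_complex):
        with pytest.raises(SelectionError):
            region_mean_bfactor(toy_complex.bound, Selection(chains=("Z",)))
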