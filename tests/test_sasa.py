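import math

import numpy as np
import pytest

from pitha.antibody_model import Atom, annotate_regions, parse_pdb, read_numbering
from pitha.sasa import (
    atom_radius,
    compute_sasa,
    fibonacci_sphere,
    is_hydrophobic,
    region_hydrophobic_area,
    region_hydrophobic_fraction,
    shrake_rupley_areas,
)
from pitha.synthetic import (
    make_structure,
    monte_carlo_sasa_oracle,
    two_sphere_exposed_areas,
)


def _atom(element, name=None, residue="ALA", serial=1, coord=(0.0, 0.0, 0.0)):
    return Atom(
        serial=serial, name=name or element.upper(), element=element,
        chain_id="H", residue_name=residue, residue_seq="1",
        coord=np.array(coord, dtype=float),
    )


class TestAtomRadius:
    @pytest.mark.parametrize(
        "element,expected",
        [("C", 1.8), ("N", 1.65), ("O", 1.4), ("S", 1.85)],
    )
    def test_heavy_atom_radii(self, element, expected):
        assert atom_radius(_atom(element)) == expected

    def test_nonpolar_hydrogen_excluded(self):
        assert atom_radius(_atom("H"), bonded_element="C") is None

    @pytest.mark.parametrize("partner", ["N", "O", "S"])
    def test_polar_hydrogen_radius(self, partner):
        assert atom_radius(_atom("H"), bonded_element=partner) == 1.0

    def test_metal_rejected_by_name(self):
        with pytest.raises(ValueError, match="Fe"):
            atom_radius(_atom("Fe"))


class TestHydrophobicRule:
    def test_carbon_sulfur_nitrogen_hydrophobic(self):
        assert is_hydrophobic(_atom("C"))
        assert is_hydrophobic(_atom("S"))
        assert is_hydrophobic(_atom("N", name="N"))  # backbone N

    def test_oxygen_and_hydrogen_not(self):
        assert not is_hydrophobic(_atom("O"))
        assert not is_hydrophobic(_atom("H"))

    def test_histidine_sidechain_nitrogen_depends_on_protonation(self):
        ne2 = _atom("N", name="NE2", residue="HIS")
        assert is_hydrophobic(ne2, has_attached_hydrogen=True)
        assert not is_hydrophobic(ne2, has_attached_hydrogen=False)

    def test_histidine_default_tautomer_without_hydrogens(self):
        ne2 = _atom("N", name="NE2", residue="HIS")
        nd1 = _atom("N", name="ND1", residue="HIS")
        assert is_hydrophobic(ne2, structure_has_hydrogens=False)
        assert not is_hydrophobic(nd1, structure_has_hydrogens=False)


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley_areas(np.zeros((1, 3)), np.array([1.8]))[0]
        assert area == pytest.approx(4 * math.pi * 3.2**2, rel=1e-12)

    def test_distant_spheres_not_occluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        areas = shrake_rupley_areas(coords, np.array([1.8, 1.8]))
        assert areas == pytest.approx([4 * math.pi * 3.2**2] * 2, rel=1e-12)

    def test_two_sphere_overlap_matches_cap_formula(self):
        d = 3.0
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        radii = np.array([1.8, 1.65])
        areas = shrake_rupley_areas(coords, radii, n_sphere_points=15360)
        exact = two_sphere_exposed_areas(1.8, 1.65, d)
        assert areas[0] == pytest.approx(exact[0], rel=5e-3)
        assert areas[1] == pytest.approx(exact[1], rel=5e-3)

    def test_agrees_with_monte_carlo_oracle_on_cluster(self):
        structure, _, _ = make_structure("random_cluster", n_atoms=30, seed=17)
        coords = np.array([a.coord for a in structure.atoms])
        radii = np.full(30, 1.8)
        sr = shrake_rupley_areas(coords, radii, n_sphere_points=15360)
        mc, se = monte_carlo_sasa_oracle(coords, radii, n_samples=100_000, seed=5)
        # 2% agreement, up to the resolution of the two estimators
        assert np.all(np.abs(sr - mc) <= 0.02 * mc + 3 * se + 0.05)

    def test_occlusion_monotone(self):
        structure, _, _ = make_structure("random_cluster", n_atoms=10, seed=3)
        coords = np.array([a.coord for a in structure.atoms])
        radii = np.full(10, 1.8)
        before = shrake_rupley_areas(coords, radii)
        more = np.vstack([coords, coords.mean(axis=0)])
        after = shrake_rupley_areas(more, np.full(11, 1.8))[:10]
        assert np.all(after <= before + 1e-12)

    def test_convergence_of_total_area(self):
        structure, _, _ = make_structure("random_cluster", n_atoms=30, seed=4)
        coords = np.array([a.coord for a in structure.atoms])
        radii = np.full(30, 1.8)
        coarse = shrake_rupley_areas(coords, radii, n_sphere_points=960).sum()
        fine = shrake_rupley_areas(coords, radii, n_sphere_points=3840).sum()
        assert abs(coarse - fine) / fine < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            shrake_rupley_areas(np.empty((0, 3)), np.empty(0))

    def test_fibonacci_points_on_unit_sphere(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


class TestRegionAreas:
    def test_buried_loop_has_zero_area(self):
        structure, numbering, annotation = make_structure("buried_loop")
        assert region_hydrophobic_area(
            structure, annotation, numbering, "CDR-H3"
        ) == 0.0

    def test_region_areas_conserve_total(self):
        structure, numbering, annotation = make_structure(
            "random_cluster", n_atoms=25, seed=11
        )
        sasa = compute_sasa(structure)
        # every residue is labeled, so region areas partition the total
        from pitha.sasa import residue_region_index

        index = residue_region_index(structure, annotation, numbering)
        by_region: dict[str, float] = {}
        for res in structure.heavy_chain:
            label = index[("H", res.residue_seq)]
            for a in res.atoms:
                by_region[label] = by_region.get(label, 0.0) + sasa.per_atom_area[a.serial]
        assert sum(by_region.values()) == pytest.approx(sasa.total_area, rel=1e-12)

    def test_translation_leaves_areas_unchanged(self):
        structure, numbering, annotation = make_structure(
            "random_cluster", n_atoms=20, seed=7
        )
        moved, _, _ = make_structure("random_cluster", n_atoms=20, seed=7)
        for res in moved.heavy_chain:
            for a in res.atoms:
                a.coord[:] = a.coord + np.array([100.0, -50.0, 25.0])
        f0 = compute_sasa(structure).hydrophobic_fraction
        f1 = compute_sasa(moved).hydrophobic_fraction
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_rotation_changes_fraction_only_at_lattice_level(self):
        structure, numbering, annotation = make_structure(
            "random_cluster", n_atoms=20, seed=7
        )
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated, _, _ = make_structure("random_cluster", n_atoms=20, seed=7)
        for res in rotated.heavy_chain:
            for a in res.atoms:
                a.coord[:] = rot @ a.coord
        f0 = compute_sasa(structure).hydrophobic_fraction
        f1 = compute_sasa(rotated).hydrophobic_fraction
        assert f1 == pytest.approx(f0, rel=0.02)

    def test_empty_region_rejected(self):
        structure, numbering, annotation = make_structure(
            "random_cluster", n_atoms=20, seed=7
        )
        with pytest.raises(ValueError, match="CDR-L1"):
            region_hydrophobic_area(structure, annotation, numbering, "CDR-L1")

    def test_fraction_between_zero_and_hundred(self, tiny_pdb, tiny_numbering):
        structure = parse_pdb(tiny_pdb, "H", "L")
        numbering = read_numbering(tiny_numbering)
        annotation = annotate_regions(numbering)
        frac = region_hydrophobic_fraction(
            structure, annotation, numbering, "CDR-H1"
        )
        assert 0.0 <= frac <= 100.0


class TestNoHydrogenMode:
    def test_heavy_atom_only_flagged(self, tiny_pdb):
        structure = parse_pdb(tiny_pdb, "H", "L")
        result = compute_sasa(structure)
        assert result.no_hydrogens
        assert result.total_area > 0

    def test_frozen_atom_immutable(self):
        atom = _atom("C")
        with pytest.raises(AttributeError):
            atom.element = "N"
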