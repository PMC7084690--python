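"""Hydrogen bonds, SASA, superposition and register statistics."""

import itertools
import math

import numpy as np
import pytest

import dimerlens as dl
from dimerlens.model import StructureError


def rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


class TestBackboneHbonds:
    def test_designed_ladder_found_exactly(self, native_dimer):
        bonds = dl.backbone_hbonds(native_dimer.dimer)
        # two bonds (one per donor chain) per facing pair
        assert len(bonds) == 2 * len(native_dimer.truth_pairs)
        assert all(abs(b.distance_no - 2.9) < 1e-6 for b in bonds)

    def test_hydrogen_geometry_also_detected(self):
        bd = dl.gen_beta_dimer(11, 0, with_hydrogens=True)
        bonds = dl.backbone_hbonds(bd.dimer)
        assert len(bonds) == 2 * len(bd.truth_pairs)
        assert all(b.angle > 150 for b in bonds)

    def test_separated_chains_give_empty_list(self, native_dimer):
        dimer = native_dimer.dimer
        mask = dimer.mask(chain_id="B")
        coords = dimer.coords.copy()
        coords[mask] += np.array([0.0, 20.0, 0.0])
        moved = dl.StructureModel(list(dimer.atoms), coords)
        assert dl.backbone_hbonds(moved) == []

    def test_zero_cutoff_gives_empty_list(self, native_dimer):
        assert dl.backbone_hbonds(native_dimer.dimer, d_max=0.0) == []

    def test_count_invariant_under_rigid_motion(self, native_dimer):
        dimer = native_dimer.dimer
        rot = rotation([1, 2, 3], 1.1)
        moved = dimer.transformed(rot, np.array([5.0, -3.0, 8.0]))
        assert len(dl.backbone_hbonds(moved)) == len(dl.backbone_hbonds(dimer))

    def test_single_chain_errors(self, native_dimer):
        mono = native_dimer.dimer.subset(native_dimer.dimer.mask(chain_id="A"))
        with pytest.raises(StructureError, match="2 chains"):
            dl.backbone_hbonds(mono)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        m, radii = dl.gen_sphere_fixture([1.7], [[0, 0, 0]])
        area = dl.sasa(m, probe=1.4, n_points=960, radii=radii).sum()
        assert area == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)

    def test_far_spheres_add_independently(self):
        m, radii = dl.gen_sphere_fixture([1.7, 2.0], [[0, 0, 0], [100, 0, 0]])
        per_atom = dl.sasa(m, probe=1.4, n_points=500, radii=radii)
        assert per_atom[0] == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)
        assert per_atom[1] == pytest.approx(4 * math.pi * 3.4 ** 2, rel=0.01)

    def test_enclosed_atom_has_zero_area(self):
        # cage of overlapping spheres around a small central atom
        shell = []
        for theta in np.linspace(0, math.pi, 8):
            for phi in np.linspace(0, 2 * math.pi, 16, endpoint=False):
                shell.append([3.0 * math.sin(theta) * math.cos(phi),
                              3.0 * math.sin(theta) * math.sin(phi),
                              3.0 * math.cos(theta)])
        radii = [1.0] + [2.0] * len(shell)
        centers = [[0.0, 0.0, 0.0]] + shell
        m, table = dl.gen_sphere_fixture(radii, centers)
        per_atom = dl.sasa(m, probe=1.4, n_points=256, radii=table)
        assert per_atom[0] == 0.0

    def test_quadrature_converges(self, native_dimer):
        m = native_dimer.dimer
        a1 = dl.sasa(m, n_points=480).sum()
        a2 = dl.sasa(m, n_points=960).sum()
        assert abs(a2 - a1) / a2 < 0.005

    def test_too_few_points_rejected(self, native_dimer):
        with pytest.raises(ValueError):
            dl.sasa(native_dimer.dimer, n_points=32)

    def test_unknown_element_names_the_atom(self):
        m = dl.StructureModel([dl.Atom("A", 7, "UNK", "Q1", "QQ")],
                              np.zeros((1, 3)))
        with pytest.raises(StructureError, match="QQ"):
            dl.sasa(m)

    def test_cross_check_against_biotite(self, native_dimer):
        biotite_struc = pytest.importorskip("biotite.structure")
        d = native_dimer.dimer
        arr = biotite_struc.AtomArray(len(d.atoms))
        arr.coord = d.coords.astype(np.float32)
        for i, a in enumerate(d.atoms):
            arr.chain_id[i] = a.chain_id
            arr.res_id[i] = a.residue_index
            arr.res_name[i] = a.residue_type
            arr.atom_name[i] = a.atom_name
            arr.element[i] = a.element
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                 vdw_radii="Single").sum()
        ours = dl.sasa(d, probe=1.4, n_points=960).sum()
        assert ours == pytest.approx(ref, rel=0.03)


class TestInterfaceArea:
    def test_two_sphere_buried_area_matches_cap_formula(self):
        m, radii = dl.gen_sphere_fixture([2.0, 2.0], [[0, 0, 0], [2.0, 0, 0]])
        buried = dl.interface_area(m, probe=1.4, n_points=960, radii=radii)
        expected = dl.sphere_cap_buried_area(2.0, 2.0, 2.0, 1.4)
        assert expected == pytest.approx(2 * math.pi * 3.4 * 2.4)
        assert buried == pytest.approx(expected, rel=0.02)

    def test_distant_chains_bury_nothing(self):
        m, radii = dl.gen_sphere_fixture([2.0, 2.0], [[0, 0, 0], [100.0, 0, 0]])
        assert dl.interface_area(m, radii=radii, n_points=256) == 0.0

    def test_symmetric_under_chain_swap(self, mutant_dimer):
        d = mutant_dimer.dimer
        swapped = d.with_chain_ids({"A": "B", "B": "A"})
        a = dl.interface_area(d, n_points=256)
        b = dl.interface_area(swapped, n_points=256)
        assert b == pytest.approx(a, rel=1e-9)

    def test_monotone_decrease_when_pulled_apart(self, native_dimer):
        d = native_dimer.dimer
        mask = d.mask(chain_id="B")
        areas = []
        for sep in (0.0, 2.0, 6.0, 30.0):
            coords = d.coords.copy()
            coords[mask] += np.array([0.0, sep, 0.0])
            areas.append(dl.interface_area(
                dl.StructureModel(list(d.atoms), coords), n_points=256))
        assert all(b <= a + 1e-9 for a, b in zip(areas, areas[1:]))
        assert areas[-1] == 0.0

    def test_needs_exactly_two_chains(self, native_dimer):
        mono = native_dimer.dimer.subset(native_dimer.dimer.mask(chain_id="A"))
        with pytest.raises(StructureError, match="2 chains"):
            dl.interface_area(mono)


class TestSuperpose:
    def test_self_superposition_is_zero(self, native_dimer):
        mono = native_dimer.dimer.subset(native_dimer.dimer.mask(chain_id="A"))
        sup = dl.superpose(mono, mono, residue_range=None)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, native_dimer):
        mono = native_dimer.dimer.subset(native_dimer.dimer.mask(chain_id="A"))
        moved = mono.transformed(rotation([0, 0, 1], math.pi / 2),
                                 np.array([5.0, 5.0, 5.0]))
        sup = dl.superpose(moved, mono, residue_range=None)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_symmetric_and_matches_grid_oracle(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        bumped = pts.copy()
        bumped[3] += [0.5, 0.0, 0.0]

        def model(xyz):
            atoms = [dl.Atom("A", i + 1, "GLY", "CA", "C") for i in range(len(xyz))]
            return dl.StructureModel(atoms, xyz)

        a, b = model(pts), model(bumped)
        sup = dl.superpose(a, b, residue_range=None)
        assert dl.superpose(b, a, residue_range=None).rmsd == pytest.approx(sup.rmsd)

        # brute force: Euler-angle grid with coarse-to-fine refinement,
        # centering removes the translation at every step
        x0 = pts - pts.mean(axis=0)
        y0 = bumped - bumped.mean(axis=0)

        def grid_rmsd(center, half_width, steps=9):
            best = (math.inf, center)
            axes = [np.linspace(c - half_width, c + half_width, steps)
                    for c in center]
            for a1, a2, a3 in itertools.product(*axes):
                r = (rotation([0, 0, 1], a1) @ rotation([0, 1, 0], a2)
                     @ rotation([1, 0, 0], a3))
                val = math.sqrt(np.mean(np.sum((x0 @ r.T - y0) ** 2, axis=1)))
                if val < best[0]:
                    best = (val, (a1, a2, a3))
            return best

        best, center = grid_rmsd((0.0, 0.0, 0.0), 0.5)
        width = 0.5 / 4
        for _ in range(6):
            best, center = grid_rmsd(center, width)
            width /= 4
        assert sup.rmsd == pytest.approx(best, abs=1e-3)

    def test_too_few_pairs_errors(self):
        atoms = [dl.Atom("A", i + 1, "GLY", "CA", "C") for i in range(2)]
        m = dl.StructureModel(atoms, np.random.default_rng(0).normal(size=(2, 3)))
        with pytest.raises(StructureError, match=">= 3"):
            dl.superpose(m, m, residue_range=None)

    def test_selection_recorded(self, native_dimer):
        mono = native_dimer.dimer.subset(native_dimer.dimer.mask(chain_id="A"))
        sup = dl.superpose(mono, mono, residue_range=(6, 15))
        assert sup.selection == "CA 6-15"


class TestRegister:
    def test_native_like_map(self, native_dimer):
        assert dl.register_map(native_dimer.dimer) == [(8, 10), (10, 8)]

    def test_mutant_like_map(self, mutant_dimer):
        assert dl.register_map(mutant_dimer.dimer) == [(10, 10)]

    def test_one_residue_shift_between_native_and_mutant(
        self, native_dimer, mutant_dimer
    ):
        shift = dl.register_shift(
            dl.register_map(native_dimer.dimer), dl.register_map(mutant_dimer.dimer)
        )
        assert shift == 1

    @pytest.mark.parametrize("offset", [-2, -1, 0, 1, 2])
    def test_designed_offsets_recovered_exactly(self, offset):
        base = dl.gen_beta_dimer(17, 0)
        other = dl.gen_beta_dimer(17, offset)
        shift = dl.register_shift(
            base.truth_pairs, other.truth_pairs, window=(1, 17)
        )
        assert shift == offset
        # hbond-derived maps agree with truth
        assert dl.register_map(other.dimer) == other.truth_pairs

    def test_identical_maps_give_zero(self, native_dimer):
        m = dl.register_map(native_dimer.dimer)
        assert dl.register_shift(m, m) == 0

    def test_empty_window_overlap_errors(self, native_dimer):
        m = dl.register_map(native_dimer.dimer)
        with pytest.raises(StructureError, match="window"):
            dl.register_shift(m, m, window=(60, 70))

    def test_empty_hbond_list_gives_empty_map(self, native_dimer):
        assert dl.register_map(native_dimer.dimer, hbonds=[]) == []
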