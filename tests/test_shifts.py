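"""Secondary-shift indexing and CSP mapping."""

import math

import pytest

import dimerlens as dl
from dimerlens.shifts import COIL, HELIX, STRAND, ShiftTableError


def table(*rows):
    return dl.ShiftTable([dl.ShiftEntry(*r) for r in rows])


class TestSecondaryShifts:
    @pytest.mark.parametrize(
        "obs,expected",
        [(52.5, 0.0), (54.5, 2.0), (50.0, -2.5)],
        ids=["identity", "downfield", "upfield"],
    )
    def test_delta_is_observed_minus_random_coil(self, obs, expected, random_coil):
        t = table((5, "A", "CA", obs))
        deltas = dl.secondary_shifts(t, random_coil)
        assert deltas[5][0] == pytest.approx(expected)

    def test_gly_without_cb_gets_zero_delta_cb(self, random_coil):
        t = table((3, "G", "CA", 45.1))
        assert dl.secondary_shifts(t, random_coil)[3] == (pytest.approx(0.0), 0.0)

    def test_residue_without_ca_is_undefined(self, random_coil):
        t = table((3, "A", "CB", 19.1), (4, "A", "CA", 52.5))
        assert 3 not in dl.secondary_shifts(t, random_coil)

    def test_unknown_residue_type_names_the_residue(self, random_coil):
        t = table((7, "X", "CA", 52.5))
        with pytest.raises(ShiftTableError, match="7"):
            dl.secondary_shifts(t, random_coil)

    def test_out_of_range_shift_flags_column_mixup(self, random_coil):
        t = table((7, "A", "CA", 300.0))
        with pytest.raises(ShiftTableError, match="column"):
            dl.secondary_shifts(t, random_coil)

    def test_gly_cannot_carry_cb(self):
        with pytest.raises(ShiftTableError, match="Gly"):
            table((3, "G", "CB", 20.0))

    def test_duplicate_atom_entry_rejected(self):
        with pytest.raises(ShiftTableError, match="duplicate"):
            table((3, "A", "CA", 52.0), (3, "A", "CA", 53.0))


class TestSmoothing:
    def test_three_point_mean(self):
        assert dl.smooth_index({10: 0.0, 11: 3.0, 12: 0.0})[11] == pytest.approx(1.0)

    def test_constant_run_stays_constant(self):
        raw = {i: 2.5 for i in range(5, 15)}
        sm = dl.smooth_index(raw)
        assert all(v == pytest.approx(2.5) for v in sm.values())

    def test_isolated_residue_is_its_own_window(self):
        assert dl.smooth_index({42: -1.7})[42] == pytest.approx(-1.7)

    def test_terminus_and_gap_average_available_members(self):
        raw = {1: 3.0, 2: 0.0, 10: 6.0, 11: 0.0}
        sm = dl.smooth_index(raw)
        assert sm[1] == pytest.approx(1.5)   # terminus: (3+0)/2
        assert sm[10] == pytest.approx(3.0)  # gap-adjacent: (6+0)/2

    def test_linearity(self):
        x = {1: 1.0, 2: -2.0, 3: 0.5, 5: 4.0}
        y = {1: 0.3, 2: 1.0, 3: -1.5, 5: 2.0}
        sx, sy = dl.smooth_index(x), dl.smooth_index(y)
        sxy = dl.smooth_index({k: x[k] + y[k] for k in x})
        for k in x:
            assert sxy[k] == pytest.approx(sx[k] + sy[k])


class TestClassification:
    @pytest.mark.parametrize(
        "value,deadband,label",
        [(-2.0, 0.7, STRAND), (0.3, 0.7, COIL), (2.0, 0.7, HELIX),
         (-0.7, 0.7, COIL), (0.1, 0.0, HELIX), (-0.1, 0.0, STRAND)],
    )
    def test_sign_rule_with_deadband(self, value, deadband, label):
        assert dl.classify_secondary({1: value}, deadband)[1] == label

    def test_zero_deadband_partitions_nonzero_values(self):
        sm = {1: 0.5, 2: -0.5, 3: 0.0}
        labels = dl.classify_secondary(sm, 0.0)
        assert labels == {1: HELIX, 2: STRAND, 3: COIL}

    def test_negative_deadband_rejected(self):
        with pytest.raises(ValueError):
            dl.classify_secondary({1: 1.0}, -0.1)

    def test_chemokine_profile_recovered_from_noisy_shifts(self, random_coil):
        t, truth = dl.gen_shift_table(noise_sd=1.0, seed=7)
        profile = dl.predict_secondary_structure(t, random_coil)
        assert dl.recovery_fraction(truth, profile.labels) >= 0.90

    def test_profile_records_reference_provenance(self, random_coil):
        t, _ = dl.gen_shift_table(seed=0)
        profile = dl.predict_secondary_structure(t, random_coil)
        assert profile.reference_provenance == random_coil.provenance


class TestCsp:
    def amide_pair(self, perturbations):
        a, _ = dl.gen_shift_table(seed=3)
        b = dl.perturb_shift_table(a, perturbations)
        return a, b

    def test_identical_tables_give_zero_everywhere(self):
        a, b = self.amide_pair({})
        profile = dl.csp(a, b)
        assert all(v == 0.0 for v in profile.delta_nh.values())

    @pytest.mark.parametrize(
        "dh,dn,expected",
        [(0.1, 0.5, 0.1), (0.0, 1.0, math.sqrt(0.04 / 2)), (0.0, 0.0, 0.0)],
    )
    def test_combined_shift_formula(self, dh, dn, expected):
        assert dl.combined_shift(dh, dn) == pytest.approx(expected)

    def test_signed_components_kept_and_combined_value_symmetric(self):
        # state b carries the perturbation, so a - b has the opposite sign
        a, b = self.amide_pair({8: (0.4, -1.5)})
        ab, ba = dl.csp(a, b), dl.csp(b, a)
        assert ab.delta_h[8] == pytest.approx(-0.4)
        assert ab.delta_n[8] == pytest.approx(1.5)
        assert ba.delta_h[8] == pytest.approx(0.4)
        assert ab.delta_nh[8] == pytest.approx(ba.delta_nh[8])

    def test_uniform_offset_on_both_states_cancels(self):
        a, b = self.amide_pair({8: (0.2, 1.0)})
        shift_all = {r: (0.05, 0.3) for r in a.residues()}
        a2 = dl.perturb_shift_table(a, shift_all)
        b2 = dl.perturb_shift_table(b, shift_all)
        p1, p2 = dl.csp(a, b), dl.csp(a2, b2)
        for r in p1.delta_nh:
            assert p2.delta_nh[r] == pytest.approx(p1.delta_nh[r])

    def test_unmatched_residues_reported_not_dropped(self):
        a, _ = dl.gen_shift_table(seed=3)
        b = dl.ShiftTable([e for e in a.entries if e.residue_index != 8])
        profile = dl.csp(a, b)
        assert 8 in profile.unmatched_a
        assert 8 not in profile.delta_nh

    def test_no_shared_residues_is_an_error(self):
        a = table((1, "A", "H", 8.3), (1, "A", "N", 119.0))
        b = table((2, "A", "H", 8.3), (2, "A", "N", 119.0))
        with pytest.raises(ShiftTableError):
            dl.csp(a, b)


class TestTiers:
    @pytest.mark.parametrize(
        "value,thresholds,tier",
        [(1.2, (0.25, 0.5, 1.0), 3), (0.0, (0.25, 0.5, 1.0), 0),
         (0.07, (0.05, 0.1), 1), (0.25, (0.25, 0.5, 1.0), 0),
         (0.3, (0.25, 0.5, 1.0), 1)],
    )
    def test_tier_counts_thresholds_strictly_exceeded(self, value, thresholds, tier):
        profile = dl.CspProfile({1: 0.0}, {1: 0.0}, {1: value})
        assert dl.tier_csp(profile, thresholds).tiers[1] == tier

    @pytest.mark.parametrize("bad", [(0.5, 0.25), (0.25, 0.25), (-0.1, 0.5), ()])
    def test_invalid_thresholds_rejected(self, bad):
        profile = dl.CspProfile({1: 0.0}, {1: 0.0}, {1: 0.1})
        with pytest.raises(ValueError):
            dl.tier_csp(profile, bad)


class TestIO:
    def test_delimited_roundtrip(self, tmp_path):
        t, _ = dl.gen_shift_table(seed=5)
        p = tmp_path / "shifts.csv"
        t.to_dataframe().to_csv(p, index=False)
        back = dl.ShiftTable.read_csv(p)
        import pandas.testing as pdt

        pdt.assert_frame_equal(back.to_dataframe(), t.to_dataframe(),
                               check_exact=False, atol=1e-9)

    def test_nmrstar_loop_reader(self, tmp_path):
        star = """\
data_test
save_assigned_chemical_shifts
loop_
_Atom_chem_shift.ID
_Atom_chem_shift.Seq_ID
_Atom_chem_shift.Comp_ID
_Atom_chem_shift.Atom_ID
_Atom_chem_shift.Val
1 5 ALA CA 54.5
2 5 ALA CB 18.9
3 5 ALA HB .
4 6 GLY CA 45.1
5 6 GLY H 8.21
stop_
save_
"""
        p = tmp_path / "shifts.str"
        p.write_text(star)
        t = dl.ShiftTable.read_nmrstar(p)
        assert t.get(5, "CA") == pytest.approx(54.5)
        assert t.get(6, "H") == pytest.approx(8.21)
        # side-chain atoms are ignored
        assert len(t.entries) == 4
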