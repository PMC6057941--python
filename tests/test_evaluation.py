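import math

import numpy as np
import pytest

from contactsieve.evaluation import (
    classify_contacts,
    evaluate_contacts,
    gdt,
    gdt_ts,
    kabsch_superpose,
    n_effective,
    precision_recall,
    reference_dihedral_chain,
)
from contactsieve.fileio import MSA
from contactsieve.geometry import HELIX_PHI, HELIX_PSI
from contactsieve.restraints import ContactRecord
from contactsieve.synthetic import make_toy_msa


def _rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()


class TestClassifyContacts:
    def test_cutoff_inclusive(self, toy_sheet):
        ref = toy_sheet.reference()
        # find pairs straddling the cutoff
        labels = classify_contacts(
            [ContactRecord(i, j, 1.0) for i, j in toy_sheet.true_contacts],
            ref,
        )
        assert all(l == "TP" for l in labels)

    def test_boundary_exactly_nine_is_tp(self, toy_sheet):
        ref = toy_sheet.reference()
        i, j = toy_sheet.true_contacts[0]
        d = ref.pair_distance(i, j)
        # synthetic boundary check: scale cb so the distance is exactly 9
        ref.cb[j - 1] = ref.cb[i - 1] + (ref.cb[j - 1] - ref.cb[i - 1]) * (
            9.0 / d
        )
        lab = classify_contacts([ContactRecord(i, j, 1.0)], ref)[0]
        assert lab == "TP"
        ref.cb[j - 1] = ref.cb[i - 1] + (ref.cb[j - 1] - ref.cb[i - 1]) * (
            9.05 / 9.0
        )
        assert classify_contacts([ContactRecord(i, j, 1.0)], ref)[0] == "FP"

    def test_unresolved_unverifiable(self, toy_sheet):
        ref = toy_sheet.reference()
        ref.resolved[0] = False
        lab = classify_contacts([ContactRecord(1, 10, 1.0)], ref)[0]
        assert lab == "unverifiable"


class TestPrecisionRecall:
    def test_hpf_style_counts(self):
        # 114 input contacts, 82 TP; filtering keeps 102 with 21 FP
        labels = ["TP"] * 82 + ["FP"] * 32
        kept = [True] * 81 + [False] + [True] * 21 + [False] * 11
        precision, recall = precision_recall(labels, kept)
        assert precision == pytest.approx(81 / 102)
        assert recall == pytest.approx(81 / 82)

    def test_all_tps_kept_recall_one(self):
        labels = ["TP", "FP", "TP"]
        precision, recall = precision_recall(labels, [True, False, True])
        assert recall == 1.0 and precision == 1.0

    def test_empty_kept_undefined(self):
        precision, recall = precision_recall(["TP"], [False])
        assert math.isnan(precision)

    def test_order_invariance(self):
        labels = ["TP", "FP", "TP", "FP"]
        kept = [True, True, False, False]
        p1 = precision_recall(labels, kept)
        perm = [2, 0, 3, 1]
        p2 = precision_recall([labels[k] for k in perm], [kept[k] for k in perm])
        assert p1 == p2

    def test_unverifiable_excluded(self):
        labels = ["TP", "unverifiable", "FP"]
        precision, _ = precision_recall(labels, [True, True, False])
        assert precision == 1.0


class TestKabsch:
    def test_identical_zero_rmsd(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_zero_rmsd(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(8, 3))
        _, _, rmsd = kabsch_superpose(P, P + [1.0, -2.0, 3.0])
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(20, 3))
        R_true = _rotation(2)
        Q = P @ R_true.T + np.array([4.0, 5.0, 6.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, R_true, atol=1e-6)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestGDT:
    def test_identical_is_one(self, toy_sheet):
        ca = toy_sheet.coords.ca
        assert gdt(ca, ca)[5.0] == 1.0

    def test_rigid_motion_invariance(self, toy_sheet):
        ca = toy_sheet.coords.ca
        R = _rotation(3)
        moved = ca @ R.T + [10.0, -4.0, 2.0]
        assert gdt(moved, ca)[5.0] == 1.0
        assert gdt_ts(moved, ca) == 1.0

    def test_half_displaced_lower_bound(self, toy_sheet):
        ca = toy_sheet.coords.ca.copy()
        n = len(ca)
        half = n // 2
        ca[:half] += 20.0
        score = gdt(ca, toy_sheet.coords.ca)[5.0]
        assert score >= (n - half) / n - 1e-9

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            gdt(np.zeros((2, 3)), np.zeros((2, 3)))


class TestNEffective:
    def test_identical_sequences_collapse_to_one(self):
        msa = MSA([(f"s{k}", "ACDEFGHIKL") for k in range(5)])
        assert n_effective(msa) == pytest.approx(1.0)

    def test_all_dissimilar_count_fully(self):
        msa = MSA([("a", "AAAAAAAAAA"), ("b", "CCCCCCCCCC"), ("c", "DDDDDDDDDD")])
        assert n_effective(msa) == pytest.approx(3.0)

    def test_one_close_pair(self):
        # a/b at 90% identity, c/d unrelated: weights 1/2,1/2,1,1
        msa = MSA(
            [
                ("a", "AAAAAAAAAA"),
                ("b", "AAAAAAAAAC"),
                ("c", "DDDDDDDDDD"),
                ("d", "EEEEEEEEEE"),
            ]
        )
        assert n_effective(msa) == pytest.approx(3.0)

    def test_gap_columns_excluded_from_denominator(self):
        # identity = matches over both-non-gap columns: 9/10 > 0.8
        msa = MSA([("a", "AAAAAAAAAA-"), ("b", "AAAAAAAAAC-")])
        assert n_effective(msa) == pytest.approx(1.0)

    def test_range_invariant(self):
        msa = make_toy_msa(2, [3, 2], length=60, seed=5)
        neff = n_effective(msa)
        assert 1.0 <= neff <= len(msa)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            MSA([])


class TestReferenceDihedralChain:
    def test_all_loop_fully_free(self, toy_sheet):
        ref = toy_sheet.reference()
        ch = reference_dihedral_chain(ref, "C" * len(ref))
        assert not ch.fixed.any()

    def test_assigned_residues_take_experimental_angles(self, toy_sheet):
        ref = toy_sheet.reference()
        ch = reference_dihedral_chain(ref, toy_sheet.ss_labels)
        k = 2  # interior strand residue
        assert ch.fixed[k]
        assert ch.phi[k] == pytest.approx(ref.phi[k])

    def test_undefined_terminal_falls_back_with_warning(self, toy_sheet):
        ref = toy_sheet.reference()
        ref.phi[:] = np.nan
        with pytest.warns(UserWarning, match="canonical"):
            ch = reference_dihedral_chain(ref, "H" + "C" * (len(ref) - 1))
        assert ch.phi[0] == HELIX_PHI and ch.fixed[0]

    def test_length_mismatch_rejected(self, toy_sheet):
        with pytest.raises(ValueError):
            reference_dihedral_chain(toy_sheet.reference(), "CC")


class TestEvaluateContacts:
    def test_all_tp_zero_violation(self, toy_sheet):
        ref = toy_sheet.reference()
        contacts = [ContactRecord(i, j, 1.0) for i, j in toy_sheet.true_contacts]
        report = evaluate_contacts(contacts, [True] * len(contacts), ref)
        assert report.precision == 1.0
        assert report.violation_energy == 0.0
        assert report.fn == 0

    def test_gdt_of_ground_truth_model(self, toy_sheet):
        ref = toy_sheet.reference()
        contacts = [ContactRecord(i, j, 1.0) for i, j in toy_sheet.true_contacts]
        report = evaluate_contacts(
            contacts, [True] * len(contacts), ref, model_ca=toy_sheet.coords.ca
        )
        assert report.gdt5 == 1.0
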