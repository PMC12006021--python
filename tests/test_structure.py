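"""Structure stage: contact classification vs the O(n^2) oracle,
rigid-body invariance, affinity-model linearity and pocket projection."""

import dataclasses
import math
import random

import numpy as np
import pytest

from oracles import oracle_contact_counts
from promiscuity.io_formats import AtomRecord, ComplexStructure
from promiscuity.structure import (
    AffinityModel,
    CONTACT_CLASSES,
    ContactProfile,
    chain_sequence,
    compare_pockets,
    contact_profile,
    pocket_residues,
    predict_affinity,
)
from promiscuity.synthetic import (
    PocketSpec,
    apply_edit_script,
    complex_from_contacts,
    generate_complex,
)


def _random_complex(rng, n_protein=20, n_ligand=10, box=15.0):
    elements = ["C", "N", "O", "S", "P", "F"]
    atoms = []
    for i in range(n_protein):
        atoms.append(AtomRecord(
            element=rng.choice(elements),
            x=rng.uniform(0, box), y=rng.uniform(0, box), z=rng.uniform(0, box),
            res_name="ALA", res_num=i + 1, chain_id="A", atom_name="CA",
            is_ligand=False,
        ))
    for i in range(n_ligand):
        atoms.append(AtomRecord(
            element=rng.choice(elements),
            x=rng.uniform(0, box), y=rng.uniform(0, box), z=rng.uniform(0, box),
            res_name="LIG", res_num=1, chain_id="L", atom_name=f"L{i}",
            is_ligand=True,
        ))
    return ComplexStructure(atoms=tuple(atoms), ligand_name="LIG")


def _transform(complex_, rotation, translation):
    moved = []
    for a in complex_.atoms:
        xyz = rotation @ np.array([a.x, a.y, a.z]) + translation
        moved.append(dataclasses.replace(a, x=xyz[0], y=xyz[1], z=xyz[2]))
    return ComplexStructure(atoms=tuple(moved), ligand_name=complex_.ligand_name)


def _random_rotation(rng):
    m = np.array([[rng.gauss(0, 1) for _ in range(3)] for _ in range(3)])
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


class TestContactProfile:
    def test_distant_ligand_all_zero(self):
        atoms = (
            AtomRecord("C", 0, 0, 0, "ALA", 1, "A", "CA", False),
            AtomRecord("C", 20.0, 0, 0, "LIG", 1, "L", "C1", True),
        )
        profile = contact_profile(ComplexStructure(atoms, "LIG"), cutoff=10.5)
        assert profile.total == 0

    def test_single_cc_pair(self):
        atoms = (
            AtomRecord("C", 0, 0, 0, "ALA", 1, "A", "CA", False),
            AtomRecord("C", 3.0, 0, 0, "LIG", 1, "L", "C1", True),
        )
        profile = contact_profile(ComplexStructure(atoms, "LIG"))
        assert profile.counts["CC"] == 1
        assert profile.total == 1

    def test_hydrogens_excluded(self):
        atoms = (
            AtomRecord("H", 0, 0, 0, "ALA", 1, "A", "H", False),
            AtomRecord("C", 1.0, 0, 0, "ALA", 1, "A", "CA", False),
            AtomRecord("C", 3.0, 0, 0, "LIG", 1, "L", "C1", True),
            AtomRecord("H", 3.5, 0, 0, "LIG", 1, "L", "H1", True),
        )
        profile = contact_profile(ComplexStructure(atoms, "LIG"))
        assert profile.total == 1  # only the heavy CC pair

    def test_random_complexes_match_brute_force_oracle(self):
        """100 random 30-atom complexes against the double-loop oracle."""
        rng = random.Random(77)
        for _ in range(100):
            cplx = _random_complex(rng)
            profile = contact_profile(cplx, cutoff=6.0)
            expected = oracle_contact_counts(
                cplx.protein_atoms, cplx.ligand_atoms, 6.0
            )
            assert profile.counts == expected

    def test_rigid_body_invariance(self):
        rng = random.Random(8)
        np_rng = random.Random(9)
        for _ in range(20):
            cplx = _random_complex(rng)
            rot = _random_rotation(np_rng)
            moved = _transform(cplx, rot, np.array([5.0, -3.0, 11.0]))
            assert contact_profile(cplx, 6.0).counts == contact_profile(moved, 6.0).counts

    def test_total_contacts_monotone_in_cutoff(self):
        rng = random.Random(13)
        cplx = _random_complex(rng)
        totals = [contact_profile(cplx, c).total for c in (2.0, 4.0, 8.0, 12.0, 20.0)]
        assert totals == sorted(totals)

    def test_planted_counts_reproduced_exactly(self):
        wanted = {"CC": 4, "CO": 2}
        cplx = complex_from_contacts(wanted)
        profile = contact_profile(cplx, cutoff=10.5)
        assert profile.counts["CC"] == 4
        assert profile.counts["CO"] == 2
        assert profile.total == 6


class TestAffinityModel:
    def test_zero_profile_returns_intercept(self):
        profile = ContactProfile({c: 0 for c in CONTACT_CLASSES}, 10.5)
        model = AffinityModel(intercept=-1.5, coefficients={c: -0.1 for c in CONTACT_CLASSES})
        assert predict_affinity(profile, model) == pytest.approx(-1.5)

    def test_doubling_counts_doubles_excess_over_intercept(self):
        rng = random.Random(2)
        counts = {c: rng.randint(0, 20) for c in CONTACT_CLASSES}
        doubled = {c: 2 * v for c, v in counts.items()}
        model = AffinityModel.default()
        d1 = predict_affinity(ContactProfile(counts, 10.5), model) - model.intercept
        d2 = predict_affinity(ContactProfile(doubled, 10.5), model) - model.intercept
        assert d2 == pytest.approx(2 * d1)

    def test_unit_coefficients_sum_counts(self):
        counts = dict(zip(CONTACT_CLASSES, [1, 2, 3, 4, 5, 1, 0, 0, 1, 0]))
        model = AffinityModel(intercept=0.0, coefficients={c: 1.0 for c in CONTACT_CLASSES})
        assert predict_affinity(ContactProfile(counts, 10.5), model) == 17.0

    def test_superposition_to_machine_precision(self):
        rng = random.Random(4)
        a = {c: rng.randint(0, 30) for c in CONTACT_CLASSES}
        b = {c: rng.randint(0, 30) for c in CONTACT_CLASSES}
        s = {c: a[c] + b[c] for c in CONTACT_CLASSES}
        model = AffinityModel.default()
        da = predict_affinity(ContactProfile(a, 10.5), model) - model.intercept
        db = predict_affinity(ContactProfile(b, 10.5), model) - model.intercept
        ds = predict_affinity(ContactProfile(s, 10.5), model) - model.intercept
        assert math.isclose(ds, da + db, rel_tol=0, abs_tol=1e-12)

    def test_model_file_round_trip(self, tmp_path):
        model = AffinityModel.default()
        path = tmp_path / "model.txt"
        lines = [f"intercept {model.intercept}"]
        lines += [f"{c} {model.coefficients[c]}" for c in CONTACT_CLASSES]
        path.write_text("\n".join(lines) + "\n")
        loaded = AffinityModel.from_file(path)
        assert loaded.coefficients == model.coefficients
        assert loaded.intercept == model.intercept


class TestPocketResidues:
    def test_far_ligand_empty_pocket(self):
        atoms = (
            AtomRecord("C", 0, 0, 0, "ALA", 1, "A", "CA", False),
            AtomRecord("C", 50.0, 0, 0, "LIG", 1, "L", "C1", True),
        )
        assert pocket_residues(ComplexStructure(atoms, "LIG"), 5.0) == []

    def test_single_residue_in_range(self):
        atoms = (
            AtomRecord("C", 3.0, 0, 0, "ALA", 7, "A", "CA", False),
            AtomRecord("C", 40.0, 0, 0, "GLY", 8, "A", "CA", False),
            AtomRecord("C", 0, 0, 0, "LIG", 1, "L", "C1", True),
        )
        assert pocket_residues(ComplexStructure(atoms, "LIG"), 5.0) == [("A", 7, "ALA")]

    def test_planted_pocket_membership(self):
        spec = PocketSpec(n_residues=10, pocket_indices=(3, 7, 9))
        cplx, _ = generate_complex(spec, seed=1)
        found = pocket_residues(cplx, spec.pocket_cutoff)
        assert [r[1] for r in found] == [3, 7, 9]


class TestComparePockets:
    def test_identity_mapping_when_comparison_is_reference(self):
        cplx, _ = generate_complex(seed=2)
        ref_seq, _ = chain_sequence(cplx)
        pc = compare_pockets(cplx, ref_seq)
        assert set(pc.statuses) == {"identical"}
        assert pc.n_insertions == 0

    def test_single_pocket_substitution_detected(self):
        cplx, truth = generate_complex(seed=3)
        ref_seq, _ = chain_sequence(cplx)
        pos = truth.pocket_edit["pocket_indices"][1]
        new = "W" if ref_seq[pos - 1] != "W" else "F"
        mutated = apply_edit_script(ref_seq, substitutions={pos: new})
        pc = compare_pockets(cplx, mutated)
        assert pc.n_substituted == 1
        assert pc.n_identical == len(pc.residues) - 1

    def test_planted_edit_script_two_subs_one_insertion(self):
        """2 substitutions + 1 single-residue insertion inside the pocket
        are reported as exactly (2 substituted, 1 insertion)."""
        spec = PocketSpec(n_residues=40, pocket_indices=(18, 19, 20, 21, 22))
        cplx, _ = generate_complex(spec, seed=4)
        ref_seq, _ = chain_sequence(cplx)
        subs = {}
        for pos in (19, 22):
            subs[pos] = "W" if ref_seq[pos - 1] != "W" else "F"
        ins_res = "P" if "P" not in ref_seq[19:21] else "G"
        comparison = apply_edit_script(ref_seq, substitutions=subs,
                                       insertions={20: ins_res})
        pc = compare_pockets(cplx, comparison)
        assert pc.n_substituted == 2
        assert pc.n_insertions == 1
        assert pc.n_deleted == 0

    def test_low_identity_projection_rejected(self):
        cplx, _ = generate_complex(seed=5)
        hostile = "W" * 60
        with pytest.raises(ValueError, match="unreliable"):
            compare_pockets(cplx, hostile)


class TestGenerateComplex:
    def test_isolated_ligand_spec_zero_contacts(self):
        spec = PocketSpec(n_residues=8, pocket_indices=())
        cplx, _ = generate_complex(spec, seed=6)
        assert contact_profile(cplx, spec.contact_cutoff).total == 0

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValueError):
            PocketSpec(n_residues=5, pocket_indices=(9,))
        with pytest.raises(ValueError):
            PocketSpec(pocket_cutoff=12.0, contact_cutoff=10.5)

    def test_profile_matches_oracle_on_generated_geometry(self):
        cplx, _ = generate_complex(seed=8)
        profile = contact_profile(cplx, 10.5)
        assert profile.counts == oracle_contact_counts(
            cplx.protein_atoms, cplx.ligand_atoms, 10.5
        )
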