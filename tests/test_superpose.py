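"""Kabsch superposition, residue pairing and iterative outlier rejection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xlcal.fixtures import make_helix_model
from xlcal.superpose import align_models, kabsch, pair_residues

from conftest import random_rotation


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: optimal-rotation RMSD via scipy's quaternion method."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / np.sqrt(len(a)))


class TestKabsch:
    def test_identical_sets(self):
        a = np.random.default_rng(0).uniform(-10, 10, size=(8, 3))
        result = kabsch(a, a)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_invariance(self):
        a = np.random.default_rng(1).uniform(-10, 10, size=(6, 3))
        result = kabsch(a, a + np.array([5.0, 0.0, 0.0]))
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-10, 10, size=(4, 3))
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        b = a @ rot.T + rng.normal(0, 0.5, size=a.shape)
        assert kabsch(a, b).rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-6)

    def test_oracle_agreement_many_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(4, 30)
            a = rng.uniform(-20, 20, size=(n, 3))
            b = (a + rng.normal(0, 1.0, size=a.shape)) @ random_rotation(rng).T
            assert kabsch(a, b).rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-6)

    def test_symmetric_rmsd(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-10, 10, size=(10, 3))
        b = a + rng.normal(0, 2, size=a.shape)
        assert kabsch(a, b).rmsd == pytest.approx(kabsch(b, a).rmsd, abs=1e-9)

    def test_rigid_transform_invariance(self):
        """RMSD unchanged when both sets are moved by a common rigid transform."""
        rng = np.random.default_rng(5)
        a = rng.uniform(-10, 10, size=(12, 3))
        b = a + rng.normal(0, 1, size=a.shape)
        base = kabsch(a, b).rmsd
        for _ in range(10):
            rot = random_rotation(rng)
            t = rng.uniform(-50, 50, size=3)
            assert kabsch(a @ rot.T + t, b @ rot.T + t).rmsd == pytest.approx(base, abs=1e-9)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(-10, 10, size=(10, 3))
        b = a * np.array([-1.0, 1.0, 1.0])  # mirror image
        result = kabsch(a, b)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        assert result.rmsd > 0.5

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        assert kabsch(a, a).degenerate


class TestPairResidues:
    def test_identity_pairing(self):
        m = make_helix_model(12, lysines=(3, 7))
        a, b, pairing = pair_residues(m, m, mode="calpha")
        assert len(pairing) == 12
        assert all(pa == pb for pa, pb, _ in pairing)
        np.testing.assert_allclose(a, b)

    def test_truncation_pairs_remainder(self):
        """Full-length vs ΔN-truncated: the truncated run is omitted, rest paired."""
        full = make_helix_model(30, lysines=(5, 25), model_id="full")
        trunc = make_helix_model(30, lysines=(5, 25), model_id="d")
        trunc.chains["A"] = trunc.chains["A"][10:]  # drop N-terminal 10 residues
        a, b, pairing = pair_residues(full, trunc, mode="calpha")
        assert len(pairing) == 20
        paired_full = {pa[1] for pa, _, _ in pairing}
        assert paired_full == set(range(11, 31))

    def test_all_atom_mode_uses_common_atoms(self):
        m1 = make_helix_model(10, lysines=(5,))
        m2 = make_helix_model(10, lysines=())  # no NZ on residue 5
        m2.chains["A"][4].res_name = "LYS"  # same sequence, side chain missing
        _, _, pairing = pair_residues(m1, m2, mode="all_atom")
        res5_atoms = {name for pa, _, name in pairing if pa[1] == 5}
        assert res5_atoms == {"N", "CA", "C"}

    def test_no_pairs_errors(self):
        m1 = make_helix_model(6)
        m2 = make_helix_model(6)
        for res in m2.chains["A"]:
            res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(ValueError):
            pair_residues(m1, m2, mode="calpha")


class TestAlignModels:
    def test_identical_models_zero_rmsd_both_modes(self):
        m = make_helix_model(20, lysines=(4, 12))
        for refine in (None, (2.0, 5)):
            result = align_models(m, m, refine=refine)
            assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_outlier_rejection_recovers_exact_core(self):
        """90% exact matches + 10% displaced 15 Å: refinement rejects the displaced set."""
        a = make_helix_model(40, model_id="ref")
        b = make_helix_model(40, model_id="mob")
        displaced = [3, 17, 29, 35]  # 4 of 40 residues
        for idx in displaced:
            for atom in b.chains["A"][idx].atoms:
                atom.coords = atom.coords + np.array([15.0, 0.0, 0.0])
        plain = align_models(a, b, refine=None)
        refined = align_models(a, b, refine=(2.0, 5))
        assert plain.rmsd > 3.0
        assert refined.rmsd == pytest.approx(0.0, abs=1e-6)
        assert refined.n_pairs_rejected == len(displaced)
        assert {pa[1] - 1 for pa, _, _ in refined.rejected_pairs} == set(displaced)

    def test_refined_never_worse_than_unrefined(self):
        """Rejection can only shrink the fitted set's residual (50 random fixtures)."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = make_helix_model(25)
            b = make_helix_model(25)
            for res in b.chains["A"]:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(0, 1.0, size=3)
            plain = align_models(a, b, refine=None)
            refined = align_models(a, b, refine=(2.0, 5))
            assert refined.rmsd <= plain.rmsd + 1e-12

    def test_all_rejected_errors(self):
        a = make_helix_model(10)
        b = make_helix_model(10)
        rng = np.random.default_rng(12)
        for res in b.chains["A"]:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0, 8.0, size=3)
        with pytest.raises(ValueError, match="too many pairs"):
            align_models(a, b, refine=(0.01, 50))

    def test_two_stage_calpha_fit_allatom_report(self):
        """Fit on Cα pairs, report all-atom RMSD: side-chain error shows only in the report."""
        a = make_helix_model(20, lysines=(5, 15))
        b = make_helix_model(20, lysines=(5, 15))
        for res in b.chains["A"]:
            nz = res.get("NZ")
            if nz is not None:
                nz.coords = nz.coords + np.array([0.0, 0.0, 4.0])
        calpha_only = align_models(a, b, mode="calpha")
        two_stage = align_models(a, b, mode="calpha", rmsd_atoms="all_atom")
        assert calpha_only.rmsd == pytest.approx(0.0, abs=1e-9)
        assert two_stage.rmsd > 0.5
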