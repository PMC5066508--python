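"""Backbone reading and Kabsch superposition, checked against a grid-search oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import minihelix as mx
from conftest import random_rotation


def brute_force_rmsd(P, Q, coarse_deg=15.0):
    """Independent superposition oracle: dense Euler-angle grid search over
    proper rotations (translation solved by centering), then Nelder-Mead
    refinement from the best grid point. No SVD involved."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        d = Pc @ R.T - Qc
        return np.sqrt((d**2).sum() / len(Pc))

    step = np.deg2rad(coarse_deg)
    grid = np.arange(0, 2 * np.pi, step)
    half = np.arange(-np.pi / 2, np.pi / 2 + 1e-9, step)
    best_angles, best = None, np.inf
    for a in grid:
        for b in half:
            for c in grid:
                val = rmsd_of((a, b, c))
                if val < best:
                    best, best_angles = val, (a, b, c)
    res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return min(best, res.fun)


def write_pdb(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestReadBackbone:
    def test_synthetic_hairpin_yields_102_points(self, clean_hairpin_pdb):
        sel = mx.read_backbone(clean_hairpin_pdb, "A", (1, 17))
        assert sel.n_points == 17 * 6 == 102
        assert sel.n_residues == 17
        assert sel.missing == ()
        assert sel.labels[0] == (1, "P") and sel.labels[-1] == (17, "O3'")

    def test_range_outside_chain_errors(self, clean_hairpin_pdb):
        with pytest.raises(ValueError, match="missing"):
            mx.read_backbone(clean_hairpin_pdb, "A", (10, 30))

    def test_unknown_chain_errors(self, clean_hairpin_pdb):
        with pytest.raises(ValueError, match="chain"):
            mx.read_backbone(clean_hairpin_pdb, "B", (1, 17))

    def test_p_only_atom_set(self, clean_hairpin_pdb):
        sel = mx.read_backbone(clean_hairpin_pdb, "A", (1, 17), "p")
        assert sel.n_points == 17


class TestKabschSuperpose:
    def test_identity_gives_zero(self, clean_hairpin_pdb):
        sel = mx.read_backbone(clean_hairpin_pdb, "A", (1, 17))
        result = mx.kabsch_superpose(sel, sel)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_atoms == 102

    def test_rigid_copy_gives_zero(self):
        rng = np.random.default_rng(42)
        P = rng.normal(scale=5.0, size=(20, 3))
        R = random_rotation(rng)
        Q = P @ R.T + np.array([1.0, -4.0, 2.5])
        result = mx.kabsch_superpose(P, Q)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.rotation, R, atol=1e-8)
        assert result.transform(P) == pytest.approx(Q, abs=1e-8)

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            P = rng.normal(size=(8, 3))
            Q = rng.normal(size=(8, 3))
            result = mx.kabsch_superpose(P, Q)
            assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(
                result.rotation @ result.rotation.T, np.eye(3), atol=1e-9
            )

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        assert mx.kabsch_superpose(P, Q).rmsd == pytest.approx(
            mx.kabsch_superpose(Q, P).rmsd, abs=1e-9
        )

    def test_rmsd_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        base = mx.kabsch_superpose(P, Q).rmsd
        P2 = P @ random_rotation(rng).T + rng.normal(size=3)
        assert mx.kabsch_superpose(P2, Q).rmsd == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        P = rng.normal(scale=3.0, size=(10, 3))
        Q = rng.normal(scale=3.0, size=(10, 3))
        kabsch = mx.kabsch_superpose(P, Q).rmsd
        oracle = brute_force_rmsd(P, Q)
        assert kabsch <= oracle + 1e-9  # Kabsch is the optimum
        assert abs(kabsch - oracle) < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            mx.kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            mx.kabsch_superpose(line, line)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            mx.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def two_arm_pdb(tmp_path, noise=0.0, seed=0):
    """One chain holding two 17-residue copies of the same hairpin, the second
    renumbered 18-34 and rigidly displaced."""
    rng = np.random.default_rng(seed)
    base = mx.generate_hairpin_coords(17, noise=noise, seed=seed)
    lines = [l for l in base.splitlines() if l.startswith("ATOM")]
    shifted = []
    R = random_rotation(rng)
    t = np.array([25.0, -10.0, 5.0])
    serial = len(lines)
    for line in lines:
        resseq = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        new = R @ xyz + t
        serial += 1
        shifted.append(
            f"ATOM  {serial:5d} {line[12:16]} {line[17:20]} A{resseq + 17:4d}    "
            f"{new[0]:8.3f}{new[1]:8.3f}{new[2]:8.3f}  1.00  0.00          "
            f"{line[76:78].strip():>2s}"
        )
    return "\n".join(lines + shifted) + "\nEND\n"


class TestOverlayAcVsT:
    def test_two_copies_of_same_hairpin_superpose_to_zero(self, tmp_path):
        path = write_pdb(tmp_path, "two.pdb", two_arm_pdb(tmp_path))
        result = mx.overlay_ac_vs_t(path, (1, 17), (18, 34))
        # PDB coordinates carry 3 decimals, so "identical" copies differ by
        # up to 5e-4 A per coordinate after rounding
        assert result.rmsd == pytest.approx(0.0, abs=2e-3)
        assert result.n_atoms == 102

    def test_rmsd_monotone_in_noise(self, tmp_path, clean_hairpin_pdb):
        clean = mx.read_backbone(clean_hairpin_pdb, "A", (1, 17))
        rmsds = []
        for sigma in (0.1, 0.3, 0.6):
            noisy_path = write_pdb(
                tmp_path, f"n{sigma}.pdb",
                mx.generate_hairpin_coords(17, noise=sigma, seed=21),
            )
            noisy = mx.read_backbone(noisy_path, "A", (1, 17))
            rmsds.append(mx.kabsch_superpose(clean, noisy).rmsd)
        assert rmsds[0] < rmsds[1] < rmsds[2]
        # per-atom Gaussian displacement of sigma per coordinate gives an
        # expected RMSD near sigma * sqrt(3); allow a broad simulation band
        for sigma, rmsd in zip((0.1, 0.3, 0.6), rmsds):
            assert 0.0 < rmsd < 3.0 * sigma

    def test_non_17_residue_range_rejected(self, tmp_path):
        path = write_pdb(tmp_path, "two.pdb", two_arm_pdb(tmp_path))
        with pytest.raises(ValueError, match="17 residues"):
            mx.overlay_ac_vs_t(path, (1, 16), (18, 34))
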