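"""Kabsch superposition, correspondence-search docking, Ca RMSD."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from icebound.ice_lattice import build_ice_lattice, extract_plane_patch
from icebound.structio import WaterSet
from icebound.superpose import calpha_rmsd, dock_waters_to_plane, kabsch
from icebound.synthetic_data import gen_reference_structure, gen_transformed_patch


def brute_force_rmsd(P, Q, grid_step_deg=20.0):
    """Independent oracle: rotation-grid search + local refinement.

    For fixed rotation the optimal translation matches centroids, so the
    objective is a function of three Euler angles only.
    """

    def objective(angles):
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        return np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P))

    best = None
    grid = np.arange(-180.0, 180.0, grid_step_deg)
    for a in grid:
        for b in np.arange(-90.0, 90.1, grid_step_deg):
            for c in grid:
                v = objective([a, b, c])
                if best is None or v < best[0]:
                    best = (v, [a, b, c])
    res = minimize(objective, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    return min(best[0], res.fun)


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(6, 3))
        r = kabsch(P, P)
        assert r.rmsd < 1e-12
        assert np.allclose(r.rotation, np.eye(3), atol=1e-10)

    def test_planted_transform_recovered(self, rng):
        P = rng.normal(size=(10, 3)) * 4
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3) * 10
        r = kabsch(P, P @ R.T + t)
        assert np.abs(r.rotation - R).max() < 1e-6
        assert r.rmsd < 1e-6
        assert np.abs(r.translation - t).max() < 1e-6

    def test_matches_brute_force_grid_oracle(self, rng):
        P = rng.normal(size=(4, 3)) * 3
        Q = rng.normal(size=(4, 3)) * 3
        r = kabsch(P, Q)
        assert r.rmsd == pytest.approx(brute_force_rmsd(P, Q), abs=1e-4)

    def test_proper_rotation_enforced(self, rng):
        # reflected target: best proper fit must still have det +1
        P = rng.normal(size=(7, 3))
        Q = P.copy()
        Q[:, 0] *= -1
        r = kabsch(P, Q)
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)
        assert r.rotation.T @ r.rotation == pytest.approx(np.eye(3), abs=1e-8)

    def test_collinear_raises(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch(P, P)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rmsd_invariant_under_joint_rigid_motion(self, rng):
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        base = kabsch(P, Q).rmsd
        M = Rotation.random(random_state=rng).as_matrix()
        s = rng.normal(size=3) * 7
        moved = kabsch(P @ M.T + s, Q @ M.T + s).rmsd
        assert moved == pytest.approx(base, abs=1e-9)


class TestDocking:
    def test_patch_subset_docks_to_zero(self, basal_patch):
        ws = WaterSet([f"w{i}" for i in range(11)], basal_patch.oxygens[:11].copy())
        res = dock_waters_to_plane(ws, basal_patch, n_starts=24, seed=0)
        assert res.rmsd < 1e-6

    def test_planted_transform_and_noise_band(self, basal_patch):
        # 50 replicates; noise sigma=0.2 A per coordinate
        sigma = 0.2
        rmsds = []
        for rep in range(50):
            mot = gen_transformed_patch(basal_patch, 11, noise_sigma=sigma, seed=rep)
            res = dock_waters_to_plane(mot.waters, basal_patch, n_starts=24, seed=0)
            rmsds.append(res.rmsd)
        lo, hi = 0.5 * sigma * np.sqrt(3), 2.0 * sigma * np.sqrt(3)
        assert lo <= np.mean(rmsds) <= hi

    def test_noise_free_transform_recovered(self, basal_patch):
        mot = gen_transformed_patch(basal_patch, 11, noise_sigma=0.0, seed=5)
        res = dock_waters_to_plane(mot.waters, basal_patch, n_starts=24, seed=0)
        assert res.rmsd < 1e-6
        # returned transform must undo the planted one on the water set
        moved = res.transform(mot.waters.coords)
        cols = [res.correspondence[w] for w in mot.waters.ids]
        d = np.linalg.norm(moved - basal_patch.oxygens[cols], axis=1)
        assert d.max() < 1e-5

    def test_consistency_with_kabsch_on_final_correspondence(self, basal_patch):
        mot = gen_transformed_patch(basal_patch, 9, noise_sigma=0.3, seed=2)
        res = dock_waters_to_plane(mot.waters, basal_patch, n_starts=16, seed=0)
        cols = [res.correspondence[w] for w in mot.waters.ids]
        direct = kabsch(
            mot.waters.coords,
            basal_patch.oxygens,
            pairing=list(enumerate(cols)),
        )
        assert res.rmsd <= direct.rmsd + 1e-9

    def test_more_starts_never_worse(self, basal_patch):
        mot = gen_transformed_patch(basal_patch, 10, noise_sigma=0.4, seed=11)
        r_few = dock_waters_to_plane(mot.waters, basal_patch, n_starts=4, seed=3)
        r_many = dock_waters_to_plane(mot.waters, basal_patch, n_starts=48, seed=3)
        assert r_many.rmsd <= r_few.rmsd + 1e-9

    def test_deterministic_given_seed(self, basal_patch):
        mot = gen_transformed_patch(basal_patch, 10, noise_sigma=0.3, seed=4)
        a = dock_waters_to_plane(mot.waters, basal_patch, n_starts=16, seed=9)
        b = dock_waters_to_plane(mot.waters, basal_patch, n_starts=16, seed=9)
        assert a.rmsd == b.rmsd
        assert np.array_equal(a.rotation, b.rotation)

    def test_patch_too_small_raises(self, basal_patch):
        from icebound.ice_lattice import IcePlanePatch

        tiny = IcePlanePatch(
            "basal", 1.0, basal_patch.oxygens[:5], basal_patch.basis, basal_patch.normal
        )
        ws = WaterSet([f"w{i}" for i in range(6)], basal_patch.oxygens[:6].copy())
        with pytest.raises(ValueError, match="larger patch"):
            dock_waters_to_plane(ws, tiny)


class TestCalphaRmsd:
    def test_self_is_zero(self, reference_structure):
        st, _ = reference_structure
        assert calpha_rmsd(st, st) < 1e-12

    def test_isotropic_perturbation_scaling(self, reference_structure, rng):
        # RMSD after fitting ~ sigma * sqrt(3) for large N (small DOF loss)
        from dataclasses import replace

        from icebound.structio import Structure

        st, _ = reference_structure
        sigma = 0.2
        atoms = [
            replace(a, xyz=tuple(np.asarray(a.xyz) + rng.normal(0, sigma, 3)))
            for a in st.atoms
        ]
        st2 = Structure(atoms, st.cell, st.space_group, st.sym_ops, "PERT")
        r = calpha_rmsd(st, st2)
        expect = sigma * np.sqrt(3)
        assert 0.8 * expect <= r <= 1.1 * expect

    def test_too_few_common_residues(self, reference_structure):
        from icebound.structio import Structure

        st, _ = reference_structure
        few = Structure([a for a in st.atoms if a.residue_number <= 2], st.cell)
        with pytest.raises(ValueError, match="common"):
            calpha_rmsd(st, few)
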