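"""Rigid-body superposition: Kabsch, water-to-ice-plane docking, Ca RMSD.

``kabsch`` is the closed-form least-squares proper rotation (reflections
rejected — the chirality of a water motif is physically meaningful).
``dock_waters_to_plane`` searches the correspondence as well: a bound-water
set has no a-priori pairing with lattice oxygens, so an iterative-closest-
point loop alternates an optimal injective assignment (Hungarian algorithm
on the pairwise distance matrix) with a Kabsch fit, from many deterministic
and seeded-random starts.  The reported RMSD is the minimum over starts —
the figure of merit for how ice-like a bound-water motif is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .ice_lattice import IcePlanePatch
from .structio import Structure, WaterSet

__all__ = ["SuperpositionResult", "kabsch", "dock_waters_to_plane", "calpha_rmsd"]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform ``x -> rotation @ x + translation`` and RMSD."""

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int
    correspondence: dict = field(default_factory=dict)  # water_id -> target index
    converged: bool = True
    n_starts: int = 1
    seed: int | None = None

    def transform(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": [list(map(float, row)) for row in self.rotation],
            "translation": [float(v) for v in self.translation],
            "rmsd": float(self.rmsd),
            "n_pairs": int(self.n_pairs),
            "correspondence": {str(k): int(v) for k, v in self.correspondence.items()},
            "converged": bool(self.converged),
            "n_starts": int(self.n_starts),
            "seed": self.seed,
        }


def _kabsch_core(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation R and translation t minimising ||R P + t - Q||."""
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid**2).sum() / len(P)))
    return R, t, rmsd


def kabsch(
    P: np.ndarray,
    Q: np.ndarray,
    pairing: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of paired point sets.

    Parameters
    ----------
    P, Q : (n, 3) arrays
        Moving and fixed point sets.
    pairing : list of (i, j), optional
        Index pairs (P[i] matched to Q[j]); identity pairing by default.

    Raises on fewer than 3 pairs or (near-)collinear configurations, for
    which the rotation about the degenerate axis is undetermined.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if pairing is None:
        if len(P) != len(Q):
            raise ValueError("P and Q must have equal length without explicit pairing")
        pairing = [(i, i) for i in range(len(P))]
    if len(pairing) < 3:
        raise ValueError("at least 3 pairs are required")
    ip = [i for i, _ in pairing]
    jq = [j for _, j in pairing]
    Ps, Qs = P[ip], Q[jq]
    # collinearity check: rank of the centered moving set
    sv = np.linalg.svd(Ps - Ps.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point set: rotation undetermined")
    R, t, rmsd = _kabsch_core(Ps, Qs)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=len(pairing),
        correspondence={i: j for i, j in pairing},
    )


# ---------------------------------------------------------------------------
# correspondence-search docking
# ---------------------------------------------------------------------------

def _assignment_rmsd(
    moved: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal injective assignment of moved points to target points."""
    diff = moved[:, None, :] - target[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)
    rows, cols = linear_sum_assignment(cost)
    rmsd = float(np.sqrt(cost[rows, cols].sum() / len(rows)))
    return cols, rmsd


def _icp_from(
    P: np.ndarray,
    target: np.ndarray,
    R0: np.ndarray,
    t0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    R, t = R0, t0
    prev = np.inf
    cols = None
    converged = False
    for _ in range(max_iter):
        moved = P @ R.T + t
        cols, rmsd = _assignment_rmsd(moved, target)
        R, t, fit_rmsd = _kabsch_core(P, target[cols])
        if abs(prev - fit_rmsd) < tol:
            converged = True
            prev = fit_rmsd
            break
        prev = fit_rmsd
    moved = P @ R.T + t
    cols, rmsd = _assignment_rmsd(moved, target)
    return R, t, cols, rmsd, converged


def _seed_rotations(
    P: np.ndarray, patch_normal: np.ndarray, n_inplane: int = 12
) -> list[np.ndarray]:
    """Deterministic starts: water-plane normal aligned to ±patch normal,
    swept through in-plane angles."""
    c = P - P.mean(axis=0)
    _, _, Vt = np.linalg.svd(c)
    w_normal = Vt[2]
    seeds = []
    for sign in (1.0, -1.0):
        target_n = sign * patch_normal
        v = np.cross(w_normal, target_n)
        s = np.linalg.norm(v)
        if s < 1e-12:
            R_align = np.eye(3)
        else:
            angle = np.arctan2(s, float(w_normal @ target_n))
            R_align = Rotation.from_rotvec(v / s * angle).as_matrix()
        for k in range(n_inplane):
            ang = 2 * np.pi * k / n_inplane
            R_spin = Rotation.from_rotvec(target_n * ang).as_matrix()
            seeds.append(R_spin @ R_align)
    return seeds


def dock_waters_to_plane(
    waters: WaterSet,
    patch: IcePlanePatch,
    n_starts: int = 64,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
) -> SuperpositionResult:
    """Dock a bound-water set onto an ice-plane patch (rigid, injective).

    Multi-start iterative closest point with exact injective assignment:
    each start alternates (a) the optimal one-to-one matching of each water
    to a distinct lattice oxygen (Hungarian algorithm) and (b) the Kabsch
    fit on that matching, until the RMSD change falls below ``tol``.
    Starts comprise deterministic plane-aligned seeds plus seeded-random
    orientations; the best (lowest-RMSD) converged solution is returned.
    Deterministic for a given seed.
    """
    P = waters.coords
    target = patch.oxygens
    if len(target) < len(P):
        raise ValueError(
            f"patch has {len(target)} oxygens < {len(P)} waters; use a larger patch"
        )
    if len(P) < 3:
        raise ValueError("at least 3 waters are required for docking")

    rng = np.random.default_rng(seed)
    starts = _seed_rotations(P, patch.normal)
    n_random = max(0, n_starts - len(starts))
    if n_random:
        starts.extend(Rotation.random(n_random, random_state=rng).as_matrix())
    starts = starts[:max(n_starts, 1)]

    Pc = P.mean(axis=0)
    Tc = target.mean(axis=0)
    best = None
    any_converged = False
    for R0 in starts:
        t0 = Tc - R0 @ Pc
        R, t, cols, rmsd, conv = _icp_from(P, target, R0, t0, tol, max_iter)
        any_converged = any_converged or conv
        if best is None or rmsd < best[3] - 1e-12:
            best = (R, t, cols, rmsd, conv)
    R, t, cols, rmsd, conv = best
    corr = {wid: int(c) for wid, c in zip(waters.ids, cols)}
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=len(P),
        correspondence=corr,
        converged=conv,
        n_starts=len(starts),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calpha structure comparison
# ---------------------------------------------------------------------------

def calpha_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> float:
    """Ca RMSD between two chains after Kabsch superposition.

    Ca atoms are paired by residue number; both chains must share at least
    3 common residues.
    """
    if chain_a is None:
        chain_a = struct_a.chains[0]
    if chain_b is None:
        chain_b = struct_b.chains[0]
    ca_a = {
        a.residue_number: a.coords
        for a in struct_a.select(chain=chain_a, atom_names=["CA"])
    }
    ca_b = {
        a.residue_number: a.coords
        for a in struct_b.select(chain=chain_b, atom_names=["CA"])
    }
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common Ca residues between chains "
            f"{chain_a!r} and {chain_b!r}; need >= 3"
        )
    P = np.array([ca_a[r] for r in common])
    Q = np.array([ca_b[r] for r in common])
    return kabsch(P, Q).rmsd
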