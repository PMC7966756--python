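"""Seeded generators for every fixture the pipeline needs.

Each generator plants a known ground truth (spacing, angle, transform,
midpoint, lifetime, ...) and records it alongside the generated data, so
every analysis stage can be exercised as a parameter-recovery problem.
Generation is deterministic: the same seed reproduces identical arrays
(one global seed fans out to independent substreams per generator).

``gen_reference_structure`` builds a complete synthetic stand-in for a
microbial antifreeze-protein crystal: a single-chain scaffold in an
orthorhombic P2(1)2(1)2(1) cell with the three bound-water motifs planted
on its ice-binding site at the geometry reported for the TisAFP isoform
family (zigzag spacing 2.86 A / angle 116 deg, trough interval 4.6 A,
ring edge 2.74 A with 3.4 A hydrophobic contact), 54 IBS waters and a
configurable structure-wide water count.  It is a synthetic object — the
scaffold is not a real protein fold — but every planted quantity is
recoverable by the corresponding pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hbond_residence import HBondEventTable
from .ice_lattice import IcePlanePatch
from .structio import (
    Atom,
    IBS_RANGES,
    Structure,
    WaterSet,
    space_group_ops,
    write_structure,
)
from .thermal_unfolding import MeltTrace

__all__ = [
    "PlantedMotif",
    "gen_zigzag",
    "gen_trough",
    "gen_ring",
    "gen_transformed_patch",
    "gen_cd_trace",
    "gen_telegraph_hbonds",
    "gen_toy_structure",
    "gen_reference_structure",
]


@dataclass
class PlantedMotif:
    """Generated data plus the ground truth it was built from."""

    kind: str  # {zigzag, trough, ring, lattice_patch}
    waters: WaterSet
    truth: dict = field(default_factory=dict)
    atoms: list[Atom] = field(default_factory=list)  # side-chain anchors, if any


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# geometric motifs
# ---------------------------------------------------------------------------

def gen_zigzag(
    n_waters: int = 12,
    spacing: float = 2.86,
    angle: float = 116.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> PlantedMotif:
    """Planar zigzag water chain with given bond spacing and interior angle.

    Consecutive bond directions alternate by ±(180 - angle)/2 about the
    chain axis, so every interior three-water angle equals ``angle``
    exactly before noise.  Isotropic Gaussian noise of ``noise_sigma`` A
    per coordinate is then added.
    """
    if n_waters < 3:
        raise ValueError("a zigzag needs at least 3 waters")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    phi = math.radians((180.0 - angle) / 2.0)
    pts = [np.zeros(3)]
    for k in range(n_waters - 1):
        s = 1.0 if k % 2 == 0 else -1.0
        step = spacing * np.array([math.cos(phi), s * math.sin(phi), 0.0])
        pts.append(pts[-1] + step)
    coords = np.array(pts) + np.asarray(origin, dtype=float)
    rng = _rng(seed)
    coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    ws = WaterSet([f"zz{i}" for i in range(n_waters)], coords)
    return PlantedMotif(
        "zigzag",
        ws,
        truth={
            "spacing": spacing,
            "angle": angle,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


def gen_trough(
    n_waters: int = 6,
    interval: float = 4.6,
    noise_sigma: float = 0.0,
    seed: int = 0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (1.0, 0.0, 0.0),
) -> PlantedMotif:
    """Collinear water row at a fixed repeat interval plus noise."""
    if n_waters < 3:
        raise ValueError("a trough needs at least 3 waters")
    if interval <= 0:
        raise ValueError("interval must be positive")
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    coords = np.asarray(origin, dtype=float) + np.outer(
        np.arange(n_waters) * interval, u
    )
    rng = _rng(seed)
    coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    ws = WaterSet([f"tr{i}" for i in range(n_waters)], coords)
    return PlantedMotif(
        "trough",
        ws,
        truth={"interval": interval, "noise_sigma": noise_sigma, "seed": seed},
    )


def _ring_height_for_contact(
    n_waters: int,
    water_radius: float,
    carbon_radius: float,
    target_mean_contact: float,
) -> float:
    """Solve for the ring-plane offset giving a target mean nearest-carbon
    distance (bisection; the mean contact grows monotonically with height)."""
    cang = np.arange(6) * (2 * np.pi / 6)
    carbons = np.stack(
        [carbon_radius * np.cos(cang), carbon_radius * np.sin(cang), np.zeros(6)], axis=1
    )
    wang = np.arange(n_waters) * (2 * np.pi / n_waters)

    def mean_contact(h: float) -> float:
        ws = np.stack(
            [
                water_radius * np.cos(wang),
                water_radius * np.sin(wang),
                np.full(n_waters, h),
            ],
            axis=1,
        )
        d = np.linalg.norm(ws[:, None, :] - carbons[None, :, :], axis=2)
        return float(d.min(axis=1).mean())

    lo, hi = 0.0, 6.0
    if mean_contact(lo) > target_mean_contact:
        raise ValueError("target contact distance below the in-plane minimum")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_contact(mid) < target_mean_contact:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_ring(
    n_waters: int = 10,
    edge: float = 2.74,
    contact: float = 3.4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    chain_id: str = "A",
    residue_number: int = 43,
    plane_normal: str = "z",
) -> PlantedMotif:
    """Regular water polygon clamped around an aromatic (PHE-like) ring.

    Waters sit on a regular ``n_waters``-gon with the requested edge
    length, in a plane offset above a benzene-geometry carbon hexagon; the
    offset is solved so the mean water-to-nearest-carbon distance equals
    ``contact`` exactly (before noise).  ``plane_normal`` ('z' or 'y')
    orients the ring plane.
    """
    if n_waters < 4:
        raise ValueError("a ring needs at least 4 waters")
    R = edge / (2.0 * math.sin(math.pi / n_waters))
    carbon_radius = 1.39  # benzene C6 circumradius
    h = _ring_height_for_contact(n_waters, R, carbon_radius, contact)
    ctr = np.asarray(center, dtype=float)
    if plane_normal == "z":
        rot = np.eye(3)
    elif plane_normal == "y":
        # proper rotation -90 deg about x: (x, y, z) -> (x, z, -y)
        rot = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, -1.0, 0]])
    else:
        raise ValueError("plane_normal must be 'z' or 'y'")

    wang = np.arange(n_waters) * (2 * np.pi / n_waters)
    local = np.stack(
        [R * np.cos(wang), R * np.sin(wang), np.full(n_waters, h)], axis=1
    )
    coords = ctr + local @ rot.T
    rng = _rng(seed)
    coords = coords + rng.normal(0.0, noise_sigma, coords.shape)

    cang = np.arange(6) * (2 * np.pi / 6)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = [
        Atom(
            element="C",
            atom_name=nm,
            residue_name="PHE",
            residue_number=residue_number,
            chain_id=chain_id,
            xyz=tuple(
                ctr
                + rot
                @ np.array(
                    [carbon_radius * math.cos(a), carbon_radius * math.sin(a), 0.0]
                )
            ),
        )
        for nm, a in zip(names, cang)
    ]
    ws = WaterSet([f"rg{i}" for i in range(n_waters)], coords)
    return PlantedMotif(
        "ring",
        ws,
        truth={
            "edge": edge,
            "contact": contact,
            "height": h,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
        atoms=atoms,
    )


def gen_transformed_patch(
    patch: IcePlanePatch,
    subset_size: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    max_angle: float = math.pi,
) -> PlantedMotif:
    """Random connected-ish subset of an ice patch, rigidly moved and noised.

    Used for docking recovery tests: the planted rotation/translation and
    the pre-noise lattice positions are recorded in the truth dict.
    """
    if subset_size > len(patch):
        raise ValueError("subset_size exceeds the patch size")
    rng = _rng(seed)
    # take the subset nearest a random patch point, for spatial compactness
    anchor = patch.oxygens[rng.integers(len(patch))]
    order = np.argsort(np.linalg.norm(patch.oxygens - anchor, axis=1))
    idx = np.sort(order[:subset_size])
    base = patch.oxygens[idx]

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(-max_angle, max_angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * K @ K
    t = rng.uniform(-20, 20, size=3)
    coords = base @ R.T + t + rng.normal(0.0, noise_sigma, base.shape)
    ws = WaterSet([f"pw{i}" for i in range(subset_size)], coords)
    return PlantedMotif(
        "lattice_patch",
        ws,
        truth={
            "rotation": R,
            "translation": t,
            "subset_indices": idx,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# melting traces and hydrogen-bond occupancy
# ---------------------------------------------------------------------------

def gen_cd_trace(
    t_m: float = 47.5,
    width: float = 2.0,
    baselines: tuple[float, float] = (-11.0, -3.0),
    noise_sigma: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    t_low: float = 20.0,
    t_high: float = 60.0,
) -> tuple[MeltTrace, dict]:
    """Two-state logistic melting trace with a planted midpoint.

    ``noise_sigma`` is expressed as a fraction of the folded-to-unfolded
    amplitude.  Returns the trace and the ground-truth dict.
    """
    if grid is None:
        grid = np.arange(t_low, t_high + 0.1, 0.2)
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] < t_m < grid[-1]):
        raise ValueError("grid must span the planted midpoint")
    th_f, th_u = baselines
    f = 1.0 / (1.0 + np.exp(-(grid - t_m) / width))
    theta = th_f + (th_u - th_f) * f
    rng = _rng(seed)
    theta = theta + rng.normal(0.0, noise_sigma * abs(th_u - th_f), grid.shape)
    trace = MeltTrace(grid, theta, t_low=t_low, t_high=t_high)
    return trace, {"t_m": t_m, "width": width, "noise_sigma": noise_sigma, "seed": seed}


def gen_telegraph_hbonds(
    mean_lifetime: float = 80.0,
    dt: float = 1.0,
    n_frames: int = 2000,
    n_bonds: int = 20,
    positions: Sequence[int] = (1,),
    seed: int = 0,
    mean_off: float = 20.0,
    water_prefix: str = "w",
) -> HBondEventTable:
    """Two-state Markov (telegraph) hydrogen-bond occupancy series.

    Bonded run lengths are geometric with mean ``mean_lifetime / dt``
    frames, so the planted forward lifetime is ``mean_lifetime`` ps;
    unbonded gaps are geometric with mean ``mean_off / dt``.  Bonds are
    assigned round-robin to the given residue positions.
    """
    if mean_lifetime < dt:
        raise ValueError("mean_lifetime must be at least one frame interval")
    rng = _rng(seed)
    m_on = mean_lifetime / dt
    m_off = max(mean_off / dt, 1.0)
    series = {}
    for b in range(n_bonds):
        n_cycles = int(2 * n_frames / (m_on + m_off)) + 8
        off = rng.geometric(1.0 / m_off, n_cycles)
        on = rng.geometric(1.0 / m_on, n_cycles)
        lengths = np.empty(2 * n_cycles, dtype=int)
        lengths[0::2] = off
        lengths[1::2] = on
        states = np.zeros(2 * n_cycles, dtype=bool)
        states[1::2] = True
        occ = np.repeat(states, lengths)[:n_frames]
        if len(occ) < n_frames:  # extremely long draws; pad unbonded
            occ = np.concatenate([occ, np.zeros(n_frames - len(occ), dtype=bool)])
        respos = positions[b % len(positions)]
        series[(respos, f"{water_prefix}{b}")] = occ
    return HBondEventTable(dt=dt, series=series)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.4, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.4, 0.0]),
    "O": np.array([1.6, 1.5, 0.0]),
    "CB": np.array([0.0, -1.5, 0.0]),
}


def _residue_atoms(
    residue_number: int,
    ca_pos: np.ndarray,
    residue_name: str = "ALA",
    chain_id: str = "A",
    cb_pos: np.ndarray | None = None,
) -> list[Atom]:
    atoms = []
    for name, off in _BACKBONE_OFFSETS.items():
        pos = ca_pos + off
        if name == "CB" and cb_pos is not None:
            pos = cb_pos
        atoms.append(
            Atom(
                element=name[0],
                atom_name=name,
                residue_name=residue_name,
                residue_number=residue_number,
                chain_id=chain_id,
                xyz=tuple(float(v) for v in pos),
            )
        )
    return atoms


def _water_atom(i: int, xyz: np.ndarray, chain_id: str = "S") -> Atom:
    return Atom(
        element="O",
        atom_name="O",
        residue_name="HOH",
        residue_number=i,
        chain_id=chain_id,
        xyz=tuple(float(v) for v in xyz),
        het=True,
    )


def gen_toy_structure(
    n_residues: int = 10,
    planted_waters: Sequence[PlantedMotif] = (),
    cell: tuple = (40.0, 45.0, 50.0, 90.0, 90.0, 90.0),
    space_group: str = "P 21 21 21",
    path: str | Path | None = None,
    seed: int = 0,
    extra_waters: Sequence[np.ndarray] = (),
) -> Structure:
    """Small writable structure: poly-ALA scaffold plus planted waters.

    Residues are laid out along a line well inside the cell; motif waters
    (and any anchor atoms the motifs carry) are added verbatim.  When
    ``path`` is given the structure is also written as PDB with CRYST1.
    """
    atoms: list[Atom] = []
    for r in range(1, n_residues + 1):
        ca = np.array([5.0 + 3.0 * r, 5.0, 5.0])
        atoms.extend(_residue_atoms(r, ca))
    wi = 1
    for motif in planted_waters:
        atoms.extend(motif.atoms)
        for xyz in motif.waters.coords:
            atoms.append(_water_atom(wi, xyz))
            wi += 1
    for xyz in extra_waters:
        atoms.append(_water_atom(wi, np.asarray(xyz)))
        wi += 1
    st = Structure(
        atoms=atoms,
        cell=cell,
        space_group=space_group,
        sym_ops=space_group_ops(space_group),
        identifier="TOY",
    )
    if path is not None:
        write_structure(st, path)
    return st


# ---------------------------------------------------------------------------
# full synthetic stand-in crystal structure
# ---------------------------------------------------------------------------

#: Trough anchor residues (inward-facing hydrophobics of the IBS beta-sheet).
TROUGH_ANCHORS: tuple[tuple[int, str], ...] = (
    (22, "VAL"),
    (213, "VAL"),
    (195, "VAL"),
    (177, "VAL"),
    (150, "LEU"),
    (126, "VAL"),
)

REFERENCE_CELL = (57.12, 62.99, 101.21, 90.0, 90.0, 90.0)


def gen_reference_structure(
    seed: int = 0,
    n_waters_total: int = 746,
    n_residues: int = 223,
    motif_noise: float = 0.02,
    cell: tuple = REFERENCE_CELL,
    path: str | Path | None = None,
) -> tuple[Structure, dict]:
    """Synthetic stand-in for an antifreeze-protein crystal structure.

    Builds a single-chain (A) scaffold of ``n_residues`` residues in an
    orthorhombic P2(1)2(1)2(1) cell and plants on its ice-binding site:

    * a 12-water zigzag chain (spacing 2.86 A, angle 116 deg) anchored to
      the loop-region residues,
    * a 6-water linear trough (interval 4.6 A) between the CB atoms of the
      six hydrophobic anchor residues,
    * a 10-water hydration ring around a PHE side chain at position 43
      (edge 2.74 A, mean nearest-carbon contact 3.4 A),
    * enough additional IBS-proximal waters to total 54 on the IBS,
    * bulk waters to reach ``n_waters_total`` structure-wide.

    Motif coordinates carry isotropic Gaussian noise of ``motif_noise`` A
    (crystallographic coordinate precision).  Returns the structure and a
    ground-truth dict.  This is a synthetic object: the scaffold is not a
    real protein fold, but every planted quantity is recoverable by the
    corresponding analysis stage.
    """
    # Layout note.  The P2(1)2(1)2(1) operator (1/2+x, 1/2-y, -z) maps the
    # z ~ 50 A slab of this cell onto itself, so symmetry images of waters
    # placed there can fall back near the ice-binding site.  All IBS waters
    # are therefore confined to y in [4, 13]: the operator reflects y about
    # b/4 ~ 15.75, sending their images into y in [18.5, 27.5], at least
    # 4.5 A from every IBS atom (all of which keep y <= 14).  Bulk waters
    # live in z in [64.5, 89], whose images under every non-identity
    # operator stay > 4 A away from IBS atoms in z.  The generator verifies
    # both properties by brute force before returning.
    rng = _rng(seed)
    chain = "A"
    truth: dict = {"seed": seed, "motif_noise": motif_noise}

    zig = gen_zigzag(
        12, 2.86, 116.0, motif_noise, seed=seed + 101, origin=(7.5, 4.5, 50.0)
    )
    trough = gen_trough(
        6, 4.6, motif_noise, seed=seed + 102, origin=(8.0, 10.3, 50.0)
    )
    ring = gen_ring(
        10, 2.74, 3.4, motif_noise, seed=seed + 103,
        center=(42.5, 8.5, 50.0), chain_id=chain, residue_number=43,
        plane_normal="y",
    )
    truth.update(
        zigzag=zig.truth, trough=trough.truth, ring=ring.truth,
        n_ibs_waters=54, n_waters_total=n_waters_total,
    )

    atoms: list[Atom] = []
    special: dict[int, list[Atom]] = {}

    # loop-region residues under the zigzag waters (CB 3.5 A below in z);
    # position 22 is reserved for the trough, 43 for the aromatic ring
    loop_positions = [19, 20, 21, 23, 24, 25, 38, 39, 40, 41, 42, 44]
    for p, wxyz in zip(loop_positions, zig.waters.coords):
        cb = wxyz + np.array([0.0, 0.0, -3.5])
        ca = cb + np.array([0.0, 0.0, -1.5])
        special[p] = _residue_atoms(p, ca, "ALA", chain, cb_pos=cb)

    # trough anchors: CB 3.0 A below each trough water in z
    for (p, resname), wxyz in zip(TROUGH_ANCHORS, trough.waters.coords):
        cb = wxyz + np.array([0.0, 0.0, -3.0])
        ca = cb + np.array([0.0, 0.0, -1.5])
        special[p] = _residue_atoms(p, ca, resname, chain, cb_pos=cb)

    # PHE 43: aromatic carbons from the ring motif + backbone below in z
    ca43 = np.array([42.5, 8.5, 47.0])
    special[43] = [
        a for a in _residue_atoms(43, ca43, "PHE", chain) if a.atom_name != "CB"
    ]
    special[43].extend(ring.atoms)

    # remaining IBS waters (54 - 12 - 6 - 10 = 26) in three rows above the
    # motif plane, paired with CB atoms of sheet residues 192-198 / 210-216;
    # 3.8 A spacing keeps them out of the 3.7 A proximity network
    extra_rows = [
        (5.5, 56.0, [6.0 + 3.8 * k for k in range(9)]),
        (11.5, 56.0, [6.0 + 3.8 * k for k in range(9)]),
        (8.5, 59.8, [8.0 + 3.8 * k for k in range(8)]),
    ]
    extra_ibs: list[np.ndarray] = []
    cb_sites: list[np.ndarray] = []
    for y, z, xs in extra_rows:
        row = [np.array([x, y, z]) for x in xs]
        extra_ibs.extend(row)
        # one CB per water pair (plus one for a trailing odd water)
        for k in range(0, len(row) - 1, 2):
            mid = 0.5 * (row[k] + row[k + 1])
            cb_sites.append(mid + np.array([0.0, 0.0, -2.3]))
        if len(row) % 2:
            cb_sites.append(row[-1] + np.array([0.0, 0.0, -2.3]))
    # sheet positions free of planted roles (195/213 belong to the trough)
    sheet_positions = [192, 193, 194, 196, 197, 198, 210, 211, 212, 214, 215, 216, 123, 127]
    for p, cb in zip(sheet_positions, cb_sites):
        ca = cb + np.array([0.0, 0.0, -1.5])
        special[p] = _residue_atoms(p, ca, "ALA", chain, cb_pos=cb)

    # scaffold for all other residues, on a plane below the hydration layer.
    # IBS-range residues without a planted role go to a dedicated strip
    # (y ~ 52, z = 44) that no symmetry image band of any water reaches, so
    # they can never attract image waters into the IBS selection.
    ibs_range_positions = {p for lo_, hi_ in IBS_RANGES for p in range(lo_, hi_ + 1)}
    spare_ibs = [
        p for p in sorted(ibs_range_positions) if p not in special
    ]
    for p in range(1, n_residues + 1):
        if p in special:
            atoms.extend(special[p])
            continue
        if p in ibs_range_positions:
            k = spare_ibs.index(p)
            ca = np.array([4.0 + 2.6 * k, 52.0, 44.0])
        else:
            row_i, col = divmod(p, 16)
            ca = np.array([4.0 + 3.2 * col, 6.0 + 3.5 * row_i, 44.0])
        atoms.extend(_residue_atoms(p, ca, "ALA", chain))

    # planted waters
    wi = 1
    water_atoms: list[Atom] = []
    for motif in (zig, trough, ring):
        for xyz in motif.waters.coords:
            water_atoms.append(_water_atom(wi, xyz))
            wi += 1
    for xyz in extra_ibs:
        water_atoms.append(_water_atom(wi, xyz))
        wi += 1
    n_ibs = len(water_atoms)

    # bulk waters: seeded-random, in a slab far above the IBS, >= 2.4 A apart
    placed = [w.coords for w in water_atoms]
    n_bulk = n_waters_total - n_ibs
    if n_bulk < 0:
        raise ValueError("n_waters_total smaller than the planted IBS waters")
    lo = np.array([6.0, 5.0, 64.5])
    hi = np.array([cell[0] - 6.0, cell[1] - 5.0, 89.0])
    attempts = 0
    while n_bulk > 0:
        attempts += 1
        if attempts > 500000:
            raise RuntimeError("bulk water placement did not converge")
        pos = rng.uniform(lo, hi)
        arr = np.array(placed[-600:])
        if np.min(np.linalg.norm(arr - pos, axis=1)) < 2.4:
            continue
        water_atoms.append(_water_atom(wi, pos))
        placed.append(pos)
        wi += 1
        n_bulk -= 1

    st = Structure(
        atoms=atoms + water_atoms,
        cell=cell,
        space_group="P 21 21 21",
        sym_ops=space_group_ops("P 21 21 21"),
        identifier="SYNTHETIC-AFP",
    )
    _verify_image_clearance(st, clearance=4.2)
    if path is not None:
        write_structure(st, path)
    return st, truth


def _verify_image_clearance(st: Structure, clearance: float) -> None:
    """Assert no symmetry image of any water approaches any IBS-range atom."""
    from itertools import product as _product

    from scipy.spatial import cKDTree as _KDTree

    cell = st.gemmi_cell
    orth = np.array(cell.orth.mat.tolist())
    frac_m = np.array(cell.frac.mat.tolist())
    ibs_positions = {p for lo, hi in IBS_RANGES for p in range(lo, hi + 1)}
    ibs_atom_xyz = np.array(
        [
            a.xyz
            for a in st.atoms
            if not a.is_water and a.residue_number in ibs_positions
        ]
    )
    wxyz = np.array([a.xyz for a in st.atoms if a.is_water])
    frac = wxyz @ frac_m.T
    tree = _KDTree(ibs_atom_xyz)
    for op in st.sym_ops:
        base = op.apply(frac)
        for shift in _product((-1, 0, 1), repeat=3):
            if op.is_identity and shift == (0, 0, 0):
                continue
            img = (base + np.asarray(shift, dtype=float)) @ orth.T
            d, _ = tree.query(img)
            if d.min() < clearance:
                raise AssertionError(
                    "symmetry image of a planted water falls within "
                    f"{clearance} A of the IBS ({d.min():.2f} A); layout bug"
                )
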