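"""Ideal hexagonal-ice (ice Ih) oxygen lattices and plane patches.

The oxygen sublattice of ice Ih is a wurtzite-type hexagonal lattice: four
oxygens per hexagonal cell, each tetrahedrally coordinated, with nearest
O-O distance ``sqrt(a^2/3 + c^2/64)`` (= 3c/8 along the c axis) for the
ideal internal parameter.  With the default constants a = 4.52 A and
c = 7.36 A (ice Ih near 0 deg C) the O-O bond length is about 2.76 A.

Plane patches are the oxygen sets within a slab around a crystallographic
plane: the basal plane {0001} (one puckered bilayer of chair-form hexagonal
rings), the primary prism plane {10-10}, and the secondary prism plane
{11-20}.  Bound-water motifs on antifreeze-protein ice-binding sites are
compared against these patches: their characteristic repeat spacings are
the quantities the measured water intervals are matched to.

Hydrogens (and proton disorder) are deliberately absent: every statistic in
this package is defined on oxygen positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "IceLattice",
    "IcePlanePatch",
    "build_ice_lattice",
    "extract_plane_patch",
    "characteristic_spacings",
    "DEFAULT_A_ICE",
    "DEFAULT_C_ICE",
]

DEFAULT_A_ICE = 4.52  # A, hexagonal lattice constant of ice Ih near 0 C
DEFAULT_C_ICE = 7.36  # A

# Fractional coordinates of the 4-oxygen wurtzite basis (ideal u = 3/8):
# two hcp sites, each decorated by a second oxygen displaced 3/8 c along c.
_BASIS = np.array(
    [
        [1 / 3, 2 / 3, 0.0],
        [2 / 3, 1 / 3, 0.5],
        [1 / 3, 2 / 3, 3 / 8],
        [2 / 3, 1 / 3, 7 / 8],
    ]
)

_PLANES = ("basal", "prism1", "prism2")


@dataclass(frozen=True)
class IceLattice:
    """A block of the ideal ice Ih oxygen sublattice."""

    a_ice: float
    c_ice: float
    extent: int
    oxygens: np.ndarray  # (n, 3) Cartesian A
    lattice_vectors: np.ndarray  # (3, 3), rows a1, a2, a3

    @property
    def bond_length(self) -> float:
        """Nearest O-O distance for these constants.

        The vertical (along-c) bond is 3c/8; the three oblique bonds are
        sqrt(a^2/3 + c^2/64).  For the ideal axial ratio c/a = sqrt(8/3)
        the two coincide; for real ice Ih constants they differ by a few
        thousandths of an angstrom and the nearest distance is their
        minimum.
        """
        return float(
            min(3 * self.c_ice / 8, np.sqrt(self.a_ice**2 / 3 + self.c_ice**2 / 64))
        )

    def interior_mask(self, margin: float = 3.0) -> np.ndarray:
        """Oxygens at least ``margin`` A away from the block's bounding box."""
        lo = self.oxygens.min(axis=0) + margin
        hi = self.oxygens.max(axis=0) - margin
        return np.all((self.oxygens >= lo) & (self.oxygens <= hi), axis=1)


@dataclass(frozen=True)
class IcePlanePatch:
    """Oxygens within a slab around a crystallographic ice plane."""

    plane_id: str
    thickness: float
    oxygens: np.ndarray  # (n, 3) Cartesian A
    basis: np.ndarray  # (2, 3) in-plane primitive lattice vectors
    normal: np.ndarray  # unit normal

    def __len__(self) -> int:
        return len(self.oxygens)


def _lattice_vectors(a: float, c: float) -> np.ndarray:
    return np.array(
        [
            [a, 0.0, 0.0],
            [-a / 2, a * np.sqrt(3) / 2, 0.0],
            [0.0, 0.0, c],
        ]
    )


def build_ice_lattice(
    a_ice: float = DEFAULT_A_ICE,
    c_ice: float = DEFAULT_C_ICE,
    extent: int = 3,
) -> IceLattice:
    """Tile the 4-oxygen ice Ih basis over ``extent`` cells along each axis.

    Ordering is deterministic: cells in lexicographic (i, j, k) order, the
    four basis oxygens in fixed order within each cell.
    """
    if a_ice <= 0 or c_ice <= 0:
        raise ValueError("lattice constants must be positive")
    if extent < 1:
        raise ValueError("extent must be >= 1")
    vecs = _lattice_vectors(a_ice, c_ice)
    pts = []
    for i, j, k in product(range(extent), repeat=3):
        origin = np.array([i, j, k], dtype=float)
        frac = _BASIS + origin
        pts.append(frac @ vecs)
    oxygens = np.vstack(pts)
    return IceLattice(a_ice, c_ice, extent, oxygens, vecs)


def _plane_geometry(lat: IceLattice, plane_id: str):
    """Unit normal, in-plane primitive vectors, and an anchor point."""
    a1, a2, a3 = lat.lattice_vectors
    if plane_id == "basal":
        # {0001}: bilayer centered between the z = 3/8 c and z = 1/2 c sheets
        normal = np.array([0.0, 0.0, 1.0])
        basis = np.stack([a1, a2])
        anchor = np.array([0.0, 0.0, (3 / 8 + 1 / 2) / 2 * lat.c_ice])
    elif plane_id == "prism1":
        # {10-10}: contains a2 and c
        normal = np.cross(a2, a3)
        basis = np.stack([a2, a3])
        anchor = (_BASIS[0] @ lat.lattice_vectors)
    elif plane_id == "prism2":
        # {11-20}: contains a1 - a2 and c
        normal = np.cross(a1 - a2, a3)
        basis = np.stack([a1 - a2, a3])
        anchor = (_BASIS[0] @ lat.lattice_vectors)
    else:
        raise ValueError(f"plane_id must be one of {_PLANES}, got {plane_id!r}")
    normal = normal / np.linalg.norm(normal)
    return normal, basis, anchor


def extract_plane_patch(
    lattice: IceLattice,
    plane_id: str,
    thickness: float = 1.0,
    min_count: int = 1,
) -> IcePlanePatch:
    """Oxygens within ``thickness`` of the named plane through the lattice.

    The plane passes through an origin-adjacent oxygen (prism planes) or
    through the center of the first puckered bilayer (basal).  The slab is
    two-sided: a point belongs to the patch when its unsigned distance to
    the plane is ≤ ``thickness``.
    """
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    normal, basis, anchor = _plane_geometry(lattice, plane_id)
    d = np.abs((lattice.oxygens - anchor) @ normal)
    mask = d <= thickness + 1e-9
    oxygens = lattice.oxygens[mask]
    if len(oxygens) < min_count:
        raise ValueError(
            f"plane patch has {len(oxygens)} oxygens < min_count={min_count}; "
            "rebuild the lattice with a larger extent"
        )
    return IcePlanePatch(plane_id, thickness, oxygens, basis, normal)


def characteristic_spacings(
    patch: IcePlanePatch,
    max_length: float = 16.0,
    max_multiple: int = 2,
    decimals: int = 2,
) -> list[float]:
    """Distinct in-plane lattice repeat distances of a plane patch.

    Returns the sorted distinct norms (rounded to ``decimals``) of the
    integer combinations ``m*u + n*v`` of the patch's in-plane primitive
    vectors with ``|m|, |n| <= max_multiple``, up to ``max_length``.  These
    are the repeat intervals that rows of ice waters exhibit within the
    plane; measured intervals of protein-bound waters are compared against
    them (e.g. the primary prism plane of the default lattice repeats at
    about 4.5 A along a and 14.7 A over two cells along c).
    """
    if len(patch) < 3:
        raise ValueError("patch must contain at least 3 oxygens")
    u, v = patch.basis
    out = set()
    for m in range(-max_multiple, max_multiple + 1):
        for n in range(-max_multiple, max_multiple + 1):
            if m == 0 and n == 0:
                continue
            L = float(np.linalg.norm(m * u + n * v))
            if 0 < L <= max_length:
                out.add(round(L, decimals))
    return sorted(out)


def min_oo_distance(lattice: IceLattice, margin: float = 3.0) -> float:
    """Brute-force interior nearest-neighbour O-O distance."""
    mask = lattice.interior_mask(margin)
    if mask.sum() < 2:
        raise ValueError("lattice too small for an interior region")
    tree = cKDTree(lattice.oxygens)
    d, _ = tree.query(lattice.oxygens[mask], k=2)
    return float(d[:, 1].min())


def patch_as_waterset(patch: IcePlanePatch):
    """Expose a patch as a WaterSet (ids ``ice0, ice1, ...``)."""
    from .structio import WaterSet

    return WaterSet([f"ice{i}" for i in range(len(patch))], patch.oxygens.copy())
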