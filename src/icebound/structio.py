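"""Crystal-structure I/O, symmetry expansion and water selection.

Reading and writing of PDB/mmCIF coordinate files is delegated to gemmi;
this module converts to a small in-memory representation tailored to
bound-water analysis: a flat atom list, the unit cell, and the space-group
operators.  Crystallographic symmetry expansion surrounds a region of
interest (typically the ice-binding site) with the water images that a
neighbouring molecule in the lattice contributes, which is required before
any water-network statistic is computed — the deposited asymmetric unit
alone truncates the hydration shell at lattice contacts.

Waters are represented by their oxygen atom only: deposited crystal
structures do not resolve water hydrogens, and every geometric statistic in
this package is defined on oxygen positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O"})

__all__ = [
    "Atom",
    "SymOp",
    "Structure",
    "WaterSet",
    "RegionDefinition",
    "IBS_REGIONS",
    "read_structure",
    "write_structure",
    "expand_symmetry",
    "select_waters_near",
    "water_count",
]

# Ice-binding-site residue positions for the TisAFP isoform family
# (loop and beta-sheet sub-sites of the compound IBS), 1-based inclusive.
IBS_RANGES: tuple[tuple[int, int], ...] = (
    (19, 25),
    (38, 45),
    (123, 129),
    (147, 153),
    (174, 180),
    (192, 198),
    (210, 216),
)


@dataclass(frozen=True)
class Atom:
    """A single atom record in Cartesian angstrom coordinates."""

    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    xyz: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False
    sym_tag: str = ""  # non-empty for symmetry-generated copies

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    def key(self) -> tuple:
        return (
            self.chain_id,
            self.residue_number,
            self.atom_name,
            self.altloc,
            self.sym_tag,
        )


@dataclass(frozen=True)
class SymOp:
    """Space-group operator: integer rotation part + fractional translation."""

    rot: tuple[tuple[int, int, int], ...]
    tran: tuple[float, float, float]

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (n, 3)."""
        r = np.asarray(self.rot, dtype=float)
        t = np.asarray(self.tran, dtype=float)
        return frac @ r.T + t

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            abs(x) < 1e-9 for x in self.tran
        )


@dataclass
class Structure:
    """A coordinate set with unit cell and space-group metadata."""

    atoms: list[Atom]
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str = "P 1"
    sym_ops: list[SymOp] = field(default_factory=list)
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if not (a > 0 and b > 0 and c > 0):
                raise ValueError("unit cell lengths must be positive")
            if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
                raise ValueError("unit cell angles must lie in (0, 180) degrees")
        for at in self.atoms:
            if not all(math.isfinite(v) for v in at.xyz):
                raise ValueError(
                    f"non-finite coordinate for atom {at.chain_id}/"
                    f"{at.residue_number}/{at.atom_name}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for at in self.atoms:
            seen.setdefault(at.chain_id, None)
        return list(seen)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        if self.cell is None:
            raise ValueError("structure has no unit cell")
        return gemmi.UnitCell(*self.cell)

    def waters(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_water]

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        sel = self.atoms if atoms is None else atoms
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in sel], dtype=float)

    def select(
        self,
        chain: str | None = None,
        residue_numbers: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> list[Atom]:
        resnums = set(residue_numbers) if residue_numbers is not None else None
        names = set(atom_names) if atom_names is not None else None
        out = []
        for at in self.atoms:
            if chain is not None and at.chain_id != chain:
                continue
            if resnums is not None and at.residue_number not in resnums:
                continue
            if names is not None and at.atom_name not in names:
                continue
            out.append(at)
        return out


@dataclass
class WaterSet:
    """An ordered set of water oxygens with stable string identifiers."""

    ids: list[str]
    coords: np.ndarray  # (n, 3) Cartesian angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("water ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            bad = [
                wid
                for wid, xyz in zip(self.ids, self.coords)
                if not np.all(np.isfinite(xyz))
            ]
            raise ValueError(f"non-finite coordinates for waters {bad}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "WaterSet":
        return WaterSet([self.ids[i] for i in indices], self.coords[list(indices)])

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom]) -> "WaterSet":
        ids = []
        for at in atoms:
            tag = f"~{at.sym_tag}" if at.sym_tag else ""
            ids.append(f"{at.chain_id}/{at.residue_number}{tag}")
        return cls(ids, np.array([a.xyz for a in atoms]) if atoms else np.zeros((0, 3)))


@dataclass(frozen=True)
class RegionDefinition:
    """Named, inclusive, 1-based residue-position ranges on the sequence."""

    regions: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        for name, ranges in self.regions.items():
            spans = sorted(ranges)
            for lo, hi in spans:
                if lo < 1 or hi < lo:
                    raise ValueError(f"bad range ({lo},{hi}) in region {name!r}")
            for (_, hi1), (lo2, _) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"overlapping ranges in region {name!r}")

    def positions(self, name: str) -> set[int]:
        return {
            p for lo, hi in self.regions[name] for p in range(lo, hi + 1)
        }

    def classify(self, position: int) -> str | None:
        for name, ranges in self.regions.items():
            if any(lo <= position <= hi for lo, hi in ranges):
                return name
        return None


#: The ice-binding-site region of the TisAFP isoforms.
IBS_REGIONS = RegionDefinition({"IBS": IBS_RANGES})


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _op_from_gemmi(op: gemmi.Op) -> SymOp:
    den = op.DEN
    rot = tuple(tuple(int(v // den) for v in row) for row in op.rot)
    tran = tuple(v / den for v in op.tran)
    return SymOp(rot, tran)


def space_group_ops(name: str) -> list[SymOp]:
    """Operators for a space group by Hermann-Mauguin name (gemmi tables)."""
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        raise ValueError(
            f"unknown space group {name!r}; supported names follow the "
            "International Tables as listed by gemmi"
        )
    return [_op_from_gemmi(op) for op in sg.operations()]


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """One conformer per atom site: highest occupancy, ties favour ''/'A'."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []

    def rank(x: Atom) -> tuple:
        return (round(x.occupancy, 6), x.altloc == "", x.altloc == "A")

    for at in atoms:
        k = (at.chain_id, at.residue_number, at.residue_name, at.atom_name)
        cur = best.get(k)
        if cur is None:
            best[k] = at
            order.append(k)
        elif rank(at) > rank(cur):
            best[k] = at
    return [replace(best[k], altloc="") for k in order]


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path : file path
    fmt : {'auto', 'pdb', 'mmcif'}
        Dialect; 'auto' detects from the extension/contents (gemmi).

    Only the first model is read.  Alternate conformers are collapsed to a
    single site (blank/'A' altloc preferred, then highest occupancy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        element=at.element.name,
                        atom_name=at.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        altloc=at.altloc if at.altloc else "",
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        het=res.het_flag == "H",
                    )
                )
    atoms = _dedupe_altlocs(atoms)

    cell = None
    if st.cell and st.cell.a > 0:
        cell = (
            st.cell.a,
            st.cell.b,
            st.cell.c,
            st.cell.alpha,
            st.cell.beta,
            st.cell.gamma,
        )
    sg_name = st.spacegroup_hm or "P 1"
    try:
        ops = space_group_ops(sg_name)
    except ValueError:
        ops = []
    return Structure(
        atoms=atoms,
        cell=cell,
        space_group=sg_name,
        sym_ops=ops,
        identifier=st.name or path.stem,
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a fixed-column PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.identifier or "XXXX"
    if structure.cell is not None:
        st.cell = gemmi.UnitCell(*structure.cell)
    st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for at in structure.atoms:
        ch = chain_map.get(at.chain_id)
        if ch is None:
            ch = gemmi.Chain(at.chain_id)
            chain_map[at.chain_id] = ch
        if len(ch) and ch[-1].seqid.num == at.residue_number and ch[-1].name == at.residue_name:
            res = ch[-1]
        else:
            res = gemmi.Residue()
            res.name = at.residue_name
            res.seqid = gemmi.SeqId(at.residue_number, " ")
            res.het_flag = "H" if at.het else "A"
            ch.add_residue(res)
            res = ch[-1]
        ga = gemmi.Atom()
        ga.name = at.atom_name
        ga.element = gemmi.Element(at.element)
        ga.pos = gemmi.Position(*at.xyz)
        ga.occ = at.occupancy
        ga.b_iso = at.b_factor
        res.add_atom(ga)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def water_count(structure: Structure) -> int:
    """Number of water molecules (oxygen sites) in the structure."""
    return sum(1 for a in structure.atoms if a.is_water and a.atom_name in ("O", "OW"))


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def _center_coords(center) -> np.ndarray:
    if isinstance(center, WaterSet):
        return center.coords
    if isinstance(center, np.ndarray):
        return np.asarray(center, dtype=float).reshape(-1, 3)
    # sequence of Atom
    return np.array([a.xyz for a in center], dtype=float).reshape(-1, 3)


def expand_symmetry(
    structure: Structure,
    center,
    radius: float,
    *,
    duplicate_tol: float = 0.1,
    shells: int = 1,
) -> Structure:
    """Add symmetry images of waters that fall near a region of interest.

    Every water oxygen is mapped through each space-group operator combined
    with integer lattice translations over ``±shells`` unit cells; images
    within ``radius`` of any atom of ``center`` (a :class:`WaterSet`, an
    (n, 3) array, or a sequence of atoms) are appended with a symmetry tag
    of the form ``"op{i}+{u}{v}{w}"``.  Images within ``duplicate_tol`` of
    an existing atom are dropped.

    The original atoms are always retained unchanged.
    """
    if structure.cell is None:
        raise ValueError("symmetry expansion requires a unit cell")
    if not structure.sym_ops:
        raise ValueError(
            f"no operators available for space group "
            f"{structure.space_group!r}; supply sym_ops explicitly"
        )
    ctr = _center_coords(center)
    if len(ctr) == 0:
        return Structure(
            list(structure.atoms),
            structure.cell,
            structure.space_group,
            list(structure.sym_ops),
            structure.identifier,
        )

    cell = structure.gemmi_cell
    orth = np.array(cell.orth.mat.tolist())
    frac_m = np.array(cell.frac.mat.tolist())

    waters = [a for a in structure.atoms if a.is_water]
    wxyz = np.array([a.xyz for a in waters]).reshape(-1, 3)
    all_xyz = structure.coords()
    existing = cKDTree(all_xyz)
    ctr_tree = cKDTree(ctr)

    new_atoms: list[Atom] = []
    new_xyz: list[np.ndarray] = []
    if len(waters):
        frac = wxyz @ frac_m.T
        for i_op, op in enumerate(structure.sym_ops):
            op_frac = op.apply(frac)
            for shift in product(range(-shells, shells + 1), repeat=3):
                if op.is_identity and shift == (0, 0, 0):
                    continue
                img_frac = op_frac + np.asarray(shift, dtype=float)
                img = img_frac @ orth.T
                near = ctr_tree.query_ball_point(img, radius)
                tag = f"op{i_op}+{shift[0]},{shift[1]},{shift[2]}"
                for j, hits in enumerate(near):
                    if not hits:
                        continue
                    pos = img[j]
                    if existing.query(pos)[0] < duplicate_tol:
                        continue
                    if new_xyz and min(
                        float(np.linalg.norm(pos - p)) for p in new_xyz
                    ) < duplicate_tol:
                        continue
                    new_xyz.append(pos)
                    new_atoms.append(
                        replace(
                            waters[j],
                            xyz=tuple(float(v) for v in pos),
                            sym_tag=tag,
                        )
                    )
    return Structure(
        list(structure.atoms) + new_atoms,
        structure.cell,
        structure.space_group,
        list(structure.sym_ops),
        structure.identifier,
    )


# ---------------------------------------------------------------------------
# water selection
# ---------------------------------------------------------------------------

def select_waters_near(
    structure: Structure,
    residue_ranges: RegionDefinition | Sequence[tuple[int, int]] = IBS_REGIONS,
    cutoff: float = 4.0,
    *,
    chain: str | None = None,
    region_name: str | None = None,
) -> WaterSet:
    """Waters with any-atom distance ≤ ``cutoff`` to the named residues.

    ``residue_ranges`` may be a :class:`RegionDefinition` (the first — or
    ``region_name`` — entry is used) or a plain sequence of inclusive
    (start, end) ranges.  Order of the result is deterministic: chain,
    residue number, symmetry tag.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if isinstance(residue_ranges, RegionDefinition):
        name = region_name or next(iter(residue_ranges.regions))
        ranges = residue_ranges.regions[name]
    else:
        ranges = tuple(residue_ranges)
    if not ranges:
        raise ValueError("residue ranges must be non-empty")
    positions = {p for lo, hi in ranges for p in range(lo, hi + 1)}

    ref_atoms = [
        a
        for a in structure.atoms
        if not a.is_water
        and a.residue_number in positions
        and (chain is None or a.chain_id == chain)
    ]
    waters = [
        a
        for a in structure.atoms
        if a.is_water and a.atom_name in ("O", "OW")
    ]
    if not ref_atoms or not waters or cutoff == 0:
        return WaterSet([], np.zeros((0, 3)))

    tree = cKDTree(np.array([a.xyz for a in ref_atoms]))
    keep = []
    for at in waters:
        d, _ = tree.query(np.asarray(at.xyz))
        if d <= cutoff:
            keep.append(at)
    keep.sort(key=lambda a: (a.chain_id, a.residue_number, a.sym_tag))
    return WaterSet.from_atoms(keep)
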