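"""Structure I/O, symmetry expansion and water selection."""

from itertools import product

import numpy as np
import pytest

from icebound.structio import (
    Atom,
    IBS_REGIONS,
    RegionDefinition,
    Structure,
    WaterSet,
    expand_symmetry,
    read_structure,
    select_waters_near,
    space_group_ops,
    water_count,
    write_structure,
)
from icebound.synthetic_data import gen_toy_structure, gen_zigzag


def _water(i, xyz, chain="S"):
    return Atom("O", "O", "HOH", i, chain, tuple(float(v) for v in xyz), het=True)


def _probe(xyz, resnum=1, chain="A", name="CB"):
    return Atom(name[0], name, "ALA", resnum, chain, tuple(float(v) for v in xyz))


class TestReadWrite:
    def test_round_trip_preserves_atoms(self, tmp_path):
        st = gen_toy_structure(
            n_residues=5,
            planted_waters=[gen_zigzag(5, 2.86, 116.0, 0.05, seed=3, origin=(15, 20, 25))],
            path=tmp_path / "toy.pdb",
        )
        back = read_structure(tmp_path / "toy.pdb")
        assert len(back.atoms) == len(st.atoms)
        assert water_count(back) == 5
        orig = {a.key(): a.coords for a in st.atoms}
        for a in back.atoms:
            assert np.allclose(a.coords, orig[a.key()], atol=1e-3)
        assert back.cell == pytest.approx(st.cell)
        assert back.space_group.replace(" ", "") == "P212121"

    def test_mmcif_dialect(self, tmp_path):
        import gemmi

        st = gen_toy_structure(n_residues=3, path=tmp_path / "toy.pdb")
        g = gemmi.read_structure(str(tmp_path / "toy.pdb"))
        g.setup_entities()
        g.make_mmcif_document().write_file(str(tmp_path / "toy.cif"))
        back = read_structure(tmp_path / "toy.cif", fmt="mmcif")
        assert len(back.atoms) == len(st.atoms)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_garbage_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\n_loop nonsense {{{{\n")
        with pytest.raises(ValueError, match="cannot parse"):
            read_structure(bad, fmt="mmcif")

    def test_altloc_keeps_highest_occupancy_conformer(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "CRYST1   40.000   40.000   40.000  90.00  90.00  90.00 P 1\n"
            "ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.30 10.00           C\n"
            "ATOM      2  CA BALA A   1      12.000  10.000  10.000  0.70 10.00           C\n"
            "END\n"
        )
        st = read_structure(pdb)
        assert len(st.atoms) == 1
        assert st.atoms[0].coords[0] == pytest.approx(12.0)
        assert st.atoms[0].altloc == ""


class TestInvariants:
    def test_bad_cell_rejected(self):
        with pytest.raises(ValueError):
            Structure(atoms=[], cell=(0.0, 10, 10, 90, 90, 90))
        with pytest.raises(ValueError):
            Structure(atoms=[], cell=(10, 10, 10, 90, 190, 90))

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            Structure(atoms=[_water(1, (np.nan, 0, 0))])

    def test_waterset_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            WaterSet(["a", "a"], np.zeros((2, 3)))

    def test_region_definition_rejects_overlap(self):
        with pytest.raises(ValueError):
            RegionDefinition({"x": ((1, 5), (4, 8))})


class TestExpandSymmetry:
    def test_identity_space_group_adds_only_lattice_translates(self):
        # P1 has no non-trivial operators: with a radius smaller than the
        # distance to any neighbour-cell copy nothing is added
        st = Structure(
            atoms=[_water(1, (5, 5, 5)), _probe((6, 5, 5))],
            cell=(20, 20, 20, 90, 90, 90),
            space_group="P 1",
            sym_ops=space_group_ops("P 1"),
        )
        out = expand_symmetry(st, np.array([[6.0, 5, 5]]), radius=8.0)
        assert len(out.atoms) == len(st.atoms)

    @staticmethod
    def _brute_force_images(st, center, radius):
        """Oracle: every operator x every neighbour cell, direct distances."""
        cell = st.gemmi_cell
        orth = np.array(cell.orth.mat.tolist())
        frac_m = np.array(cell.frac.mat.tolist())
        images = []
        for at in st.atoms:
            if not at.is_water:
                continue
            f = frac_m @ at.coords
            for i_op, op in enumerate(st.sym_ops):
                rf = np.asarray(op.rot, float) @ f + np.asarray(op.tran)
                for shift in product((-1, 0, 1), repeat=3):
                    if op.is_identity and shift == (0, 0, 0):
                        continue
                    pos = orth @ (rf + np.asarray(shift, float))
                    if np.min(np.linalg.norm(center - pos, axis=1)) <= radius:
                        images.append(pos)
        return np.array(images).reshape(-1, 3)

    def test_single_image_case_matches_oracle(self):
        # choose the radius between the nearest and second-nearest image of
        # one water, so the oracle predicts exactly one tagged copy
        center = np.array([[18.5, 28.0, 25.0]])
        st = Structure(
            atoms=[_water(1, (3.0, 7.0, 10.0)), _probe((18.5, 28.0, 25.0))],
            cell=(20, 30, 40, 90, 90, 90),
            space_group="P 21 21 21",
            sym_ops=space_group_ops("P 21 21 21"),
        )
        all_images = self._brute_force_images(st, center, radius=1e9)
        d = np.sort(np.linalg.norm(all_images - center, axis=1))
        assert d[0] < d[1]
        radius = 0.5 * (d[0] + d[1])
        assert len(self._brute_force_images(st, center, radius)) == 1
        out = expand_symmetry(st, center, radius)
        assert sum(1 for a in out.atoms if a.sym_tag) == 1

    def test_expansion_matches_brute_force_oracle(self, rng):
        waters = [
            _water(i + 1, rng.uniform([1, 1, 1], [19, 29, 39])) for i in range(25)
        ]
        st = Structure(
            atoms=waters + [_probe((10.0, 15.0, 20.0))],
            cell=(20, 30, 40, 90, 90, 90),
            space_group="P 21 21 21",
            sym_ops=space_group_ops("P 21 21 21"),
        )
        center = np.array([[10.0, 15.0, 20.0]])
        oracle = self._brute_force_images(st, center, 8.0)
        out = expand_symmetry(st, center, 8.0)
        added = np.array([a.coords for a in out.atoms if a.sym_tag]).reshape(-1, 3)
        assert len(added) == len(oracle)
        # set equality up to ordering
        from scipy.spatial.distance import cdist

        if len(added):
            d = cdist(added, oracle)
            assert d.min(axis=1).max() < 1e-9

    def test_added_atoms_are_true_group_images(self, reference_structure):
        st, _ = reference_structure
        probe = select_waters_near(st, IBS_REGIONS, 4.0)
        out = expand_symmetry(st, probe, radius=8.0)
        cell = st.gemmi_cell
        frac_m = np.array(cell.frac.mat.tolist())
        wfrac = np.array([frac_m @ a.coords for a in st.atoms if a.is_water])
        for at in out.atoms:
            if not at.sym_tag:
                continue
            f = frac_m @ at.coords
            ok = False
            for op in st.sym_ops:
                # invert: find source whose op-image differs by integer shift
                diff = wfrac @ np.asarray(op.rot, float).T + np.asarray(op.tran) - f
                if np.any(np.all(np.abs(diff - np.round(diff)) < 1e-6, axis=1)):
                    ok = True
                    break
            assert ok, f"atom {at.key()} is not an operator image"

    def test_requires_cell(self):
        st = Structure(atoms=[_water(1, (1, 1, 1))])
        with pytest.raises(ValueError, match="unit cell"):
            expand_symmetry(st, np.array([[0.0, 0, 0]]), 5.0)


class TestSelectWaters:
    def _structure_with_waters(self, dists):
        atoms = [_probe((0.0, 0, 0), resnum=10)]
        atoms += [_water(i + 1, (d, 0, 0)) for i, d in enumerate(dists)]
        return Structure(atoms=atoms)

    def test_distance_threshold(self):
        st = self._structure_with_waters([2.5, 3.9, 6.0])
        ws = select_waters_near(st, [(10, 10)], cutoff=4.0)
        assert len(ws) == 2

    def test_zero_cutoff_empty(self):
        st = self._structure_with_waters([2.5])
        assert len(select_waters_near(st, [(10, 10)], cutoff=0.0)) == 0

    def test_monotone_in_cutoff(self):
        st = self._structure_with_waters([1.0, 2.0, 3.5, 4.2, 7.0])
        prev: set = set()
        for cutoff in (1.5, 2.5, 4.0, 8.0):
            ids = set(select_waters_near(st, [(10, 10)], cutoff).ids)
            assert prev <= ids
            prev = ids

    def test_reference_ibs_count(self, reference_structure):
        st, truth = reference_structure
        ws = select_waters_near(st, IBS_REGIONS, 4.0)
        assert len(ws) == truth["n_ibs_waters"] == 54
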