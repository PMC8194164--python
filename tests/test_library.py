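"""Library building, receptor/ligand preparation, serialization, splitting."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from targetfish.chem import MoleculeRecord
from targetfish.fixtures import FixtureSpec, generate_complex, generate_library, write_complex
from targetfish.library import (
    LibraryBuildError,
    build_library,
    load_library,
    prepare_ligand,
    prepare_receptor,
    save_library,
    split_library,
)
from targetfish.structures import format_pdb_atom, parse_receptor


def _write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\n")


def _peptide_with_waters_and_ion(tmp_path):
    """20-residue glycine chain + 3 waters + 1 sodium ion, no hydrogens."""
    complex_ = generate_complex([], n_buffer=10)  # 20 glycines, ligand far away
    lines = []
    serial = 1
    for res in complex_.receptor.residues:
        for atom in res.atoms:
            if atom.element == "H":
                continue  # strip fixture hydrogens to exercise H addition
            lines.append(format_pdb_atom(serial, atom.name, res.resname, res.chain,
                                         res.resseq, atom.coord, atom.element))
            serial += 1
    for i in range(3):
        lines.append(format_pdb_atom(serial, "O", "HOH", "A", 100 + i,
                                     np.array([50.0 + 5 * i, 20.0, 0.0]), "O", hetero=True))
        serial += 1
    lines.append(format_pdb_atom(serial, "NA", "NA", "A", 200,
                                 np.array([60.0, 25.0, 0.0]), "Na", hetero=True))
    path = tmp_path / "raw.pdb"
    _write_pdb(path, lines + ["END"])
    return path


class TestPrepareReceptor:
    def test_waters_and_ion_removed_hydrogens_added(self, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        raw = _peptide_with_waters_and_ion(tmp_path)
        # independent parser: count input atoms
        st_in = gemmi.read_structure(str(raw))
        n_in = sum(1 for model in st_in for chain in model
                   for res in chain for _ in res)
        cleaned, out = prepare_receptor(raw, tmp_path / "prep.pdb")
        st_out = gemmi.read_structure(str(out))
        out_residues = [res for model in st_out for chain in model for res in chain]
        assert all(res.name not in ("HOH", "WAT", "NA") for res in out_residues)
        n_out = sum(len(res) for res in out_residues)
        n_h = sum(1 for res in out_residues for atom in res if atom.element.name == "H")
        # output = input - (3 water O) - (1 Na) + added amide hydrogens
        assert n_out == n_in - 4 + n_h
        assert n_h == 19  # every residue except the chain start gets one amide H

    def test_idempotent_on_hydrogenated_input(self, tmp_path):
        raw = _peptide_with_waters_and_ion(tmp_path)
        _, first = prepare_receptor(raw, tmp_path / "p1.pdb")
        _, second = prepare_receptor(first, tmp_path / "p2.pdb")
        s1, s2 = parse_receptor(first), parse_receptor(second)
        assert s1.n_atoms == s2.n_atoms

    def test_empty_after_cleaning_raises(self, tmp_path):
        path = tmp_path / "only_water.pdb"
        _write_pdb(path, [format_pdb_atom(1, "O", "HOH", "A", 1,
                                          np.array([0.0, 0.0, 0.0]), "O", hetero=True), "END"])
        with pytest.raises(LibraryBuildError):
            prepare_receptor(path, tmp_path / "out.pdb")


class TestPrepareLigand:
    def _ethanol_3d(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        return MoleculeRecord.from_mol(mol, "ethanol")

    def test_pdbqt_retains_hydroxyl_hydrogen(self, tmp_path):
        out = prepare_ligand(self._ethanol_3d(), tmp_path / "eth.pdbqt")
        text = out.read_text()
        atom_types = [line[77:79].strip() for line in text.splitlines()
                      if line.startswith("ATOM")]
        assert "HD" in atom_types            # the hydroxyl hydrogen survives
        assert atom_types.count("HD") == 1   # nonpolar hydrogens merged away
        assert "OA" in atom_types

    def test_rigid_ring_declares_zero_torsions(self, tmp_path):
        mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        out = prepare_ligand(MoleculeRecord.from_mol(mol, "bz"), tmp_path / "bz.pdbqt")
        assert "TORSDOF 0" in out.read_text()

    def test_deterministic_output(self, tmp_path):
        rec = self._ethanol_3d()
        a = prepare_ligand(rec, tmp_path / "a.pdbqt")
        b = prepare_ligand(rec, tmp_path / "b.pdbqt")
        assert a.read_bytes() == b.read_bytes()

    def test_requires_coordinates(self, tmp_path):
        with pytest.raises(ValueError):
            prepare_ligand(MoleculeRecord.from_smiles("CCO", "flat"), tmp_path / "x.pdbqt")


class TestBuildLibrary:
    def test_count_and_class_conservation(self, toy_library):
        assert len(toy_library) == 8
        assert toy_library.classes == {"kinase", "hiv"}
        for entry in toy_library.entries:
            assert entry.cocrystal_ligand.mol.GetNumConformers() == 1
            assert np.isfinite(entry.activity)

    def test_missing_receptor_row_rejected_others_kept(self, tmp_path):
        manifest = generate_library(FixtureSpec(seed=3, n_classes=1, n_targets_per_class=2), tmp_path)
        table = pd.read_csv(manifest)
        table.loc[0, "receptor"] = "structures/does_not_exist.pdb"
        library, report = build_library(table, base_dir=tmp_path)
        assert len(library) == len(table) - 1
        assert len(report) == 1 and "not found" in report[0]["reason"]

    def test_duplicate_pdb_id_aborts(self, tmp_path):
        manifest = generate_library(FixtureSpec(seed=3, n_classes=1), tmp_path)
        table = pd.read_csv(manifest)
        table.loc[1, "pdb_id"] = table.loc[0, "pdb_id"]
        with pytest.raises(LibraryBuildError, match="duplicate"):
            build_library(table, base_dir=tmp_path)

    def test_missing_class_label_aborts(self, tmp_path):
        manifest = generate_library(FixtureSpec(seed=3, n_classes=1), tmp_path)
        table = pd.read_csv(manifest)
        table.loc[0, "class"] = ""
        with pytest.raises(LibraryBuildError, match="class"):
            build_library(table, base_dir=tmp_path)

    def test_double_build_serializes_identically(self, tmp_path):
        manifest = generate_library(FixtureSpec(seed=5, n_classes=1), tmp_path / "lib")
        lib1, _ = build_library(manifest)
        lib2, _ = build_library(manifest)
        save_library(lib1, tmp_path / "s1")
        save_library(lib2, tmp_path / "s2")
        for name in ("manifest.json", "fingerprints.bin"):
            assert (tmp_path / "s1" / name).read_bytes() == (tmp_path / "s2" / name).read_bytes()


def test_serialization_roundtrip(toy_library, tmp_path):
    save_library(toy_library, tmp_path / "ser1")
    loaded = load_library(tmp_path / "ser1")
    save_library(loaded, tmp_path / "ser2")
    for name in ("manifest.json", "fingerprints.bin"):
        assert (tmp_path / "ser1" / name).read_bytes() == (tmp_path / "ser2" / name).read_bytes()
    entry0 = toy_library.entries[0]
    back0 = loaded.by_id(entry0.pdb_id)
    assert back0.target_name == entry0.target_name
    assert np.array_equal(back0.reference_ifp.bits, entry0.reference_ifp.bits)


class TestSplitLibrary:
    def _library_one_class(self, tmp_path, n=10):
        """10 entries, one class, one target name."""
        manifest = generate_library(
            FixtureSpec(seed=9, n_classes=1, n_targets_per_class=1, n_ligands_per_target=5),
            tmp_path,
        )
        table = pd.read_csv(manifest)
        # replicate rows with fresh ids to reach n entries of one target
        rows = [table.iloc[i % len(table)].copy() for i in range(n)]
        for i, row in enumerate(rows):
            row["pdb_id"] = f"X{i:03d}"
        library, _ = build_library(pd.DataFrame(rows), base_dir=tmp_path)
        return library

    def test_exact_fraction(self, tmp_path):
        library = self._library_one_class(tmp_path, n=10)
        split = split_library(library, fraction=0.8, seed=0)
        assert len(split.training) == 8 and len(split.validation) == 2

    def test_validation_targets_present_in_training(self, toy_library):
        split = split_library(toy_library, fraction=0.5, seed=1)
        train_names = {toy_library.by_id(i).target_name for i in split.training}
        for pdb_id in split.validation:
            assert toy_library.by_id(pdb_id).target_name in train_names

    def test_singleton_target_forced_into_training(self, toy_library):
        # every target_name has 2 entries; at fraction 0.5 one of each must train
        split = split_library(toy_library, fraction=0.5, seed=2)
        assert set(split.training) | set(split.validation) == {e.pdb_id for e in toy_library.entries}
        assert not set(split.training) & set(split.validation)

    def test_deterministic(self, toy_library):
        s1 = split_library(toy_library, fraction=0.75, seed=3)
        s2 = split_library(toy_library, fraction=0.75, seed=3)
        assert s1 == s2

    def test_stratification_within_one_entry(self, toy_library):
        split = split_library(toy_library, fraction=0.75, seed=4)
        for cls in toy_library.classes:
            class_ids = {e.pdb_id for e in toy_library.entries if e.target_class == cls}
            n_train = len(class_ids & set(split.training))
            assert abs(n_train - 0.75 * len(class_ids)) <= 1

    def test_invalid_fraction_rejected(self, toy_library):
        with pytest.raises(ValueError):
            split_library(toy_library, fraction=1.0, seed=0)
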