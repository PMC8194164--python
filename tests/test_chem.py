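"""Molecule parsing, fingerprint generation, and Tanimoto similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from targetfish.chem import (
    FINGERPRINT_LENGTHS,
    Fingerprint,
    FingerprintAlgorithm,
    FingerprintMismatchError,
    FingerprintSet,
    MoleculeParseError,
    MoleculeRecord,
    compute_fingerprints,
    ligand_similarity,
    load_fingerprint_sets,
    parse_molecules,
    save_fingerprint_sets,
    tanimoto,
)

from conftest import make_fp


def brute_force_tanimoto(bits_a, bits_b):
    """Independent oracle: enumerate set-bit index sets, apply the ratio."""
    on_a = {i for i, b in enumerate(bits_a) if b}
    on_b = {i for i, b in enumerate(bits_b) if b}
    if not on_a and not on_b:
        return 0.0
    return len(on_a & on_b) / (len(on_a) + len(on_b) - len(on_a & on_b))


class TestParseMolecules:
    def test_valid_smiles_in_order(self, tmp_path):
        f = tmp_path / "mols.smi"
        f.write_text("CCO ethanol\nc1ccccc1 benzene\nCC(=O)O acetic\n")
        records = parse_molecules(f)
        assert [r.id for r in records] == ["ethanol", "benzene", "acetic"]

    def test_invalid_entries_skipped_not_fatal(self, tmp_path):
        f = tmp_path / "mols.smi"
        f.write_text("CCO a\nnot_a_smiles((( b\nCCN c\n")
        records = parse_molecules(f)
        assert [r.id for r in records] == ["a", "c"]

    def test_benzene_heavy_atom_count(self, tmp_path):
        f = tmp_path / "one.smi"
        f.write_text("c1ccccc1 bz\n")
        (record,) = parse_molecules(f)
        assert record.rdkit_mol.GetNumHeavyAtoms() == 6

    def test_zero_valid_molecules_raises(self, tmp_path):
        f = tmp_path / "bad.smi"
        f.write_text("xxxx\n")
        with pytest.raises(MoleculeParseError):
            parse_molecules(f)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_molecules(tmp_path / "absent.smi")

    def test_sdf_roundtrip(self, tmp_path):
        mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        Chem.AllChem.EmbedMolecule(mol, randomSeed=3)
        mol.SetProp("_Name", "ethanol3d")
        path = tmp_path / "m.sdf"
        w = Chem.SDWriter(str(path))
        w.write(mol)
        w.close()
        (record,) = parse_molecules(path, fmt="sdf")
        assert record.id == "ethanol3d"
        assert record.smiles == Chem.CanonSmiles("CCO")


class TestComputeFingerprints:
    def test_deterministic_and_lengths(self):
        rec = MoleculeRecord.from_smiles("CCO", "eth")
        algos = list(FingerprintAlgorithm)
        fps1 = compute_fingerprints(rec, algos)
        fps2 = compute_fingerprints(rec, algos)
        for algo in algos:
            assert fps1[algo].n_bits == FINGERPRINT_LENGTHS[algo]
            assert np.array_equal(fps1[algo].bits, fps2[algo].bits)

    def test_methane_morgan(self):
        fps = compute_fingerprints(MoleculeRecord.from_smiles("C", "methane"), ["morgan"])
        fp = fps[FingerprintAlgorithm.MORGAN]
        assert fp.n_bits == 2048 and fp.n_on >= 0

    def test_atom_order_invariance(self, tmp_path):
        # same molecule, permuted atom numbering in the SDF input
        mol = Chem.MolFromSmiles("CCO")
        permuted = Chem.RenumberAtoms(mol, [2, 0, 1])
        rec_a = MoleculeRecord.from_mol(mol, "a")
        rec_b = MoleculeRecord.from_mol(permuted, "b")
        # independent canonicalization check
        assert Chem.CanonSmiles(Chem.MolToSmiles(permuted, canonical=False)) == rec_a.smiles
        fa = compute_fingerprints(rec_a, ["morgan", "daylight"])
        fb = compute_fingerprints(rec_b, ["morgan", "daylight"])
        for algo in fa.fingerprints:
            assert np.array_equal(fa[algo].bits, fb[algo].bits)

    def test_empty_algorithm_set_rejected(self):
        rec = MoleculeRecord.from_smiles("CCO", "eth")
        with pytest.raises(ValueError):
            compute_fingerprints(rec, [])


class TestTanimoto:
    def test_hand_case(self):
        # N_a=3, N_b=3, N_ab=2 -> 2/(3+3-2) = 0.5
        assert tanimoto(make_fp({0, 1, 2}), make_fp({1, 2, 9})) == pytest.approx(0.5)

    def test_identity_disjoint_and_empty(self):
        a = make_fp({3, 5, 8})
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, make_fp({10, 11})) == 0.0
        assert tanimoto(make_fp(set()), make_fp(set())) == 0.0

    def test_mismatch_rejected(self):
        with pytest.raises(FingerprintMismatchError):
            tanimoto(make_fp({1}), make_fp({1}, algorithm=FingerprintAlgorithm.MACCS))
        with pytest.raises(FingerprintMismatchError):
            tanimoto(make_fp({1}, n_bits=32), make_fp({1}, n_bits=64))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 63), max_size=40), st.lists(st.integers(0, 63), max_size=40))
    def test_matches_brute_force_oracle(self, on_a, on_b):
        a, b = make_fp(set(on_a)), make_fp(set(on_b))
        expected = brute_force_tanimoto(a.bits, b.bits)
        assert tanimoto(a, b) == pytest.approx(expected)
        assert tanimoto(b, a) == pytest.approx(tanimoto(a, b))  # symmetry
        assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_agrees_with_rdkit_on_real_molecules(self):
        """Independent cross-check against the toolkit's own Tanimoto."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        pairs = [("CCO", "CCN"), ("c1ccccc1O", "c1ccccc1N"), ("CC(=O)O", "CCC(=O)O")]
        for sa, sb in pairs:
            ours = tanimoto(
                compute_fingerprints(MoleculeRecord.from_smiles(sa, "a"), ["morgan"])[
                    FingerprintAlgorithm.MORGAN
                ],
                compute_fingerprints(MoleculeRecord.from_smiles(sb, "b"), ["morgan"])[
                    FingerprintAlgorithm.MORGAN
                ],
            )
            theirs = DataStructs.TanimotoSimilarity(
                gen.GetFingerprint(Chem.MolFromSmiles(sa)),
                gen.GetFingerprint(Chem.MolFromSmiles(sb)),
            )
            assert ours == pytest.approx(theirs)


def _fpset(mol_id, fps):
    return FingerprintSet(molecule_id=mol_id, fingerprints={f.algorithm: f for f in fps})


class TestLigandSimilarity:
    def _controlled_pair(self, targets):
        """Build fingerprint-set pair whose per-algorithm Tanimotos are `targets`."""
        algos = [FingerprintAlgorithm.MORGAN, FingerprintAlgorithm.MACCS,
                 FingerprintAlgorithm.DAYLIGHT][: len(targets)]
        q_fps, r_fps = [], []
        for algo, t in zip(algos, targets):
            # query has bits 0..99 on; reference shares exactly round(100t) of them
            # reference bits are a subset of the query's: T = s/(100 + s - s) = s/100
            shared = round(100 * t)
            q_fps.append(make_fp(range(100), n_bits=256, algorithm=algo))
            r_fps.append(make_fp(range(shared), n_bits=256, algorithm=algo))
        return _fpset("q", q_fps), _fpset("r", r_fps), algos

    def test_mean_of_components(self):
        q, r, algos = self._controlled_pair([0.2, 0.4, 0.6])
        score = ligand_similarity(q, r, algos)
        assert score.value == pytest.approx(np.mean(list(score.components.values())))
        assert score.value == pytest.approx(0.4, abs=0.02)

    def test_single_algorithm_equals_tanimoto(self):
        q, r, algos = self._controlled_pair([0.5])
        score = ligand_similarity(q, r, algos)
        assert score.value == tanimoto(q[algos[0]], r[algos[0]])

    def test_identity_gives_one(self):
        rec = MoleculeRecord.from_smiles("CCOc1ccccc1", "m")
        fps = compute_fingerprints(rec, ["morgan", "maccs", "daylight"])
        score = ligand_similarity(fps, fps, ["morgan", "maccs", "daylight"])
        assert score.value == 1.0 and all(v == 1.0 for v in score.components.values())

    def test_missing_algorithm_is_error(self):
        q = _fpset("q", [make_fp({1})])
        r = _fpset("r", [make_fp({1})])
        with pytest.raises(KeyError):
            ligand_similarity(q, r, ["morgan", "maccs"])

    def test_monotone_in_components(self):
        # raising one component Tanimoto cannot lower the mean
        lo = ligand_similarity(*self._controlled_pair([0.2, 0.4, 0.3])[:2],
                               [FingerprintAlgorithm.MORGAN, FingerprintAlgorithm.MACCS,
                                FingerprintAlgorithm.DAYLIGHT])
        hi = ligand_similarity(*self._controlled_pair([0.2, 0.8, 0.3])[:2],
                               [FingerprintAlgorithm.MORGAN, FingerprintAlgorithm.MACCS,
                                FingerprintAlgorithm.DAYLIGHT])
        assert hi.value >= lo.value


def test_sidecar_roundtrip(tmp_path):
    recs = [MoleculeRecord.from_smiles(s, f"m{i}") for i, s in enumerate(["CCO", "c1ccccc1"])]
    sets = [compute_fingerprints(r, ["morgan", "maccs", "avalon"]) for r in recs]
    path = tmp_path / "fps.bin"
    save_fingerprint_sets(sets, path)
    loaded = load_fingerprint_sets(path)
    assert [s.molecule_id for s in loaded] == ["m0", "m1"]
    for orig, back in zip(sets, loaded):
        for algo, fp in orig.fingerprints.items():
            assert np.array_equal(fp.bits, back[algo].bits)
    # double save is byte-identical
    path2 = tmp_path / "fps2.bin"
    save_fingerprint_sets(loaded, path2)
    assert path.read_bytes() == path2.read_bytes()
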