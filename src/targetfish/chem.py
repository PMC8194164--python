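"""Molecule handling, fingerprint generation and Tanimoto ligand similarity.

The ligand-similarity score ``T_L`` between a query and a reference ligand is
the unweighted mean of per-algorithm Tanimoto coefficients

    T = N_ab / (N_a + N_b - N_ab)

where ``N_a`` and ``N_b`` count the set bits of the two fingerprints and
``N_ab`` the bits set in both.  Fingerprint presets follow common practice in
ligand-based target fishing: ``MM`` = Morgan + MACCS, ``MMD`` = Morgan +
MACCS + Daylight-style path fingerprint.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

logger = logging.getLogger(__name__)


class FingerprintAlgorithm(str, Enum):
    """Supported 2D fingerprint algorithms."""

    MORGAN = "morgan"
    MACCS = "maccs"
    DAYLIGHT = "daylight"
    ATOMPAIRS = "atompairs"
    TORSION = "torsion"
    PHARMACOPHORE2D = "pharmacophore2d"
    AVALON = "avalon"


#: Configured bit lengths.  Morgan radius 2 and the Daylight-style path
#: fingerprint are folded to 2048 bits; MACCS is the fixed 167-slot RDKit
#: key set (bit 0 unused); Avalon at 512 bits is used as the QSAR descriptor.
#: Atom-pair / torsion / 2D-pharmacophore use the toolkit defaults.
FINGERPRINT_LENGTHS: dict[FingerprintAlgorithm, int] = {
    FingerprintAlgorithm.MORGAN: 2048,
    FingerprintAlgorithm.MACCS: 167,
    FingerprintAlgorithm.DAYLIGHT: 2048,
    FingerprintAlgorithm.ATOMPAIRS: 2048,
    FingerprintAlgorithm.TORSION: 2048,
    FingerprintAlgorithm.PHARMACOPHORE2D: 39972,
    FingerprintAlgorithm.AVALON: 512,
}

#: Fingerprint-set presets for the ligand similarity search.
PRESETS: dict[str, tuple[FingerprintAlgorithm, ...]] = {
    "MM": (FingerprintAlgorithm.MORGAN, FingerprintAlgorithm.MACCS),
    "MMD": (
        FingerprintAlgorithm.MORGAN,
        FingerprintAlgorithm.MACCS,
        FingerprintAlgorithm.DAYLIGHT,
    ),
}


class MoleculeParseError(ValueError):
    """A molecule could not be parsed or has no heavy atoms."""


class FingerprintError(RuntimeError):
    """Fingerprint computation failed for a named algorithm."""

    def __init__(self, algorithm: FingerprintAlgorithm, message: str):
        self.algorithm = algorithm
        super().__init__(f"{algorithm.value}: {message}")


class FingerprintMismatchError(ValueError):
    """Two fingerprints are not comparable (algorithm or length differ)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed small molecule with its canonical SMILES.

    ``smiles`` is canonicalized at ingestion so duplicate detection and
    fingerprinting are independent of input atom ordering.  ``mol`` retains
    the RDKit molecule (with conformer, when the source had 3D coordinates).
    """

    id: str
    smiles: str
    source: str = "smiles"  # smiles | sdf | pdb-ligand
    mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str, source: str = "smiles") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise MoleculeParseError(f"{mol_id!r}: cannot parse SMILES {smiles!r}")
        return cls(id=mol_id, smiles=Chem.MolToSmiles(mol), source=source, mol=mol)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, mol_id: str, source: str = "sdf") -> "MoleculeRecord":
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise MoleculeParseError(f"{mol_id!r}: empty molecule")
        # canonical SMILES on the H-suppressed graph; the stored mol keeps
        # any explicit hydrogens and conformer for 3D work
        return cls(id=mol_id, smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)),
                   source=source, mol=mol)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        """The RDKit molecule, re-parsed from canonical SMILES when absent."""
        if self.mol is not None:
            return self.mol
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise MoleculeParseError(f"{self.id!r}: stored SMILES unparsable")
        return mol


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary fingerprint for one molecule."""

    algorithm: FingerprintAlgorithm
    bits: np.ndarray  # uint8 0/1 vector

    def __post_init__(self):
        object.__setattr__(self, "bits", np.ascontiguousarray(self.bits, dtype=np.uint8))

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    @property
    def on_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class FingerprintSet:
    """All fingerprints computed for one molecule, keyed by algorithm."""

    molecule_id: str
    fingerprints: dict[FingerprintAlgorithm, Fingerprint]

    def __getitem__(self, algorithm: FingerprintAlgorithm) -> Fingerprint:
        return self.fingerprints[algorithm]

    def __contains__(self, algorithm: FingerprintAlgorithm) -> bool:
        return algorithm in self.fingerprints


@dataclass(frozen=True)
class SimilarityScore:
    """Per-algorithm Tanimoto components and their mean (``T_L``)."""

    value: float
    components: dict[FingerprintAlgorithm, float]


def parse_molecules(path: str | Path, fmt: str = "smiles") -> list[MoleculeRecord]:
    """Read molecules from a SMILES file (``smiles id`` per line) or an SDF.

    Valid molecules are returned in file order; unparsable entries are logged
    and skipped, never silently dropped without a report.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    MoleculeParseError
        if the file yields zero valid molecules.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    n_rejected = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}_{lineno}"
            try:
                records.append(MoleculeRecord.from_smiles(smiles, mol_id))
            except MoleculeParseError:
                n_rejected += 1
                logger.warning("rejected unparsable SMILES at %s:%d: %s", path, lineno, smiles)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_rejected += 1
                logger.warning("rejected unparsable SDF entry %d in %s", i, path)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{i}"
            records.append(MoleculeRecord.from_mol(mol, name, source="sdf"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not records:
        raise MoleculeParseError(f"no valid molecules in {path}")
    return records


def _bitvect_to_array(bv) -> np.ndarray:
    arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=FINGERPRINT_LENGTHS[FingerprintAlgorithm.MORGAN]
)
_RDK_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(
    fpSize=FINGERPRINT_LENGTHS[FingerprintAlgorithm.DAYLIGHT]
)
_AP_GEN = rdFingerprintGenerator.GetAtomPairGenerator(
    fpSize=FINGERPRINT_LENGTHS[FingerprintAlgorithm.ATOMPAIRS]
)
_TT_GEN = rdFingerprintGenerator.GetTopologicalTorsionGenerator(
    fpSize=FINGERPRINT_LENGTHS[FingerprintAlgorithm.TORSION]
)


def _compute_one(mol: Chem.Mol, algorithm: FingerprintAlgorithm) -> np.ndarray:
    if algorithm is FingerprintAlgorithm.MORGAN:
        return _bitvect_to_array(_MORGAN_GEN.GetFingerprint(mol))
    if algorithm is FingerprintAlgorithm.MACCS:
        return _bitvect_to_array(MACCSkeys.GenMACCSKeys(mol))
    if algorithm is FingerprintAlgorithm.DAYLIGHT:
        return _bitvect_to_array(_RDK_GEN.GetFingerprint(mol))
    if algorithm is FingerprintAlgorithm.ATOMPAIRS:
        return _bitvect_to_array(_AP_GEN.GetFingerprint(mol))
    if algorithm is FingerprintAlgorithm.TORSION:
        return _bitvect_to_array(_TT_GEN.GetFingerprint(mol))
    if algorithm is FingerprintAlgorithm.PHARMACOPHORE2D:
        return _bitvect_to_array(Generate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory))
    if algorithm is FingerprintAlgorithm.AVALON:
        return _bitvect_to_array(
            pyAvalonTools.GetAvalonFP(mol, nBits=FINGERPRINT_LENGTHS[FingerprintAlgorithm.AVALON])
        )
    raise FingerprintError(algorithm, "unsupported algorithm")


def compute_fingerprints(
    record: MoleculeRecord,
    algorithms: Iterable[FingerprintAlgorithm | str],
) -> FingerprintSet:
    """Compute the requested fingerprints for one molecule.

    Fingerprints are computed from the canonical-SMILES molecule, so two
    representations of the same molecule (e.g. SDF with permuted atom order)
    yield bit-identical fingerprints.
    """
    algos = [FingerprintAlgorithm(a) for a in algorithms]
    if not algos:
        raise ValueError("algorithms must be non-empty")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise MoleculeParseError(f"{record.id!r}: stored SMILES unparsable")
    fps: dict[FingerprintAlgorithm, Fingerprint] = {}
    for algo in algos:
        try:
            bits = _compute_one(mol, algo)
        except FingerprintError:
            raise
        except Exception as exc:  # pragma: no cover - toolkit internal failure
            raise FingerprintError(algo, str(exc)) from exc
        fps[algo] = Fingerprint(algorithm=algo, bits=bits)
    return FingerprintSet(molecule_id=record.id, fingerprints=fps)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient ``N_ab / (N_a + N_b - N_ab)`` of two fingerprints.

    Two all-zero fingerprints compare as 0.0 (with a warning) rather than
    NaN or 1.0, so featureless molecules never rank as perfect matches.
    """
    if a.algorithm != b.algorithm or a.n_bits != b.n_bits:
        raise FingerprintMismatchError(
            f"cannot compare {a.algorithm.value}[{a.n_bits}] with {b.algorithm.value}[{b.n_bits}]"
        )
    n_a = a.n_on
    n_b = b.n_on
    if n_a == 0 and n_b == 0:
        logger.warning("Tanimoto of two all-zero fingerprints defined as 0.0")
        return 0.0
    n_ab = int(np.count_nonzero(a.bits & b.bits))
    return n_ab / (n_a + n_b - n_ab)


def ligand_similarity(
    query: FingerprintSet,
    reference: FingerprintSet,
    algorithms: Sequence[FingerprintAlgorithm | str],
) -> SimilarityScore:
    """Ligand-similarity score ``T_L``: mean per-algorithm Tanimoto.

    Every requested algorithm must be present in both sets; a missing one is
    a contract error, never silently averaged over a subset.
    """
    algos = [FingerprintAlgorithm(a) for a in algorithms]
    if not algos:
        raise ValueError("algorithms must be non-empty")
    components: dict[FingerprintAlgorithm, float] = {}
    for algo in algos:
        if algo not in query or algo not in reference:
            raise KeyError(f"algorithm {algo.value!r} missing from a fingerprint set")
        components[algo] = tanimoto(query[algo], reference[algo])
    return SimilarityScore(value=float(np.mean(list(components.values()))), components=components)


# ---------------------------------------------------------------------------
# Binary sidecar serialization: fingerprints are stored packed so libraries
# load without re-deriving them from structures.
# ---------------------------------------------------------------------------

_MAGIC = b"TFFP"


def save_fingerprint_sets(sets: Sequence[FingerprintSet], path: str | Path) -> None:
    """Write fingerprint sets to a length-prefixed packed binary sidecar."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(sets)))
        for fpset in sets:
            mol_id = fpset.molecule_id.encode()
            fh.write(struct.pack("<H", len(mol_id)))
            fh.write(mol_id)
            fh.write(struct.pack("<H", len(fpset.fingerprints)))
            for algo in sorted(fpset.fingerprints, key=lambda a: a.value):
                fp = fpset.fingerprints[algo]
                tag = algo.value.encode()
                packed = np.packbits(fp.bits).tobytes()
                fh.write(struct.pack("<H", len(tag)))
                fh.write(tag)
                fh.write(struct.pack("<II", fp.n_bits, len(packed)))
                fh.write(packed)


def load_fingerprint_sets(path: str | Path) -> list[FingerprintSet]:
    """Read fingerprint sets written by :func:`save_fingerprint_sets`."""
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path}: not a fingerprint sidecar file")
        (n_sets,) = struct.unpack("<I", fh.read(4))
        out: list[FingerprintSet] = []
        for _ in range(n_sets):
            (id_len,) = struct.unpack("<H", fh.read(2))
            mol_id = fh.read(id_len).decode()
            (n_fp,) = struct.unpack("<H", fh.read(2))
            fps: dict[FingerprintAlgorithm, Fingerprint] = {}
            for _ in range(n_fp):
                (tag_len,) = struct.unpack("<H", fh.read(2))
                algo = FingerprintAlgorithm(fh.read(tag_len).decode())
                n_bits, n_bytes = struct.unpack("<II", fh.read(8))
                packed = np.frombuffer(fh.read(n_bytes), dtype=np.uint8)
                bits = np.unpackbits(packed)[:n_bits]
                fps[algo] = Fingerprint(algorithm=algo, bits=bits)
            out.append(FingerprintSet(molecule_id=mol_id, fingerprints=fps))
    return out
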