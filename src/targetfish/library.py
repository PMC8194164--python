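"""Reference target library: build, validate, serialize, split.

A library row is one protein-ligand complex: receptor structure, co-crystal
ligand (with 3D coordinates), target class and name, and the experimental
binding activity in -log M (pKi/pKd/pIC50).  Building a library computes the
co-crystal fingerprint set and the reference interaction fingerprint for
every entry, so the prediction pipeline never touches raw structures again.

Serialized form: a directory with a JSON manifest, a packed binary
fingerprint sidecar, and the copied structure files — human-inspectable and
diff-able.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import pdbqt
from .chem import (
    FINGERPRINT_LENGTHS,
    FingerprintAlgorithm,
    FingerprintSet,
    MoleculeRecord,
    load_fingerprint_sets,
    save_fingerprint_sets,
)
from .ifp import DEFAULT_SCHEME, IFPScheme, InteractionFingerprint, extract_ifp
from .structures import (
    ALLOWED_METALS,
    STANDARD_AMINO_ACIDS,
    ReceptorStructure,
    add_backbone_amide_hydrogens,
    parse_receptor,
    write_receptor_pdb,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["pdb_id", "receptor", "ligand", "class", "target_name", "activity", "activity_kind"]

#: Library-default fingerprint algorithms: the MMD similarity-search set plus
#: Avalon, which serves as the activity-model descriptor.
DEFAULT_ALGORITHMS = (
    FingerprintAlgorithm.MORGAN,
    FingerprintAlgorithm.MACCS,
    FingerprintAlgorithm.DAYLIGHT,
    FingerprintAlgorithm.AVALON,
)


class LibraryBuildError(RuntimeError):
    pass


@dataclass
class TargetEntry:
    """One reference protein-ligand complex."""

    pdb_id: str
    target_class: str
    target_name: str
    receptor_path: Path
    cocrystal_ligand: MoleculeRecord
    cocrystal_fps: FingerprintSet
    reference_ifp: InteractionFingerprint
    activity: float | None = None
    activity_kind: str | None = None  # Ki | Kd | IC50
    receptor: ReceptorStructure | None = field(default=None, repr=False)

    def receptor_structure(self) -> ReceptorStructure:
        if self.receptor is None:
            self.receptor = parse_receptor(self.receptor_path)
        return self.receptor


@dataclass
class TargetLibrary:
    entries: list[TargetEntry]
    metadata: dict

    def __post_init__(self):
        ids = [e.pdb_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise LibraryBuildError("duplicate pdb_id in library")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def classes(self) -> set[str]:
        return {e.target_class for e in self.entries}

    def by_id(self, pdb_id: str) -> TargetEntry:
        for entry in self.entries:
            if entry.pdb_id == pdb_id:
                return entry
        raise KeyError(pdb_id)

    def validate(self) -> None:
        """Reject entries whose fingerprint lengths disagree with metadata."""
        lengths = self.metadata["fingerprints"]
        for entry in self.entries:
            for algo, fp in entry.cocrystal_fps.fingerprints.items():
                expected = lengths.get(algo.value)
                if expected is not None and fp.n_bits != expected:
                    raise LibraryBuildError(
                        f"{entry.pdb_id}: {algo.value} length {fp.n_bits} != metadata {expected}"
                    )


@dataclass(frozen=True)
class DataSplit:
    training: list[str]
    validation: list[str]
    seed: int


# ---------------------------------------------------------------------------
# Receptor / ligand preparation
# ---------------------------------------------------------------------------

def prepare_receptor(
    pdb_path: str | Path,
    out_path: str | Path | None = None,
    allowed_residues: set[str] | None = None,
) -> tuple[ReceptorStructure, Path]:
    """Clean a receptor: drop waters and non-allowed residues, add hydrogens.

    Waters (HOH/WAT) and residues outside the allow-list (20 canonical amino
    acids plus common catalytic metals) are removed; backbone amide hydrogens
    are placed geometrically when the structure carries none.  Output is a
    cleaned PDB file (PDBQT only via an externally configured converter).
    """
    allowed = allowed_residues or (STANDARD_AMINO_ACIDS | ALLOWED_METALS)
    structure = parse_receptor(pdb_path)
    kept = [
        res for res in structure.residues
        if not res.is_water and res.resname in allowed
    ]
    n_dropped = len(structure.residues) - len(kept)
    if n_dropped:
        logger.info("prepare_receptor: removed %d water/non-standard residues", n_dropped)
    cleaned = ReceptorStructure(kept, source=str(pdb_path))
    if cleaned.n_atoms == 0:
        raise LibraryBuildError(f"{pdb_path}: empty structure after cleaning")
    has_hydrogens = any(a.element == "H" for r in kept for a in r.atoms)
    if not has_hydrogens:
        add_backbone_amide_hydrogens(cleaned)
    out = Path(out_path) if out_path else Path(pdb_path).with_suffix(".prepared.pdb")
    write_receptor_pdb(cleaned, out)
    return cleaned, out


def prepare_ligand(
    record: MoleculeRecord,
    out_path: str | Path,
    fmt: str = "pdbqt",
) -> Path:
    """Write a docking-ready ligand file (PDBQT with torsion annotation, or SDF)."""
    mol = record.mol
    if mol is None or mol.GetNumConformers() == 0:
        raise ValueError(f"{record.id}: ligand has no 3D coordinates")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"{record.id}: ligand has no heavy atoms")
    out = Path(out_path)
    if fmt == "pdbqt":
        pdbqt.write_ligand_pdbqt(mol, out)
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(out))
        writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown ligand format {fmt!r}")
    return out


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

def _load_cocrystal_ligand(path: Path, mol_id: str) -> MoleculeRecord:
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        mol = next((m for m in supplier if m is not None), None)
    else:
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
    if mol is None:
        raise LibraryBuildError(f"{path}: cannot parse co-crystal ligand")
    if mol.GetNumConformers() == 0:
        raise LibraryBuildError(f"{path}: co-crystal ligand has no 3D coordinates")
    return MoleculeRecord.from_mol(mol, mol_id, source="pdb-ligand" if path.suffix != ".sdf" else "sdf")


def build_library(
    manifest: str | Path | pd.DataFrame,
    algorithms=DEFAULT_ALGORITHMS,
    scheme: IFPScheme = DEFAULT_SCHEME,
    base_dir: str | Path | None = None,
) -> tuple[TargetLibrary, list[dict]]:
    """Build a target library from a manifest table.

    Manifest columns: ``pdb_id,receptor,ligand,class,target_name,activity,
    activity_kind``.  Rows whose structure files are missing or unparsable
    are rejected with a reason (returned in the build report); duplicate
    pdb_ids or missing class labels abort the build.

    Returns (library, build_report) where the report lists rejected rows.
    """
    if isinstance(manifest, (str, Path)):
        base_dir = base_dir or Path(manifest).parent
        table = pd.read_csv(manifest, dtype={"pdb_id": str})
    else:
        table = manifest.copy()
        base_dir = base_dir or Path(".")
    base_dir = Path(base_dir)
    missing_cols = set(MANIFEST_COLUMNS[:5]) - set(table.columns)
    if missing_cols:
        raise LibraryBuildError(f"manifest missing columns: {sorted(missing_cols)}")
    if table["pdb_id"].duplicated().any():
        dupes = table.loc[table["pdb_id"].duplicated(), "pdb_id"].tolist()
        raise LibraryBuildError(f"duplicate pdb_id in manifest: {dupes}")
    if table["class"].isna().any() or (table["class"].astype(str).str.strip() == "").any():
        raise LibraryBuildError("manifest row with missing class label")

    from .chem import compute_fingerprints  # local import avoids cycle at module load

    algos = [FingerprintAlgorithm(a) for a in algorithms]
    entries: list[TargetEntry] = []
    report: list[dict] = []
    for _, row in table.iterrows():
        pdb_id = str(row["pdb_id"])
        receptor_path = base_dir / str(row["receptor"])
        ligand_path = base_dir / str(row["ligand"])
        try:
            if not receptor_path.exists():
                raise LibraryBuildError(f"receptor file not found: {receptor_path}")
            if not ligand_path.exists():
                raise LibraryBuildError(f"ligand file not found: {ligand_path}")
            receptor, prepared_path = prepare_receptor(
                receptor_path, receptor_path.with_suffix(".prepared.pdb")
            )
            ligand = _load_cocrystal_ligand(ligand_path, f"{pdb_id}_ligand")
            fps = compute_fingerprints(ligand, algos)
            ref_ifp = extract_ifp(receptor, ligand.mol, scheme)
            activity = row.get("activity")
            activity = float(activity) if activity is not None and np.isfinite(float(activity)) else None
            entries.append(
                TargetEntry(
                    pdb_id=pdb_id,
                    target_class=str(row["class"]),
                    target_name=str(row["target_name"]),
                    receptor_path=prepared_path,
                    cocrystal_ligand=ligand,
                    cocrystal_fps=fps,
                    reference_ifp=ref_ifp,
                    activity=activity,
                    activity_kind=str(row["activity_kind"]) if "activity_kind" in row and pd.notna(row["activity_kind"]) else None,
                    receptor=receptor,
                )
            )
        except (LibraryBuildError, ValueError) as exc:
            logger.warning("rejecting manifest row %s: %s", pdb_id, exc)
            report.append({"pdb_id": pdb_id, "reason": str(exc)})
    metadata = {
        "fingerprints": {a.value: FINGERPRINT_LENGTHS[a] for a in algos},
        "ifp_scheme": scheme.version,
        "built": None,
    }
    library = TargetLibrary(entries=entries, metadata=metadata)
    library.validate()
    return library, report


# ---------------------------------------------------------------------------
# Serialization: directory with JSON manifest + fingerprint sidecar + files
# ---------------------------------------------------------------------------

def save_library(library: TargetLibrary, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"metadata": library.metadata, "entries": []}
    fp_sets = []
    for entry in library.entries:
        receptor_name = f"{entry.pdb_id}_receptor.pdb"
        dest = out / "structures" / receptor_name
        if Path(entry.receptor_path).resolve() != dest.resolve():
            shutil.copyfile(entry.receptor_path, dest)
        ligand_name = f"{entry.pdb_id}_ligand.sdf"
        writer = Chem.SDWriter(str(out / "structures" / ligand_name))
        writer.write(entry.cocrystal_ligand.mol)
        writer.close()
        manifest["entries"].append(
            {
                "pdb_id": entry.pdb_id,
                "target_class": entry.target_class,
                "target_name": entry.target_name,
                "receptor": f"structures/{receptor_name}",
                "ligand": f"structures/{ligand_name}",
                "ligand_smiles": entry.cocrystal_ligand.smiles,
                "activity": entry.activity,
                "activity_kind": entry.activity_kind,
                "reference_ifp": {
                    "residue_index": [list(k) for k in entry.reference_ifp.residue_index],
                    "bits_hex": np.packbits(entry.reference_ifp.bits).tobytes().hex(),
                    "scheme_version": entry.reference_ifp.scheme_version,
                },
            }
        )
        fp_sets.append(entry.cocrystal_fps)
    save_fingerprint_sets(fp_sets, out / "fingerprints.bin")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out


def load_library(lib_dir: str | Path) -> TargetLibrary:
    lib_dir = Path(lib_dir)
    manifest = json.loads((lib_dir / "manifest.json").read_text())
    fp_sets = {s.molecule_id: s for s in load_fingerprint_sets(lib_dir / "fingerprints.bin")}
    entries = []
    for em in manifest["entries"]:
        ligand = _load_cocrystal_ligand(lib_dir / em["ligand"], f"{em['pdb_id']}_ligand")
        ifp_meta = em["reference_ifp"]
        residue_index = [tuple(k) for k in ifp_meta["residue_index"]]
        n_bits = 8 * len(residue_index)
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(ifp_meta["bits_hex"]), dtype=np.uint8))[:n_bits]
        entries.append(
            TargetEntry(
                pdb_id=em["pdb_id"],
                target_class=em["target_class"],
                target_name=em["target_name"],
                receptor_path=lib_dir / em["receptor"],
                cocrystal_ligand=ligand,
                cocrystal_fps=fp_sets[f"{em['pdb_id']}_ligand"],
                reference_ifp=InteractionFingerprint(
                    residue_index=residue_index,
                    bits=bits,
                    scheme_version=ifp_meta["scheme_version"],
                ),
                activity=em["activity"],
                activity_kind=em["activity_kind"],
            )
        )
    library = TargetLibrary(entries=entries, metadata=manifest["metadata"])
    library.validate()
    return library


# ---------------------------------------------------------------------------
# Train / validation split
# ---------------------------------------------------------------------------

def split_library(library: TargetLibrary, fraction: float = 0.8, seed: int = 0) -> DataSplit:
    """Per-class stratified split with the guarantee that every validation
    entry's target_name also occurs in the training set.

    The first (shuffled) entry of every target_name group is pinned to
    training, so a target_name represented by a single complex always trains
    (logged); validation entries are then drawn per class to match the
    requested fraction as closely as the constraint allows.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    training: list[str] = []
    validation: list[str] = []
    for cls in sorted(library.classes):
        class_entries = [e for e in library.entries if e.target_class == cls]
        order = rng.permutation(len(class_entries))
        shuffled = [class_entries[i] for i in order]
        pinned: set[str] = set()
        eligible: list[TargetEntry] = []
        seen_names: set[str] = set()
        for entry in shuffled:
            if entry.target_name not in seen_names:
                pinned.add(entry.pdb_id)
                seen_names.add(entry.target_name)
            else:
                eligible.append(entry)
        n_val = round((1 - fraction) * len(class_entries))
        if n_val > len(eligible):
            logger.warning(
                "class %s: only %d of %d requested validation entries available "
                "(single-complex targets forced into training)",
                cls, len(eligible), n_val,
            )
            n_val = len(eligible)
        val_ids = {e.pdb_id for e in eligible[:n_val]}
        for entry in class_entries:
            (validation if entry.pdb_id in val_ids else training).append(entry.pdb_id)
    split = DataSplit(training=training, validation=validation, seed=seed)
    _check_split(library, split)
    return split


def _check_split(library: TargetLibrary, split: DataSplit) -> None:
    train_names = {library.by_id(i).target_name for i in split.training}
    for pdb_id in split.validation:
        name = library.by_id(pdb_id).target_name
        if name not in train_names:
            raise AssertionError(f"validation entry {pdb_id} target {name!r} absent from training")
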