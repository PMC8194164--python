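"""Deterministic synthetic fixtures: complexes, libraries, datasets, decoys.

Every generator is a pure function of (spec, seed), so fixture bytes are
reproducible.  Receptors are idealized short peptide chains written directly
in PDB format: residues are spaced 10 A apart along x with a planar local
backbone template, which is deliberately non-physical — geometric
interaction tests need exact control over which contacts exist, not
realistic protein models.  Ligand fragments are placed analytically so that
the scheme-v1 interaction detector recovers exactly the declared bit set;
this round trip is the primary correctness harness for the interaction-
fingerprint module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs
from rdkit.Geometry import Point3D

from .activity import AVALON_BITS, ActivityDataset, featurize_avalon
from .chem import MoleculeRecord
from .structures import Atom, ReceptorStructure, Residue, write_receptor_pdb

RESIDUE_SPACING = 10.0  # Angstrom between consecutive CA atoms along x

# local backbone template (relative to CA): planar, N-H pointing +y, C=O -y
_BACKBONE = {
    "N": (-1.46, 0.0, 0.0),
    "H": (-1.46, 1.01, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.75, -1.25, 0.0),
    "O": (0.65, -2.47, 0.0),
}

_SIDECHAINS = {
    "GLY": {},
    "ALA": {"CB": (0.0, 0.51, 1.44)},
    "PHE": {
        "CB": (0.0, 0.51, 1.44),
        "CG": (0.0, 0.51, 2.95),
        "CD1": (1.204, 0.51, 3.645),
        "CD2": (-1.204, 0.51, 3.645),
        "CE1": (1.204, 0.51, 5.035),
        "CE2": (-1.204, 0.51, 5.035),
        "CZ": (0.0, 0.51, 5.73),
    },
    "ASP": {
        "CB": (0.0, 0.51, 1.44),
        "CG": (0.0, 0.51, 2.97),
        "OD1": (0.0, 1.59, 3.60),
        "OD2": (0.0, -0.57, 3.60),
    },
    "LYS": {
        "CB": (0.0, 0.51, 1.44),
        "CG": (0.0, 0.51, 2.95),
        "CD": (0.0, 0.51, 4.46),
        "CE": (0.0, 0.51, 5.97),
        "NZ": (0.0, 0.51, 7.45),
    },
}


class FixtureGeometryError(ValueError):
    """Requested planted geometry cannot be satisfied."""


def _hexagon(center: np.ndarray, axis1: np.ndarray, axis2: np.ndarray, radius: float = 1.39):
    return [
        center + radius * (math.cos(math.radians(a)) * axis1 + math.sin(math.radians(a)) * axis2)
        for a in range(0, 360, 60)
    ]


@dataclass
class _PlantSite:
    """One planted interaction site: residue type + ligand fragment geometry."""

    resname: str
    fragment_smiles: str  # parsed with explicit-H retention
    fragment_coords: list[tuple[float, float, float]]  # local frame, SMILES atom order
    expected: tuple[str, ...]  # interaction types recovered at this residue


def _site_hbond_donor() -> _PlantSite:
    # acetone O placed 2.9 A from the backbone N at D-H...A angle 160 deg
    o = np.array([-0.80, 2.824, 0.0])
    u = (o - np.array(_BACKBONE["N"])) / 2.9
    c2 = o + 1.22 * u
    rot = lambda v, a: np.array(
        [math.cos(a) * v[0] - math.sin(a) * v[1], math.sin(a) * v[0] + math.cos(a) * v[1], 0.0]
    )
    me1 = c2 + 1.5 * rot(u, math.radians(120))
    me2 = c2 + 1.5 * rot(u, math.radians(-120))
    return _PlantSite(
        resname="GLY",
        fragment_smiles="CC(C)=O",
        fragment_coords=[tuple(me1), tuple(c2), tuple(me2), tuple(o)],
        expected=("protein-HB-donor",),
    )


def _site_hbond_acceptor() -> _PlantSite:
    # methanol O-H donating to the backbone carbonyl O along the C=O axis
    o_bb = np.array(_BACKBONE["O"])
    c_bb = np.array(_BACKBONE["C"])
    u = (o_bb - c_bb) / np.linalg.norm(o_bb - c_bb)
    o_lig = o_bb + 2.9 * u
    h_lig = o_lig - 0.96 * u
    c_lig = o_lig + 1.43 * u
    return _PlantSite(
        resname="GLY",
        fragment_smiles="[H]OC",
        fragment_coords=[tuple(h_lig), tuple(o_lig), tuple(c_lig)],
        expected=("protein-HB-acceptor",),
    )


def _site_hydrophobic() -> _PlantSite:
    cb = np.array(_SIDECHAINS["ALA"]["CB"])
    mid = cb + np.array([0.0, 0.0, 4.0])
    return _PlantSite(
        resname="ALA",
        fragment_smiles="CCC",
        fragment_coords=[
            (mid[0] - 1.26, mid[1], mid[2] + 0.71),
            tuple(mid),
            (mid[0] + 1.26, mid[1], mid[2] + 0.71),
        ],
        expected=("hydrophobic",),
    )


def _site_aromatic_face() -> _PlantSite:
    # benzene stacked parallel 3.5 A above the PHE ring plane; the stacked
    # carbons necessarily also satisfy the hydrophobic contact criterion
    center = np.array([0.0, 0.51 + 3.5, 4.34])
    ring = _hexagon(center, np.array([1.0, 0, 0]), np.array([0.0, 0, 1.0]))
    return _PlantSite(
        resname="PHE",
        fragment_smiles="c1ccccc1",
        fragment_coords=[tuple(p) for p in ring],
        expected=("aromatic-face", "hydrophobic"),
    )


def _site_aromatic_edge() -> _PlantSite:
    # T-shaped: ligand ring perpendicular, centroids 5.8 A apart — inside the
    # edge window but beyond every hydrophobic contact distance
    center = np.array([0.0, 0.51 + 5.8, 4.34])
    ring = _hexagon(center, np.array([1.0, 0, 0]), np.array([0.0, 1.0, 0]))
    return _PlantSite(
        resname="PHE",
        fragment_smiles="c1ccccc1",
        fragment_coords=[tuple(p) for p in ring],
        expected=("aromatic-edge",),
    )


def _site_salt_bridge_negative() -> _PlantSite:
    # methylammonium N+ 3.76 A from the ASP carboxylate oxygens: inside the
    # 4.0 A salt-bridge cutoff, outside the 3.5 A hydrogen-bond cutoff
    n = np.array([0.0, 0.51, 7.2])
    c = n + np.array([0.0, 0.0, 1.5])
    return _PlantSite(
        resname="ASP",
        fragment_smiles="C[NH3+]",
        fragment_coords=[tuple(c), tuple(n)],
        expected=("salt-bridge-protein-negative",),
    )


def _site_salt_bridge_positive() -> _PlantSite:
    # acetate carboxylate O- 3.8 A beyond the LYS NZ along the side chain
    nz = np.array(_SIDECHAINS["LYS"]["NZ"])
    o_minus = nz + np.array([0.0, 0.0, 3.8])
    c_carboxyl = o_minus + np.array([0.0, 0.0, 1.27])
    o_double = c_carboxyl + np.array([0.0, 1.08, 0.63])
    c_methyl = c_carboxyl + np.array([0.0, -1.2, 0.9])
    return _PlantSite(
        resname="LYS",
        fragment_smiles="CC([O-])=O",
        fragment_coords=[tuple(c_methyl), tuple(c_carboxyl), tuple(o_minus), tuple(o_double)],
        expected=("salt-bridge-protein-positive",),
    )


def _site_metal_contact() -> _PlantSite:
    # methanol O coordinating a zinc ion at 2.2 A
    zn = np.array([0.0, 0.0, 6.0])
    o_lig = zn + np.array([0.0, 0.0, 2.2])
    c_lig = o_lig + np.array([0.0, 0.0, 1.43])
    h_lig = o_lig + np.array([0.0, 0.93, 0.24])
    return _PlantSite(
        resname="ZN",
        fragment_smiles="[H]OC",
        fragment_coords=[tuple(h_lig), tuple(o_lig), tuple(c_lig)],
        expected=("metal-contact",),
    )


_SITE_BUILDERS = {
    "protein-HB-donor": _site_hbond_donor,
    "protein-HB-acceptor": _site_hbond_acceptor,
    "hydrophobic": _site_hydrophobic,
    "aromatic-face": _site_aromatic_face,
    "aromatic-edge": _site_aromatic_edge,
    "salt-bridge-protein-negative": _site_salt_bridge_negative,
    "salt-bridge-protein-positive": _site_salt_bridge_positive,
    "metal-contact": _site_metal_contact,
}

PLANTABLE_INTERACTIONS = tuple(_SITE_BUILDERS)


@dataclass
class PlantedComplex:
    """A synthetic complex whose interaction bits are known by construction."""

    receptor: ReceptorStructure
    ligand: MoleculeRecord
    expected: set  # {( (chain, resseq, resname), interaction-type )}
    seed: int


def _make_residue(resname: str, index: int) -> Residue:
    offset = np.array([RESIDUE_SPACING * index, 0.0, 0.0])
    res = Residue(chain="A", resseq=index + 1, resname=resname)
    if resname == "ZN":
        res.hetero = True
        res.atoms.append(Atom("ZN", "Zn", offset + np.array([0.0, 0.0, 6.0])))
        return res
    for name, local in _BACKBONE.items():
        res.atoms.append(Atom(name, name[0], offset + np.array(local)))
    for name, local in _SIDECHAINS[resname].items():
        res.atoms.append(Atom(name, name[0], offset + np.array(local)))
    return res


_SMILES_PARAMS = Chem.SmilesParserParams()
_SMILES_PARAMS.removeHs = False


def _fragment_mol(smiles: str, coords: list[tuple[float, float, float]]) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, _SMILES_PARAMS)
    if mol is None or mol.GetNumAtoms() != len(coords):
        raise FixtureGeometryError(f"fragment {smiles!r}: atom/coordinate mismatch")
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.AddConformer(conf)
    return mol


def generate_complex(
    planted: list[str], seed: int = 0, n_buffer: int = 2, ligand_id: str = "planted_ligand"
) -> PlantedComplex:
    """Build a receptor + positioned ligand realizing exactly ``planted``.

    Each planted interaction type occupies its own residue site, separated
    by buffer glycines (sites are 2 residues = 20 A apart) so fragments
    cannot cross-talk.  With an empty ``planted`` list the ligand (benzene)
    is displaced 40 A from the chain and the fingerprint is all-zero.
    """
    unknown = [p for p in planted if p not in _SITE_BUILDERS]
    if unknown:
        raise FixtureGeometryError(f"cannot plant interaction types: {unknown}")
    sites = [_SITE_BUILDERS[p]() for p in planted]
    n_residues = max(10, n_buffer + 2 * len(sites) + n_buffer)
    site_indices = [n_buffer + 2 * k for k, _ in enumerate(sites)]

    residues = []
    fragment_mols = []
    site_at = dict(zip(site_indices, sites))
    for i in range(n_residues):
        site = site_at.get(i)
        residues.append(_make_residue(site.resname if site else "GLY", i))
        if site:
            offset = np.array([RESIDUE_SPACING * i, 0.0, 0.0])
            coords = [tuple(np.array(c) + offset) for c in site.fragment_coords]
            fragment_mols.append(_fragment_mol(site.fragment_smiles, coords))
    if not sites:
        fragment_mols.append(
            _fragment_mol(
                "c1ccccc1",
                [tuple(p) for p in _hexagon(np.array([0.0, 40.0, 0.0]),
                                            np.array([1.0, 0, 0]), np.array([0.0, 0, 1.0]))],
            )
        )
    ligand = fragment_mols[0]
    for frag in fragment_mols[1:]:
        ligand = Chem.CombineMols(ligand, frag)
    Chem.SanitizeMol(ligand)
    _check_clashes(residues, ligand)

    expected = set()
    for i, site in site_at.items():
        key = ("A", i + 1, site.resname)
        for itype in site.expected:
            expected.add((key, itype))
    return PlantedComplex(
        receptor=ReceptorStructure(residues, source=f"planted:{','.join(planted)}"),
        ligand=MoleculeRecord.from_mol(ligand, ligand_id, source="pdb-ligand"),
        expected=expected,
        seed=seed,
    )


def _check_clashes(residues: list[Residue], ligand: Chem.Mol, min_dist: float = 1.5) -> None:
    conf = ligand.GetConformer()
    lig = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                     conf.GetAtomPosition(i).z] for i in range(ligand.GetNumAtoms())])
    rec = np.array([a.coord for r in residues for a in r.atoms])
    dmin = np.min(np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2))
    if dmin < min_dist:
        raise FixtureGeometryError(f"planted geometry clashes: min distance {dmin:.2f} A")


def write_complex(complex_: PlantedComplex, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write receptor PDB + ligand SDF; returns (receptor_path, ligand_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    receptor_path = out_dir / f"{stem}_receptor.pdb"
    ligand_path = out_dir / f"{stem}_ligand.sdf"
    write_receptor_pdb(complex_.receptor, receptor_path)
    writer = Chem.SDWriter(str(ligand_path))
    writer.write(complex_.ligand.mol)
    writer.close()
    return receptor_path, ligand_path


# ---------------------------------------------------------------------------
# Toy target libraries
# ---------------------------------------------------------------------------

#: Per-class co-crystal ligand families with controlled pairwise similarity:
#: within-family Morgan Tanimoto is moderate-to-high (the first two members
#: of "kinase" are a near-duplicate pair), cross-family pairs stay <= 0.3.
LIGAND_FAMILIES: dict[str, list[str]] = {
    "kinase": [
        "NS(=O)(=O)c1ccc(CCCCCCCC)cc1",
        "NS(=O)(=O)c1ccc(CCCCCCCCC)cc1",
        "NS(=O)(=O)c1ccc(C)cc1",
        "NS(=O)(=O)c1ccc(O)cc1",
        "NS(=O)(=O)c1ccc(Cl)cc1",
        "NS(=O)(=O)c1ccc(CC)cc1",
    ],
    "hiv": [
        "NCCCCCC",
        "NCCCCCCC",
        "NCCCCCCCC",
        "NCCCCCCCCC",
        "CC(N)CCCCC",
        "NCCCCCCCCCC",
    ],
    "carbonic-anhydrase": [
        "NC(=O)c1ccncc1",
        "CNC(=O)c1ccncc1",
        "CCNC(=O)c1ccncc1",
        "NC(=O)c1ccncc1C",
        "NC(=O)c1ccncc1Cl",
        "CC(=O)Nc1ccncc1",
    ],
    "bromodomain": [
        "COc1ccccc1O",
        "CCOc1ccccc1O",
        "COc1ccccc1OC",
        "COc1ccc(F)cc1O",
        "COc1ccccc1N",
        "Oc1ccccc1OCC(F)F",
    ],
}

_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _morgan_tanimoto(smiles_a: str, smiles_b: str) -> float:
    fa = _MORGAN_GEN.GetFingerprint(Chem.MolFromSmiles(smiles_a))
    fb = _MORGAN_GEN.GetFingerprint(Chem.MolFromSmiles(smiles_b))
    return DataStructs.TanimotoSimilarity(fa, fb)


@dataclass
class FixtureSpec:
    """Parameters of a toy library (stands in for a curated complex set)."""

    seed: int = 0
    n_classes: int = 2
    n_targets_per_class: int = 2
    n_ligands_per_target: int = 1
    activity_informative_bits: tuple[int, ...] = (3, 17, 42, 101, 200)
    activity_weights: tuple[float, ...] = (1.5, -1.0, 0.8, 1.2, -0.6)
    activity_noise_sd: float = 0.2
    activity_base: float = 6.0


def generate_library(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a toy library (receptor PDBs, ligand SDFs, manifest CSV).

    Classes draw co-crystal ligands from the fixed family pool; similarity
    structure is verified at generation (near-duplicate pair >= 0.7 within
    the first family, every cross-class pair <= 0.3) and violations raise.
    Each co-crystal ligand is embedded in 3D (seeded ETKDG) and parked
    against a small mixed ALA/GLY receptor; activities follow a linear model
    on the declared informative Avalon bits plus Gaussian noise.

    Returns the manifest path consumed by ``build_library``.
    """
    classes = list(LIGAND_FAMILIES)
    if spec.n_classes > len(classes):
        raise FixtureGeometryError(f"at most {len(classes)} classes available")
    if spec.n_targets_per_class * spec.n_ligands_per_target > 6:
        raise FixtureGeometryError("family pool exhausted: at most 6 ligands per class")
    chosen = classes[: spec.n_classes]
    _validate_pool(chosen)

    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    rows = []
    counter = 0
    weights = np.asarray(spec.activity_weights, dtype=float)
    informative = list(spec.activity_informative_bits)
    for cls in chosen:
        pool = LIGAND_FAMILIES[cls]
        for t in range(spec.n_targets_per_class):
            target_name = f"{cls} target {t + 1}"
            for j in range(spec.n_ligands_per_target):
                smiles = pool[(t * spec.n_ligands_per_target + j) % len(pool)]
                pdb_id = f"S{counter:03d}"
                counter += 1
                record = _embedded_record(smiles, f"{pdb_id}_lig", seed=spec.seed + counter)
                receptor = _parking_receptor()
                _park_ligand(record.mol, receptor)
                receptor_path = out_dir / "structures" / f"{pdb_id}.pdb"
                write_receptor_pdb(receptor, receptor_path)
                ligand_path = out_dir / "structures" / f"{pdb_id}_ligand.sdf"
                writer = Chem.SDWriter(str(ligand_path))
                writer.write(record.mol)
                writer.close()
                bits = featurize_avalon(record)
                activity = float(
                    spec.activity_base
                    + bits[informative] @ weights
                    + rng.normal(0.0, spec.activity_noise_sd)
                )
                rows.append(
                    {
                        "pdb_id": pdb_id,
                        "receptor": f"structures/{pdb_id}.pdb",
                        "ligand": f"structures/{pdb_id}_ligand.sdf",
                        "class": cls,
                        "target_name": target_name,
                        "activity": round(activity, 3),
                        "activity_kind": "Ki",
                    }
                )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def _validate_pool(classes: list[str]) -> None:
    first = LIGAND_FAMILIES[classes[0]]
    if _morgan_tanimoto(first[0], first[1]) < 0.7:
        raise FixtureGeometryError("near-duplicate pair below 0.7 Morgan Tanimoto")
    for i, cls_a in enumerate(classes):
        for cls_b in classes[i + 1:]:
            for sa in LIGAND_FAMILIES[cls_a]:
                for sb in LIGAND_FAMILIES[cls_b]:
                    t = _morgan_tanimoto(sa, sb)
                    if t > 0.3:
                        raise FixtureGeometryError(
                            f"cross-class pair {sa!r}/{sb!r} Tanimoto {t:.2f} > 0.3"
                        )


def _embedded_record(smiles: str, mol_id: str, seed: int) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    mol3d = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31 - 1)
    if AllChem.EmbedMolecule(mol3d, params) != 0:
        raise FixtureGeometryError(f"embedding failed for {smiles}")
    return MoleculeRecord.from_mol(Chem.RemoveHs(mol3d), mol_id, source="sdf")


def _parking_receptor(n_residues: int = 12) -> ReceptorStructure:
    pattern = ["ALA", "GLY", "ALA", "ALA"]
    return ReceptorStructure(
        [_make_residue(pattern[i % len(pattern)], i) for i in range(n_residues)],
        source="parking",
    )


def _park_ligand(mol: Chem.Mol, receptor: ReceptorStructure) -> None:
    """Translate the ligand centroid to a pocket-like spot above mid-chain."""
    mid = (len(receptor.residues) // 2) * RESIDUE_SPACING
    target = np.array([mid, 4.5, 1.5])
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    shift = target - coords.mean(axis=0)
    for i, c in enumerate(coords + shift):
        conf.SetAtomPosition(i, Point3D(*map(float, c)))


# ---------------------------------------------------------------------------
# Synthetic activity datasets
# ---------------------------------------------------------------------------

def generate_activity_dataset(
    n: int = 300,
    k_informative: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_bits: int = AVALON_BITS,
    class_label: str = "synthetic",
) -> tuple[ActivityDataset, dict]:
    """Synthetic QSAR dataset: activity = linear model on k informative bits.

    Descriptor rows are simulated Avalon-length bit-vectors (bits on with
    probability 0.3); the returned info dict records the ground-truth
    informative indices and weights for recovery tests.  Zero-variance
    informative columns are resampled.
    """
    if n < 50:
        raise ValueError("need n >= 50")
    rng = np.random.default_rng(seed)
    informative = rng.choice(n_bits, size=k_informative, replace=False)
    weights = rng.normal(1.0, 0.5, size=k_informative) * rng.choice([-1, 1], size=k_informative)
    for _ in range(100):
        X = (rng.random((n, n_bits)) < 0.3).astype(np.uint8)
        col_var = X[:, informative].std(axis=0)
        if np.all(col_var > 0):
            break
    else:  # pragma: no cover - p(degenerate) vanishes at n >= 50
        raise RuntimeError("could not sample a non-degenerate feature matrix")
    y = 6.0 + X[:, informative] @ weights + rng.normal(0.0, noise_sd, size=n)
    dataset = ActivityDataset(
        molecule_ids=[f"syn_{i:04d}" for i in range(n)],
        X=X,
        y=y,
        activity_kinds=["Ki"] * n,
        class_label=class_label,
    )
    return dataset, {"informative": informative.tolist(), "weights": weights.tolist()}


# ---------------------------------------------------------------------------
# Decoy sets
# ---------------------------------------------------------------------------

#: Fixed decoy pool spanning > 100 Da of molecular weight.
DECOY_POOL = [
    "CCO",
    "CC(C)=O",
    "OCC(O)CO",
    "c1ccc2ccccc2c1",
    "OCC1OC(O)C(O)C(O)C1O",
    "CN1CCC[C@H]1c1cccnc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Clc1ccc(Cl)c(Cl)c1",
    "NCCc1ccc(O)c(O)c1",
    "CCCCCCCCCCCCCCCC(=O)O",
    "c1ccc(-c2ccccc2)cc1",
    "CC(C)Cc1ccc(C)cc1C(C)C(=O)O",
    "O=C(O)c1ccccc1O",
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",
    "OC1CCCCC1",
    "O=C1CCCCC1",
    "CC(C)(C)c1ccc(O)cc1",
    "C1CCOC1",
    "CC1=CC(=O)CC(C)(C)C1",
    "c1ccsc1",
]


def generate_decoys(
    n_per_target: int,
    target_ligands: dict[str, list[MoleculeRecord]],
    seed: int = 0,
    max_similarity: float = 0.4,
) -> list[tuple[MoleculeRecord, str]]:
    """Draw decoys for each intended target from the fixed pool.

    Each decoy's Morgan Tanimoto to every co-crystal ligand of its intended
    target stays below ``max_similarity``, and each per-target set spans at
    least 100 Da of molecular weight (matching the unbiased-list design of
    decoy benchmarks).  Raises when the pool cannot satisfy the constraints.
    """
    if n_per_target < 1:
        raise ValueError("n_per_target must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[MoleculeRecord, str]] = []
    for target_name in sorted(target_ligands):
        refs = [_MORGAN_GEN.GetFingerprint(r.rdkit_mol) for r in target_ligands[target_name]]
        order = rng.permutation(len(DECOY_POOL))
        chosen: list[str] = []
        for idx in order:
            smiles = DECOY_POOL[idx]
            fp = _MORGAN_GEN.GetFingerprint(Chem.MolFromSmiles(smiles))
            if all(DataStructs.TanimotoSimilarity(fp, ref) < max_similarity for ref in refs):
                chosen.append(smiles)
            if len(chosen) == n_per_target:
                break
        if len(chosen) < n_per_target:
            raise FixtureGeometryError(f"decoy pool exhausted for target {target_name!r}")
        weights = [Descriptors.MolWt(Chem.MolFromSmiles(s)) for s in chosen]
        if n_per_target > 1 and max(weights) - min(weights) < 100.0:
            # deterministically widen the spread with the extreme-MW pool members
            by_mw = sorted(DECOY_POOL, key=lambda s: Descriptors.MolWt(Chem.MolFromSmiles(s)))
            for cand in (by_mw[0], by_mw[-1]):
                fp = _MORGAN_GEN.GetFingerprint(Chem.MolFromSmiles(cand))
                if cand not in chosen and all(
                    DataStructs.TanimotoSimilarity(fp, ref) < max_similarity for ref in refs
                ):
                    chosen[-1] = cand
                    weights = [Descriptors.MolWt(Chem.MolFromSmiles(s)) for s in chosen]
                    if max(weights) - min(weights) >= 100.0:
                        break
            if max(weights) - min(weights) < 100.0:
                raise FixtureGeometryError(
                    f"cannot reach 100 Da weight spread for target {target_name!r}"
                )
        for k, smiles in enumerate(chosen):
            out.append(
                (
                    MoleculeRecord.from_smiles(smiles, f"decoy_{target_name}_{k}".replace(" ", "_")),
                    target_name,
                )
            )
    return out
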