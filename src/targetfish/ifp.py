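"""Structural interaction fingerprints (SIFt-style) and the binding score T_B.

For each receptor residue, eight interaction bits are recorded against a
ligand pose, in this fixed slot order:

    0 hydrophobic            ligand C/S within 4.5 A of a side-chain carbon
    1 aromatic-face          ring centroids <= 4.5 A, interplanar angle <= 30 deg
    2 aromatic-edge          centroids <= 6.0 A, angle in (30, 90] deg
    3 protein-HB-acceptor    protein acceptor <= 3.5 A from a ligand donor
    4 protein-HB-donor       protein donor <= 3.5 A from a ligand acceptor
    5 salt-bridge-positive   protein cation <= 4.0 A from a ligand anion
    6 salt-bridge-negative   protein carboxylate <= 4.0 A from a ligand cation
    7 metal-contact          ligand O/N/S <= 2.8 A from a metal ion

Hydrogen-bond geometry additionally requires a D-H...A angle >= 120 degrees
whenever the donor hydrogen is present; with no explicit hydrogen the check
is distance-only.  These geometric criteria are versioned as scheme "v1";
the binding-similarity score T_B is the Tanimoto coefficient of two
fingerprints built on the same receptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from rdkit import Chem

from .structures import ReceptorStructure, Residue

logger = logging.getLogger(__name__)

INTERACTION_TYPES = (
    "hydrophobic",
    "aromatic-face",
    "aromatic-edge",
    "protein-HB-acceptor",
    "protein-HB-donor",
    "salt-bridge-protein-positive",
    "salt-bridge-protein-negative",
    "metal-contact",
)
N_SLOTS = len(INTERACTION_TYPES)
_TYPE_INDEX = {t: i for i, t in enumerate(INTERACTION_TYPES)}


@dataclass(frozen=True)
class IFPScheme:
    """Geometric criteria for interaction detection (versioned)."""

    version: str = "v1"
    hydrophobic_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    hbond_angle_min: float = 120.0  # degrees, D-H...A
    salt_bridge_cutoff: float = 4.0
    aromatic_face_cutoff: float = 4.5
    aromatic_face_angle_max: float = 30.0
    aromatic_edge_cutoff: float = 6.0
    aromatic_edge_angle_max: float = 90.0
    metal_cutoff: float = 2.8


DEFAULT_SCHEME = IFPScheme()

# Residue interaction templates (atom names per residue type).
_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("ND2",),
    "GLN": ("NE2",), "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",), "HIS": ("ND1", "NE2"),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}
_CATIONIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"), ("CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")),
}


class AtomTypingError(ValueError):
    """A pose atom could not be typed for interaction analysis."""


@dataclass
class InteractionFingerprint:
    """Per-residue interaction bits for one protein-ligand pose."""

    residue_index: list[tuple[str, int, str]]  # (chain, resseq, resname), file order
    bits: np.ndarray  # uint8, length 8 * len(residue_index)
    scheme_version: str = "v1"

    def __post_init__(self):
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.size != N_SLOTS * len(self.residue_index):
            raise ValueError("bit length must be 8 x residue count")

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def set_bit(self, residue_i: int, interaction: str) -> None:
        self.bits[residue_i * N_SLOTS + _TYPE_INDEX[interaction]] = 1

    def get_bit(self, residue_i: int, interaction: str) -> bool:
        return bool(self.bits[residue_i * N_SLOTS + _TYPE_INDEX[interaction]])

    def on_interactions(self) -> set[tuple[tuple[str, int, str], str]]:
        """The set of (residue key, interaction type) pairs that are on."""
        out = set()
        for flat in np.flatnonzero(self.bits):
            res_i, slot = divmod(int(flat), N_SLOTS)
            out.add((self.residue_index[res_i], INTERACTION_TYPES[slot]))
        return out

    def interaction_table(self) -> list[tuple[str, int, str, str]]:
        """Human-readable rows (chain, resseq, resname, interaction)."""
        return [
            (key[0], key[1], key[2], itype) for key, itype in sorted(self.on_interactions())
        ]


@dataclass(frozen=True)
class BindingSimilarity:
    """Tanimoto similarity of two interaction fingerprints (T_B)."""

    value: float
    shared_on_bits: int


@dataclass
class _LigandAtoms:
    """Typed ligand pose atoms extracted from an RDKit molecule + conformer."""

    coords: np.ndarray
    elements: list[str]
    hydrophobic: list[int] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    donors: list[tuple[int, list[np.ndarray]]] = field(default_factory=list)  # (idx, H coords)
    cations: list[int] = field(default_factory=list)
    anions: list[int] = field(default_factory=list)
    metal_binders: list[int] = field(default_factory=list)
    aromatic_rings: list[np.ndarray] = field(default_factory=list)  # (k, 3) ring coords


def _type_ligand(pose: Chem.Mol) -> _LigandAtoms:
    if pose.GetNumConformers() == 0:
        raise AtomTypingError("ligand pose carries no 3D conformer")
    conf = pose.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(pose.GetNumAtoms())]
    )
    lig = _LigandAtoms(coords=coords, elements=[a.GetSymbol() for a in pose.GetAtoms()])
    for atom in pose.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        if not sym:
            raise AtomTypingError(f"atom {idx} has no element symbol")
        if sym == "H":
            continue
        charge = atom.GetFormalCharge()
        if sym in ("C", "S"):
            lig.hydrophobic.append(idx)
        if sym in ("O", "N", "S"):
            lig.metal_binders.append(idx)
        if charge > 0:
            lig.cations.append(idx)
        elif charge < 0:
            lig.anions.append(idx)
        if sym in ("O", "N"):
            n_h = atom.GetTotalNumHs(includeNeighbors=True)
            if n_h > 0:
                h_coords = [
                    coords[nb.GetIdx()] for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"
                ]
                lig.donors.append((idx, h_coords))
            # acceptors: any neutral/anionic O; N without attached H
            if sym == "O" and charge <= 0:
                lig.acceptors.append(idx)
            elif sym == "N" and charge <= 0 and n_h == 0:
                lig.acceptors.append(idx)
    ring_info = pose.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(pose.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            lig.aromatic_rings.append(coords[list(ring)])
    return lig


def _ring_normal(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = ring_coords.mean(axis=0)
    centered = ring_coords - center
    # smallest-variance direction of the ring plane
    _, _, vt = np.linalg.svd(centered)
    return center, vt[2]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_geometry_ok(
    donor: np.ndarray,
    h_coords: list[np.ndarray],
    acceptor: np.ndarray,
    scheme: IFPScheme,
) -> bool:
    if np.linalg.norm(donor - acceptor) > scheme.hbond_cutoff:
        return False
    if not h_coords:
        return True  # distance-only when the donor hydrogen is not modelled
    for h in h_coords:
        angle = _angle_deg(donor - h, acceptor - h)
        if angle >= scheme.hbond_angle_min:
            return True
    return False


def _residue_donor_hydrogens(res: Residue, donor_coord: np.ndarray) -> list[np.ndarray]:
    return [
        a.coord for a in res.atoms
        if a.element == "H" and np.linalg.norm(a.coord - donor_coord) < 1.3
    ]


def extract_ifp(
    receptor: ReceptorStructure,
    pose: Chem.Mol,
    scheme: IFPScheme = DEFAULT_SCHEME,
) -> InteractionFingerprint:
    """Compute the scheme-v1 interaction fingerprint of a ligand pose.

    Deterministic for a fixed pose and scheme; residues with no ligand atom
    within the largest cutoff contribute all-zero slots.
    """
    lig = _type_ligand(pose)
    residue_index = [r.key for r in receptor.residues]
    ifp = InteractionFingerprint(
        residue_index=residue_index,
        bits=np.zeros(N_SLOTS * len(residue_index), dtype=np.uint8),
        scheme_version=scheme.version,
    )
    max_cutoff = max(
        scheme.hydrophobic_cutoff, scheme.hbond_cutoff, scheme.salt_bridge_cutoff,
        scheme.aromatic_edge_cutoff, scheme.metal_cutoff,
    )
    lig_heavy = np.array([i for i, e in enumerate(lig.elements) if e != "H"], dtype=int)
    for res_i, res in enumerate(receptor.residues):
        res_coords = np.array([a.coord for a in res.atoms])
        dmin = np.min(
            np.linalg.norm(res_coords[:, None, :] - lig.coords[lig_heavy][None, :, :], axis=2)
        )
        if dmin > max_cutoff + 1e-9:
            continue

        if res.is_metal:
            metal = res.atoms[0].coord
            for idx in lig.metal_binders:
                if np.linalg.norm(lig.coords[idx] - metal) <= scheme.metal_cutoff:
                    ifp.set_bit(res_i, "metal-contact")
                    break
            continue

        # hydrophobic: side-chain carbons only
        sc_carbons = [a.coord for a in res.side_chain_atoms() if a.element == "C"]
        if sc_carbons and lig.hydrophobic:
            sc = np.array(sc_carbons)
            lh = lig.coords[lig.hydrophobic]
            if np.min(np.linalg.norm(sc[:, None, :] - lh[None, :, :], axis=2)) <= scheme.hydrophobic_cutoff:
                ifp.set_bit(res_i, "hydrophobic")

        # protein as H-bond donor -> ligand acceptor
        donor_atoms = []
        n_backbone = res.get("N")
        if n_backbone is not None and res.resname != "PRO":
            donor_atoms.append(n_backbone)
        for name in _SIDECHAIN_DONORS.get(res.resname, ()):
            atom = res.get(name)
            if atom is not None:
                donor_atoms.append(atom)
        for donor, acc_idx in product(donor_atoms, lig.acceptors):
            h_coords = _residue_donor_hydrogens(res, donor.coord)
            if _hbond_geometry_ok(donor.coord, h_coords, lig.coords[acc_idx], scheme):
                ifp.set_bit(res_i, "protein-HB-donor")
                break

        # protein as H-bond acceptor <- ligand donor
        acceptor_atoms = [a for a in (res.get("O"), res.get("OXT")) if a is not None]
        for name in _SIDECHAIN_ACCEPTORS.get(res.resname, ()):
            atom = res.get(name)
            if atom is not None:
                acceptor_atoms.append(atom)
        for acc, (don_idx, h_coords) in product(acceptor_atoms, lig.donors):
            if _hbond_geometry_ok(lig.coords[don_idx], h_coords, acc.coord, scheme):
                ifp.set_bit(res_i, "protein-HB-acceptor")
                break

        # salt bridges
        for name in _CATIONIC_ATOMS.get(res.resname, ()):
            atom = res.get(name)
            if atom is None:
                continue
            if any(
                np.linalg.norm(lig.coords[i] - atom.coord) <= scheme.salt_bridge_cutoff
                for i in lig.anions
            ):
                ifp.set_bit(res_i, "salt-bridge-protein-positive")
                break
        for name in _ANIONIC_ATOMS.get(res.resname, ()):
            atom = res.get(name)
            if atom is None:
                continue
            if any(
                np.linalg.norm(lig.coords[i] - atom.coord) <= scheme.salt_bridge_cutoff
                for i in lig.cations
            ):
                ifp.set_bit(res_i, "salt-bridge-protein-negative")
                break

        # aromatic stacking
        for ring_names in _AROMATIC_RINGS.get(res.resname, ()):
            atoms = [res.get(n) for n in ring_names]
            if any(a is None for a in atoms):
                continue
            p_center, p_normal = _ring_normal(np.array([a.coord for a in atoms]))
            for lring in lig.aromatic_rings:
                l_center, l_normal = _ring_normal(lring)
                dist = np.linalg.norm(p_center - l_center)
                angle = _angle_deg(p_normal, l_normal)
                angle = min(angle, 180.0 - angle)  # plane angle, not normal orientation
                if dist <= scheme.aromatic_face_cutoff and angle <= scheme.aromatic_face_angle_max:
                    ifp.set_bit(res_i, "aromatic-face")
                elif dist <= scheme.aromatic_edge_cutoff and scheme.aromatic_face_angle_max < angle <= scheme.aromatic_edge_angle_max:
                    ifp.set_bit(res_i, "aromatic-edge")
    return ifp


def align_and_compare(
    query: InteractionFingerprint, reference: InteractionFingerprint
) -> BindingSimilarity:
    """Binding similarity T_B: Tanimoto of two same-receptor fingerprints.

    Fingerprints from different receptors (mismatched residue indices) are
    never comparable; two all-empty fingerprints score 0.0 with a warning.
    """
    if query.residue_index != reference.residue_index:
        raise ValueError("interaction fingerprints built on different receptors")
    n_q = query.n_on
    n_r = reference.n_on
    shared = int(np.count_nonzero(query.bits & reference.bits))
    if n_q == 0 and n_r == 0:
        logger.warning("both interaction fingerprints empty; T_B defined as 0.0")
        return BindingSimilarity(value=0.0, shared_on_bits=0)
    return BindingSimilarity(value=shared / (n_q + n_r - shared), shared_on_bits=shared)
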