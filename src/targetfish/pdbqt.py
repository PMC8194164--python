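"""Minimal AutoDock PDBQT ligand writing and Vina-style pose parsing.

The writer emits a deliberately simplified PDBQT dialect: Gasteiger partial
charges, AutoDock-style atom types, nonpolar hydrogens merged onto their
carbons, a single rigid ROOT block, and rotatable bonds declared through
``REMARK`` annotations plus the ``TORSDOF`` record.  This is sufficient for
the Vina text contract (PDBQT in, multi-model PDBQT out with
``REMARK VINA RESULT`` energies) that the docking adapter speaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Lipinski


def _autodock_type(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if sym == "C":
        return "A" if atom.GetIsAromatic() else "C"
    if sym == "N":
        # acceptor nitrogens (no attached H) are NA in AutoDock typing
        return "N" if atom.GetTotalNumHs() > 0 else "NA"
    if sym == "O":
        return "OA"
    if sym == "S":
        return "SA"
    if sym == "H":
        return "HD"  # only polar hydrogens survive merging
    return sym.upper()


def write_ligand_pdbqt(mol: Chem.Mol, path: str | Path) -> Chem.Mol:
    """Write a 3D ligand to PDBQT; returns the polar-H merged molecule.

    Hydrogens bonded to carbon are merged (their Gasteiger charge added to
    the carbon); hydrogens on N/O/S are retained as HD atoms.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("ligand has no 3D coordinates")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("ligand has no heavy atoms")
    work = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(work)
    charges = {a.GetIdx(): float(a.GetProp("_GasteigerCharge")) for a in work.GetAtoms()}
    # fold nonpolar-H charge onto the parent carbon, then drop those H
    drop: set[int] = set()
    for atom in work.GetAtoms():
        if atom.GetSymbol() != "H":
            continue
        neighbor = atom.GetNeighbors()[0]
        if neighbor.GetSymbol() == "C":
            charges[neighbor.GetIdx()] += charges[atom.GetIdx()]
            drop.add(atom.GetIdx())

    n_torsions = len(mol.GetSubstructMatches(Lipinski.RotatableBondSmarts))
    conf = work.GetConformer()
    lines = [f"REMARK  {n_torsions} active torsions:"]
    for i, (a, b) in enumerate(mol.GetSubstructMatches(Lipinski.RotatableBondSmarts), start=1):
        lines.append(f"REMARK  {i}  A    between atoms: {a + 1}  and  {b + 1}")
    lines.append("ROOT")
    serial = 0
    for atom in work.GetAtoms():
        if atom.GetIdx() in drop:
            continue
        serial += 1
        pos = conf.GetAtomPosition(atom.GetIdx())
        name = f"{atom.GetSymbol()}{serial}"[:4]
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} LIG A   1    "
            f"{pos.x:8.3f}{pos.y:8.3f}{pos.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"    {charges[atom.GetIdx()]:6.3f} {_autodock_type(atom):<2s}"
        )
    lines.append("ENDROOT")
    lines.append(f"TORSDOF {n_torsions}")
    Path(path).write_text("\n".join(lines) + "\n")
    out = Chem.RWMol(work)
    for idx in sorted(drop, reverse=True):
        out.RemoveAtom(idx)
    return out.GetMol()


@dataclass(frozen=True)
class VinaPose:
    """One docked pose parsed from Vina multi-model PDBQT output."""

    energy: float  # kcal/mol
    coords: np.ndarray  # (n_atoms, 3)
    atom_types: tuple[str, ...]


def parse_vina_poses(text: str) -> list[VinaPose]:
    """Parse multi-model PDBQT text with ``REMARK VINA RESULT`` energies."""
    poses: list[VinaPose] = []
    energy: float | None = None
    coords: list[list[float]] = []
    types: list[str] = []
    for line in text.splitlines():
        if line.startswith("MODEL"):
            energy, coords, types = None, [], []
        elif line.startswith("REMARK VINA RESULT:"):
            energy = float(line.split()[3])
        elif line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            types.append(line[77:79].strip() if len(line) > 77 else "")
        elif line.startswith("ENDMDL"):
            if energy is None:
                raise ValueError("pose model without REMARK VINA RESULT energy")
            poses.append(VinaPose(energy, np.array(coords, dtype=float), tuple(types)))
    return poses
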