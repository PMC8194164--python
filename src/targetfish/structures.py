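"""Lightweight protein structure handling for interaction analysis.

Receptors are parsed with Biopython and held as an ordered list of residues
(file order), which fixes the slot ordering of interaction fingerprints.
Writing uses fixed-column PDB v3.3 records so outputs are byte-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Metal cofactors kept during receptor preparation: catalytically essential
#: in classes such as carbonic anhydrase (ZN) even though they are HETATM.
ALLOWED_METALS = {"ZN", "MG", "MN", "CA", "FE"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) float64, Angstrom

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    chain: str
    resseq: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def get(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.resname)

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_metal(self) -> bool:
        return self.resname in ALLOWED_METALS and len(self.atoms) == 1


@dataclass
class ReceptorStructure:
    """Ordered residues of one receptor; order fixes IFP slot layout."""

    residues: list[Residue]
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ReceptorStructure":
        """Rigid-body copy: ``x -> R x + t`` applied to every atom."""
        out = []
        for res in self.residues:
            atoms = [Atom(a.name, a.element, rotation @ a.coord + translation) for a in res.atoms]
            out.append(Residue(res.chain, res.resseq, res.resname, atoms, res.hetero))
        return ReceptorStructure(out, source=self.source)


def _guess_element(atom_name: str, bp_element: str) -> str:
    elem = (bp_element or "").strip().upper()
    if elem:
        return elem.capitalize() if len(elem) > 1 else elem
    name = atom_name.strip()
    # two-letter metal names fill columns 13-14
    if name[:2] in {"ZN", "MG", "MN", "FE", "CL", "NA", "BR"}:
        return name[:2].capitalize()
    return name.lstrip("0123456789")[0].upper()


def parse_receptor(path: str | Path) -> ReceptorStructure:
    """Parse a PDB (or receptor-style PDBQT) file into ordered residues."""
    path = Path(path)
    if path.suffix.lower() == ".pdbqt":
        return _parse_pdb_like(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    residues: list[Residue] = []
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            hetflag = res.id[0].strip()
            residue = Residue(
                chain=chain.id,
                resseq=res.id[1],
                resname=res.get_resname().strip(),
                hetero=bool(hetflag),
            )
            for atom in res:
                residue.atoms.append(
                    Atom(
                        name=atom.get_name().strip(),
                        element=_guess_element(atom.get_name(), atom.element),
                        coord=np.array(atom.get_coord(), dtype=float),
                    )
                )
            residues.append(residue)
    return ReceptorStructure(residues, source=str(path))


def _parse_pdb_like(path: Path) -> ReceptorStructure:
    """Column-based fallback for PDBQT receptors (Biopython rejects the footer)."""
    residues: list[Residue] = []
    current_key = None
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        resname = line[17:20].strip()
        key = (chain, resseq, resname)
        if key != current_key:
            residues.append(Residue(chain, resseq, resname, hetero=line.startswith("HETATM")))
            current_key = key
        name = line[12:16].strip()
        elem = line[76:78].strip() if len(line) >= 78 else ""
        coord = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        residues[-1].atoms.append(Atom(name, _guess_element(name, elem), coord))
    return ReceptorStructure(residues, source=str(path))


def format_pdb_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    coord: np.ndarray,
    element: str,
    hetero: bool = False,
) -> str:
    """One fixed-column PDB v3.3 ATOM/HETATM record."""
    record = "HETATM" if hetero else "ATOM  "
    # atom-name column convention: 1-2 char element names start in column 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record}{serial:5d} {name_field} {resname:>3s} {chain}{resseq:4d}    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element.upper():>2s}"
    )


def write_receptor_pdb(structure: ReceptorStructure, path: str | Path) -> None:
    lines: list[str] = []
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            lines.append(
                format_pdb_atom(
                    serial, atom.name, res.resname, res.chain, res.resseq,
                    atom.coord, atom.element, hetero=res.hetero,
                )
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def add_backbone_amide_hydrogens(structure: ReceptorStructure) -> int:
    """Place amide hydrogens geometrically on backbone nitrogens lacking one.

    The H is set 1.01 A from N along the direction opposite the bisector of
    the N->CA and N->C(previous residue) bonds — the ideal planar amide
    geometry.  Residues that already carry any hydrogen are left untouched;
    prolines and chain-starting residues are skipped.  Returns the number of
    hydrogens added.
    """
    n_added = 0
    aa_residues = [r for r in structure.residues if r.resname in STANDARD_AMINO_ACIDS]
    for i, res in enumerate(aa_residues):
        if res.resname == "PRO":
            continue
        if any(a.element == "H" for a in res.atoms):
            continue
        n = res.get("N")
        ca = res.get("CA")
        if n is None or ca is None or i == 0:
            continue
        prev = aa_residues[i - 1]
        if prev.chain != res.chain:
            continue
        c_prev = prev.get("C")
        if c_prev is None:
            continue
        u1 = ca.coord - n.coord
        u2 = c_prev.coord - n.coord
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        direction = -(u1 + u2)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            continue
        res.atoms.append(Atom("H", "H", n.coord + 1.01 * direction / norm))
        n_added += 1
    return n_added


def centroid(coords: Iterable[np.ndarray]) -> np.ndarray:
    arr = np.asarray(list(coords), dtype=float)
    return arr.mean(axis=0)
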