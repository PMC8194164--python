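"""Pluggable docking-engine interface with a deterministic mock engine.

Any Vina-family binary that speaks the AutoDock Vina text contract (PDBQT
receptor/ligand in, multi-model PDBQT out with ``REMARK VINA RESULT``
energies) can back the pipeline.  The mock engine performs rigid placement
of the query conformer at the box center — and returns the co-crystal pose
verbatim when the query *is* the co-crystal ligand — which makes the whole
workflow deterministic and testable without external binaries.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from rdkit import Chem

from .library import TargetEntry, prepare_ligand
from .pdbqt import parse_vina_poses
from .structures import centroid


class DockingError(RuntimeError):
    """Engine crash, timeout, or insane pose geometry."""

    def __init__(self, message: str, stderr: str = ""):
        self.stderr = stderr
        super().__init__(message)


@dataclass(frozen=True)
class DockingBox:
    """Axis-aligned search box (Angstrom)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("box extents must be positive")


@dataclass
class DockingResult:
    """Lowest-energy pose returned by an engine run."""

    pose: Chem.Mol  # query molecule with the docked conformer
    energy: float  # kcal/mol
    engine: str
    exhaustiveness: int
    seed: int


def default_box(entry: TargetEntry, padding: float = 8.0) -> DockingBox:
    """Search box around the co-crystal ligand: centroid-centered bounding
    box grown by ``padding`` on each side (community-default 8 A)."""
    mol = entry.cocrystal_ligand.mol
    if mol is None or mol.GetNumConformers() == 0:
        raise ValueError(f"{entry.pdb_id}: co-crystal ligand has no coordinates")
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
                       for i in range(mol.GetNumAtoms())])
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    center = (lo + hi) / 2
    size = (hi - lo) + 2 * padding
    return DockingBox(center=tuple(float(c) for c in center), size=tuple(float(s) for s in size))


class DockingEngine(Protocol):
    name: str

    def run(
        self, ligand: Chem.Mol, entry: TargetEntry, box: DockingBox,
        seed: int, exhaustiveness: int,
    ) -> Sequence[tuple[Chem.Mol, float]]:
        """Return candidate (pose, energy) pairs; pose is a conformer-bearing mol."""
        ...


def _set_coords(mol: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    out = Chem.Mol(mol)
    conf = out.GetConformer()
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    return out


class MockEngine:
    """Deterministic stand-in engine.

    If the query's canonical SMILES equals the entry's co-crystal ligand, the
    co-crystal pose is returned verbatim (so self-docking reproduces the
    reference binding mode exactly); otherwise the query conformer is rigidly
    translated to the box center.  The reported energy is a deterministic
    function of heavy-atom count, not a physical estimate.
    """

    name = "mock"

    def run(self, ligand, entry, box, seed, exhaustiveness):
        if entry.cocrystal_ligand.mol is not None and (
            Chem.MolToSmiles(Chem.RemoveHs(ligand)) == entry.cocrystal_ligand.smiles
        ):
            pose = Chem.Mol(entry.cocrystal_ligand.mol)
            energy = -7.0
            return [(pose, energy)]
        if ligand.GetNumConformers() == 0:
            raise DockingError("ligand has no conformer for rigid placement")
        conf = ligand.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z] for i in range(ligand.GetNumAtoms())])
        shift = np.asarray(box.center) - centroid(coords)
        pose = _set_coords(ligand, coords + shift)
        energy = -4.0 - 0.1 * ligand.GetNumHeavyAtoms()
        return [(pose, energy)]


class PlantedPoseEngine:
    """Test engine returning pre-planted (coords, energy) pose lists per entry."""

    name = "planted"

    def __init__(self, poses_by_pdb_id: dict[str, list[tuple[np.ndarray, float]]]):
        self.poses_by_pdb_id = poses_by_pdb_id

    def run(self, ligand, entry, box, seed, exhaustiveness):
        planted = self.poses_by_pdb_id.get(entry.pdb_id)
        if not planted:
            raise DockingError(f"no planted poses for {entry.pdb_id}")
        return [(_set_coords(ligand, coords), energy) for coords, energy in planted]


class VinaEngine:
    """External Vina-compatible binary behind the standard text contract."""

    def __init__(self, binary: str, timeout: float = 600.0):
        self.binary = binary
        self.timeout = timeout
        self.name = f"vina:{binary}"

    def run(self, ligand, entry, box, seed, exhaustiveness):
        from .chem import MoleculeRecord

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            ligand_pdbqt = tmp / "ligand.pdbqt"
            record = MoleculeRecord.from_mol(ligand, "query", source="smiles")
            merged = prepare_ligand(record, ligand_pdbqt, fmt="pdbqt")
            out_pdbqt = tmp / "out.pdbqt"
            cmd = [
                self.binary,
                "--receptor", str(entry.receptor_path),
                "--ligand", str(ligand_pdbqt),
                "--out", str(out_pdbqt),
                "--center_x", str(box.center[0]), "--center_y", str(box.center[1]),
                "--center_z", str(box.center[2]),
                "--size_x", str(box.size[0]), "--size_y", str(box.size[1]),
                "--size_z", str(box.size[2]),
                "--seed", str(seed), "--exhaustiveness", str(exhaustiveness),
            ]
            try:
                proc = subprocess.run(cmd, capture_output=True, text=True, timeout=self.timeout)
            except subprocess.TimeoutExpired as exc:
                raise DockingError(f"{self.binary} timed out", stderr=str(exc)) from exc
            if proc.returncode != 0:
                raise DockingError(f"{self.binary} exited {proc.returncode}", stderr=proc.stderr)
            poses = parse_vina_poses(out_pdbqt.read_text())
            if not poses:
                raise DockingError("engine produced no poses", stderr=proc.stderr)
            # pose atoms follow the merged (polar-H) ligand written above
            return [(_set_coords(Chem.Mol(merged), p.coords), p.energy) for p in poses]


def dock(
    ligand: Chem.Mol,
    entry: TargetEntry,
    box: DockingBox,
    engine: DockingEngine,
    seed: int = 42,
    exhaustiveness: int = 8,
) -> DockingResult:
    """Dock a ligand and return the lowest-energy pose.

    Selection is an exact minimum over the engine's pose list; a pose whose
    centroid strays further from the box center than the box size on any
    axis fails a sanity check.
    """
    poses = engine.run(ligand, entry, box, seed=seed, exhaustiveness=exhaustiveness)
    if not poses:
        raise DockingError(f"{engine.name}: empty pose list for {entry.pdb_id}")
    best_pose, best_energy = min(poses, key=lambda pe: pe[1])
    if not np.isfinite(best_energy):
        raise DockingError(f"{engine.name}: non-finite energy for {entry.pdb_id}")
    conf = best_pose.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(best_pose.GetNumAtoms())])
    offset = np.abs(centroid(coords) - np.asarray(box.center))
    if np.any(offset > np.asarray(box.size)):
        raise DockingError(
            f"{engine.name}: pose centroid {offset} outside box for {entry.pdb_id}"
        )
    return DockingResult(
        pose=best_pose, energy=float(best_energy), engine=engine.name,
        exhaustiveness=exhaustiveness, seed=seed,
    )
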