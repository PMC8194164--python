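"""Five-step target identification workflow.

1. Shortlist library targets whose co-crystal ligand similarity T_L (mean
   fingerprint Tanimoto over the chosen preset) reaches the cutoff (0.4).
2. Dock the query into each shortlisted receptor; keep the lowest-energy pose.
3. Extract the pose's interaction fingerprint and score it against the
   co-crystal reference to get the binding similarity T_B.
4. Predict binding activity with the target class's random-forest model.
5. Rank all candidates by the combined score 0.7*T_L + 0.3*T_B.

Class-specific (CS) mode restricts candidates to one target class before
ranking; the MM preset is recommended there, MMD for all-class runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .activity import MissingModelError, TrainedActivityModel, predict_activity
from .chem import (
    PRESETS,
    FingerprintAlgorithm,
    FingerprintSet,
    MoleculeRecord,
    compute_fingerprints,
    ligand_similarity,
)
from .docking import DockingEngine, DockingError, default_box, dock
from .ifp import align_and_compare, extract_ifp
from .library import TargetEntry, TargetLibrary

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "query_id", "rank", "target_name", "pdb_id", "target_class",
    "ligand_similarity", "binding_similarity", "combined_score",
    "docking_energy_kcal_mol", "predicted_activity_neglogM", "status",
]


@dataclass(frozen=True)
class PredictionOptions:
    """Knobs of the prediction workflow (defaults are the published ones)."""

    fp_preset: str = "MMD"
    algorithms: tuple[FingerprintAlgorithm, ...] | None = None  # overrides preset
    cutoff: float = 0.4
    class_filter: str | None = None
    weights: tuple[float, float] = (0.7, 0.3)
    top_n_report: int = 10
    docking_padding: float = 8.0
    docking_seed: int = 42
    exhaustiveness: int = 8

    def __post_init__(self):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must be in [0, 1]")
        w_l, w_b = self.weights
        if w_l < 0 or w_b < 0 or abs(w_l + w_b - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.algorithms is None and self.fp_preset not in PRESETS and self.fp_preset != "custom":
            raise ValueError(f"unknown preset {self.fp_preset!r}")

    @property
    def similarity_algorithms(self) -> tuple[FingerprintAlgorithm, ...]:
        if self.algorithms is not None:
            return tuple(FingerprintAlgorithm(a) for a in self.algorithms)
        return PRESETS[self.fp_preset]


@dataclass
class PredictionRecord:
    """One ranked candidate target for one query."""

    target_name: str
    pdb_id: str
    target_class: str
    t_ligand: float
    t_binding: float
    combined: float
    docking_energy: float | None
    predicted_activity: float | None
    rank: int | None
    status: str = "ok"  # ok | dock_failed


def require_model(
    models: dict[str, TrainedActivityModel], class_label: str
) -> TrainedActivityModel:
    """The trained model for a class, or a typed MissingModelError."""
    if class_label not in models:
        raise MissingModelError(class_label)
    return models[class_label]


def combined_score(t_l: float, t_b: float, weights: tuple[float, float] = (0.7, 0.3)) -> float:
    """Weighted combined score w_L*T_L + w_B*T_B (published weights 0.7/0.3)."""
    if not (0.0 <= t_l <= 1.0 and 0.0 <= t_b <= 1.0):
        raise ValueError(f"similarity scores must be in [0, 1]; got T_L={t_l}, T_B={t_b}")
    w_l, w_b = weights
    return w_l * t_l + w_b * t_b


def shortlist_targets(
    query_fps: FingerprintSet, library: TargetLibrary, opts: PredictionOptions
) -> list[tuple[TargetEntry, float]]:
    """Entries whose T_L reaches the cutoff, optionally restricted to a class.

    An empty shortlist is a valid outcome.
    """
    algos = opts.similarity_algorithms
    out: list[tuple[TargetEntry, float]] = []
    for entry in library.entries:
        if opts.class_filter is not None and entry.target_class != opts.class_filter:
            continue
        score = ligand_similarity(query_fps, entry.cocrystal_fps, algos)
        if score.value >= opts.cutoff:
            out.append((entry, score.value))
    return out


def _ensure_conformer(record: MoleculeRecord, seed: int) -> Chem.Mol:
    """Query molecule with a 3D conformer (ETKDG-embedded when absent)."""
    mol = record.mol if record.mol is not None else Chem.MolFromSmiles(record.smiles)
    if mol.GetNumConformers() > 0:
        return mol
    mol3d = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol3d, params) != 0:
        raise ValueError(f"{record.id}: conformer embedding failed")
    return Chem.RemoveHs(mol3d)


def rank_records(records: list[PredictionRecord]) -> list[PredictionRecord]:
    """Assign ranks 1..n to "ok" records by (combined desc, T_L desc, pdb_id asc).

    Failed records keep rank None and sort to the end.
    """
    ok = [r for r in records if r.status == "ok"]
    failed = [r for r in records if r.status != "ok"]
    ok.sort(key=lambda r: (-r.combined, -r.t_ligand, r.pdb_id))
    for i, rec in enumerate(ok, start=1):
        rec.rank = i
    return ok + failed


def predict_targets(
    query: MoleculeRecord,
    library: TargetLibrary,
    opts: PredictionOptions,
    engine: DockingEngine,
    activity_models: dict[str, TrainedActivityModel] | None = None,
) -> list[PredictionRecord]:
    """Run the full workflow for one query molecule.

    Docking failures are isolated: the affected entry is reported with
    status ``dock_failed`` and excluded from ranking.  A missing class
    activity model degrades to a null predicted activity with a warning.
    """
    activity_models = activity_models or {}
    query_fps = compute_fingerprints(query, opts.similarity_algorithms)
    shortlist = shortlist_targets(query_fps, library, opts)
    if not shortlist:
        logger.info("query %s: empty shortlist at cutoff %.2f", query.id, opts.cutoff)
        return []
    query3d = _ensure_conformer(query, opts.docking_seed)
    records: list[PredictionRecord] = []
    for entry, t_l in shortlist:
        try:
            box = default_box(entry, opts.docking_padding)
            result = dock(
                query3d, entry, box, engine,
                seed=opts.docking_seed, exhaustiveness=opts.exhaustiveness,
            )
            pose_ifp = extract_ifp(entry.receptor_structure(), result.pose)
            t_b = align_and_compare(pose_ifp, entry.reference_ifp).value
        except DockingError as exc:
            logger.warning("query %s vs %s: docking failed (%s)", query.id, entry.pdb_id, exc)
            records.append(
                PredictionRecord(
                    target_name=entry.target_name, pdb_id=entry.pdb_id,
                    target_class=entry.target_class, t_ligand=t_l, t_binding=0.0,
                    combined=0.0, docking_energy=None, predicted_activity=None,
                    rank=None, status="dock_failed",
                )
            )
            continue
        try:
            model = require_model(activity_models, entry.target_class)
            predicted = predict_activity(model, query)
        except MissingModelError:
            if activity_models:
                logger.warning("no activity model for class %s; null activity", entry.target_class)
            predicted = None
        records.append(
            PredictionRecord(
                target_name=entry.target_name, pdb_id=entry.pdb_id,
                target_class=entry.target_class, t_ligand=t_l, t_binding=t_b,
                combined=combined_score(t_l, t_b, opts.weights),
                docking_energy=result.energy, predicted_activity=predicted,
                rank=None, status="ok",
            )
        )
    return rank_records(records)


def predict_batch(
    queries: list[MoleculeRecord],
    library: TargetLibrary,
    opts: PredictionOptions,
    engine: DockingEngine,
    activity_models: dict[str, TrainedActivityModel] | None = None,
) -> dict[str, list[PredictionRecord] | Exception]:
    """Independent per-query predictions; failures isolated per query."""
    if not queries:
        raise ValueError("empty query batch")
    results: dict[str, list[PredictionRecord] | Exception] = {}
    for query in queries:
        try:
            results[query.id] = predict_targets(query, library, opts, engine, activity_models)
        except Exception as exc:  # per-query isolation by contract
            logger.warning("query %s failed: %s", query.id, exc)
            results[query.id] = exc
    return results


def results_to_frame(results: dict[str, list[PredictionRecord]]) -> pd.DataFrame:
    """Flatten batch results into the documented CSV column layout."""
    rows = []
    for query_id, records in results.items():
        if isinstance(records, Exception):
            rows.append(dict.fromkeys(RESULT_COLUMNS) | {"query_id": query_id, "status": "error"})
            continue
        for rec in records:
            rows.append(
                {
                    "query_id": query_id, "rank": rec.rank, "target_name": rec.target_name,
                    "pdb_id": rec.pdb_id, "target_class": rec.target_class,
                    "ligand_similarity": rec.t_ligand, "binding_similarity": rec.t_binding,
                    "combined_score": rec.combined,
                    "docking_energy_kcal_mol": rec.docking_energy,
                    "predicted_activity_neglogM": rec.predicted_activity,
                    "status": rec.status,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
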