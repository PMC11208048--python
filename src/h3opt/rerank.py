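"""Energy-based re-ranking of loop-model ensembles and Boltzmann analytics.

Per-model energies (kcal/mol) enter as plain numeric columns — this module
never computes them. It covers: the Delta-RMSD bookkeeping of re-ranking
experiments (Delta = RMSD of the default top-ranked model minus RMSD of the
re-ranked selection, positive = improvement), ascending-energy re-ranking,
improvement summaries over benchmark tables, Boltzmann conformer weights
w_i ~ exp(-(E_i - E_min)/kT), and weighted ensemble-average structures.

Reference benchmark tables (QM re-ranking / optimization and MD-based loop
optimization experiments, plus an MM/GBSA-MM/PBSA binding-affinity
comparison) ship as TSVs under ``h3opt/data`` and load via
:func:`load_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BOLTZMANN_K = 0.0019872  # kcal/mol/K
HARTREE_TO_KCAL = 627.509

BUNDLED_TABLES = (
    "qm_rerank_same_cdrh3",
    "qm_rerank_methods",
    "qm_optimization_methods",
    "md_optimization_worst10",
    "binding_affinity_comparison",
)


def load_table(name: str) -> pd.DataFrame:
    """Load one bundled benchmark table by short name."""
    if name not in BUNDLED_TABLES:
        raise KeyError(f"unknown table {name!r}; available: {BUNDLED_TABLES}")
    ref = importlib.resources.files("h3opt.data") / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@dataclass
class ModelEntry:
    model_id: str
    rmsd: float | None = None  # Angstrom, vs native (optional)
    energy: float | None = None  # kcal/mol (optional)


@dataclass
class EnsembleRecord:
    target_id: str
    models: list[ModelEntry]
    ranked0_id: str

    def __post_init__(self):
        ids = [m.model_id for m in self.models]
        if self.ranked0_id not in ids:
            raise ValueError(f"ranked0_id {self.ranked0_id!r} not among models {ids}")
        has_e = [m.energy is not None for m in self.models]
        if any(has_e) and not all(has_e):
            raise ValueError("energies must be all-present or all-absent")

    def model(self, model_id: str) -> ModelEntry:
        return next(m for m in self.models if m.model_id == model_id)


def delta_rmsd(ranked0_rmsd: float, candidate_rmsd: float) -> float:
    """RMSD improvement of a candidate over the default top-ranked model."""
    if ranked0_rmsd < 0 or candidate_rmsd < 0:
        raise ValueError("RMSDs must be >= 0")
    return ranked0_rmsd - candidate_rmsd


def rerank_by_energy(rec: EnsembleRecord) -> tuple[list[ModelEntry], ModelEntry]:
    """Ascending-energy ordering; ties broken by model_id lexicographically."""
    if any(m.energy is None for m in rec.models):
        raise ValueError(f"target {rec.target_id}: missing energies; cannot re-rank")
    ordered = sorted(rec.models, key=lambda m: (m.energy, m.model_id))
    return ordered, ordered[0]


@dataclass
class ImprovementSummary:
    n_improved: int
    n_total: int
    mean_improvement_over_improved: float | None  # Angstrom; None if none improved

    def as_dict(self) -> dict:
        return {
            "n_improved": self.n_improved,
            "n_total": self.n_total,
            "mean_improvement_over_improved": self.mean_improvement_over_improved,
        }


def improvement_summary(
    pairs: list[tuple[float, float]],
) -> ImprovementSummary:
    """Summarise (ranked0_rmsd, selected_rmsd) pairs.

    A target counts as improved only for a strictly positive Delta-RMSD;
    the mean improvement averages over improved targets only.
    """
    if not pairs:
        raise ValueError("no records to summarise")
    deltas = [delta_rmsd(r0, sel) for r0, sel in pairs]
    improved = [d for d in deltas if d > 0]
    return ImprovementSummary(
        n_improved=len(improved),
        n_total=len(deltas),
        mean_improvement_over_improved=(
            float(np.mean(improved)) if improved else None
        ),
    )


def summary_from_table(df: pd.DataFrame) -> ImprovementSummary:
    """Improvement summary of a table with ranked0/lowest-energy RMSD columns."""
    return improvement_summary(
        list(zip(df["ranked0_rmsd"].astype(float), df["lowest_energy_rmsd"].astype(float)))
    )


def boltzmann_weights(
    energies, temperature: float = 298.15, unit: str = "kcal/mol"
) -> np.ndarray:
    """Normalised conformer proportions exp(-(E - E_min)/kT).

    ``unit`` may be 'kcal/mol' or 'hartree' (converted by 627.509).
    """
    e = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if unit == "hartree":
        e = e * HARTREE_TO_KCAL
    elif unit != "kcal/mol":
        raise ValueError(f"unknown energy unit {unit!r}")
    kt = BOLTZMANN_K * temperature
    w = np.exp(-(e - e.min()) / kt)
    return w / w.sum()


def boltzmann_average_coords(coord_sets, weights) -> np.ndarray:
    """Per-atom convex combination of matched coordinate sets."""
    coords = [np.asarray(c, dtype=float) for c in coord_sets]
    w = np.asarray(weights, dtype=float)
    if len(coords) != len(w):
        raise ValueError("one weight per model required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    shape = coords[0].shape
    if any(c.shape != shape for c in coords):
        raise ValueError("coordinate sets must share atom correspondence")
    return np.tensordot(w, np.stack(coords), axes=1)


def boltzmann_average_structure(models, weights, ann=None, minimize: bool = False):
    """Weighted average of matched structures; optional idealization pass.

    ``models`` are :class:`AntibodyStructure` objects with identical chain
    and atom layouts. With ``minimize=True`` (requires ``ann``) the averaged
    loop is passed through the geometric idealizer.
    """
    from .refine import idealize_loop

    base = models[0].copy()
    flat_sets = []
    for m in models:
        flat = []
        for cid in base.chains:
            for r in m.chain(cid):
                flat.extend(a.coord for a in r.atoms)
        flat_sets.append(np.array(flat))
    avg = boltzmann_average_coords(flat_sets, weights)
    i = 0
    for cid in base.chains:
        for r in base.chain(cid):
            for a in r.atoms:
                a.coord = avg[i].copy()
                i += 1
    if minimize:
        if ann is None:
            raise ValueError("minimize=True requires an H3 annotation")
        base, _ = idealize_loop(base, ann)
    return base


def column_stats(df: pd.DataFrame, column: str, precision: int | None = None) -> float:
    """Arithmetic mean of a numeric column; optional printed-precision rounding."""
    col = pd.to_numeric(df[column], errors="raise").dropna()
    if col.empty:
        raise ValueError(f"column {column!r} has no numeric values")
    mean = float(col.mean())
    return round(mean, precision) if precision is not None else mean
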