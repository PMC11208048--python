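"""Structure-similarity metrics: RMSD variants, TM-score, GDT, Z-scores.

Loop RMSDs are computed *after* a framework superposition (either all-Fv
backbone heavy atoms or the V_H backbone excluding the H3 span) with no
refitting on the loop itself. TM-score and GDT use documented superposition
search heuristics (seeded window fits plus inlier-refinement rounds); the
fixed-frame variants are also exposed.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, kabsch, rmsd
from .structures import AntibodyStructure, H3Annotation, StructureError

BACKBONE_ATOMS = ("N", "CA", "C", "O")
GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)


class SuperpositionMode(str, enum.Enum):
    FV_BACKBONE = "fv_backbone"
    VH_BACKBONE_NO_H3 = "vh_backbone_no_h3"


@dataclass
class MetricReport:
    rmsd_ca: float
    rmsd_backbone: float
    rmsd_heavy: float
    rmsd_sidechain: float
    tm_score: float
    gdt_ts: float
    gdt_ha: float
    superposition_mode: str
    z_ave: float | None = None

    def to_json(self) -> str:
        def clean(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        return json.dumps({k: clean(v) for k, v in self.__dict__.items()})


# ---------------------------------------------------------------------------
# superposition


def _selection_coords(
    s: AntibodyStructure,
    mode: SuperpositionMode,
    ann: H3Annotation | None,
    chain_ids: list[str],
) -> np.ndarray:
    pts = []
    for cid in chain_ids:
        for r in s.chain(cid):
            if (
                mode is SuperpositionMode.VH_BACKBONE_NO_H3
                and ann is not None
                and cid == ann.chain_id
                and ann.start_index <= r.seq_index <= ann.end_index
            ):
                continue
            for name in BACKBONE_ATOMS:
                a = r.atom(name)
                if a is not None:
                    pts.append(a.coord)
    return np.array(pts)


def superpose(
    mobile: AntibodyStructure,
    target: AntibodyStructure,
    mode: SuperpositionMode = SuperpositionMode.VH_BACKBONE_NO_H3,
    ann: H3Annotation | None = None,
) -> tuple[RigidTransform, float]:
    """Kabsch fit of ``mobile`` onto ``target`` over the mode's selection.

    FV_BACKBONE fits all backbone heavy atoms of every common chain;
    VH_BACKBONE_NO_H3 fits the annotated chain's backbone excluding the H3
    span. Selections must match atom-for-atom (equal chain lengths and atom
    completements); mismatches raise.
    """
    chain_ids = [c for c in mobile.chains if c in target.chains]
    if mode is SuperpositionMode.VH_BACKBONE_NO_H3:
        if ann is None:
            raise StructureError("VH_BACKBONE_NO_H3 requires an H3 annotation")
        chain_ids = [ann.chain_id]
    mob = _selection_coords(mobile, mode, ann, chain_ids)
    tgt = _selection_coords(target, mode, ann, chain_ids)
    if mob.shape != tgt.shape or len(mob) == 0:
        raise StructureError(
            f"superposition selections mismatch: {mob.shape} vs {tgt.shape}"
        )
    tf = kabsch(mob, tgt)
    return tf, rmsd(tf.apply(mob), tgt)


_ATOM_CLASSES = ("CA", "backbone", "heavy", "sidechain")


def _class_coords(residues, atom_class: str) -> np.ndarray:
    pts = []
    for r in residues:
        if atom_class == "CA":
            names = ["CA"]
        elif atom_class == "backbone":
            names = list(BACKBONE_ATOMS)
        elif atom_class == "heavy":
            names = [a.name for a in r.heavy_atoms()]
        elif atom_class == "sidechain":
            # non-backbone heavy atoms; CB counts as side chain
            names = [a.name for a in r.heavy_atoms() if a.name not in BACKBONE_ATOMS]
        else:
            raise ValueError(f"unknown atom class {atom_class!r}; use {_ATOM_CLASSES}")
        pts.extend(r.coord(n) for n in names if r.atom(n) is not None)
    return np.array(pts) if pts else np.zeros((0, 3))


def h3_rmsd(
    model: AntibodyStructure,
    native: AntibodyStructure,
    ann: H3Annotation,
    atom_class: str = "CA",
    mode: SuperpositionMode = SuperpositionMode.VH_BACKBONE_NO_H3,
) -> float:
    """Loop RMSD for one atom class in the frame fixed by ``superpose``.

    Returns NaN when the class selects no atoms (e.g. side chains of an
    all-glycine loop) — the documented empty-selection convention.
    """
    tf, _ = superpose(model, native, mode=mode, ann=ann)
    m_res = model.chain(ann.chain_id)[ann.start_index : ann.end_index + 1]
    n_res = native.chain(ann.chain_id)[ann.start_index : ann.end_index + 1]
    if len(m_res) != len(n_res):
        raise StructureError("H3 span mismatch between model and native")
    mob = _class_coords(m_res, atom_class)
    tgt = _class_coords(n_res, atom_class)
    if len(mob) == 0 and len(tgt) == 0:
        return float("nan")
    if mob.shape != tgt.shape:
        raise StructureError(
            f"H3 {atom_class} selections mismatch: {mob.shape} vs {tgt.shape}"
        )
    return rmsd(tf.apply(mob), tgt)


# ---------------------------------------------------------------------------
# TM-score and GDT


def _ca_pair(model, native, chain_id=None):
    if isinstance(model, AntibodyStructure):
        cid = chain_id or next(iter(model.chains))
        model = model.ca_coords(cid)
    if isinstance(native, AntibodyStructure):
        cid = chain_id or next(iter(native.chains))
        native = native.ca_coords(cid)
    model = np.asarray(model, dtype=float)
    native = np.asarray(native, dtype=float)
    if model.shape != native.shape or model.ndim != 2:
        raise StructureError("matched CA coordinate sets required")
    return model, native


def tm_d0(l_target: int) -> float:
    """Zhang-Skolnick normalisation length; clamped to 0.5 below 16 residues."""
    if l_target < 16:
        warnings.warn("TM-score d0 clamped to 0.5 for chains shorter than 16 residues")
        return 0.5
    return max(0.5, 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8)


def tm_from_distances(d: np.ndarray, l_target: int | None = None) -> float:
    """Closed-form TM kernel: mean of 1/(1 + (d_i/d0)^2) over per-residue
    distances in a fixed frame."""
    d = np.asarray(d, dtype=float)
    if l_target is None:
        l_target = len(d)
    d0 = tm_d0(l_target)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def _seed_windows(n: int) -> list[np.ndarray]:
    seeds = [np.arange(n)]
    for wlen in (4, max(4, n // 4), max(4, n // 2)):
        if wlen > n:
            continue
        step = max(1, wlen // 2)
        for start in range(0, n - wlen + 1, step):
            seeds.append(np.arange(start, start + wlen))
    return seeds


def _candidate_transforms(model, native, refine_fns, rounds: int = 3):
    """Candidate superpositions: seeded window fits plus, for every
    refinement rule, up to ``rounds`` of inlier re-fitting."""
    candidates = []
    for idx in _seed_windows(len(model)):
        tf0 = kabsch(model[idx], native[idx])
        candidates.append(tf0)
        for refine in refine_fns:
            tf = tf0
            for _ in range(rounds):
                d = np.linalg.norm(tf.apply(model) - native, axis=1)
                inliers = refine(d)
                if inliers.sum() < 3:
                    break
                tf = kabsch(model[inliers], native[inliers])
                candidates.append(tf)
    return candidates


def tm_score(model, native, chain_id: str | None = None, search: bool = True) -> float:
    """Template-modeling score in (0, 1], maximised over a superposition search."""
    model, native = _ca_pair(model, native, chain_id)
    d0 = tm_d0(len(model))

    def score(tf):
        return tm_from_distances(np.linalg.norm(tf.apply(model) - native, axis=1))

    if not search:
        return score(kabsch(model, native))
    # progressive refinement cuts around d0, as in iterative TM searches
    cuts = sorted({max(d0, 1.0), max(d0, 4.5), 2.0 * d0, 8.0})
    candidates = _candidate_transforms(
        model, native, [(lambda d, c=c: d < c) for c in cuts], rounds=5
    )
    scored = sorted(candidates, key=score, reverse=True)
    best = score(scored[0])
    # local continuous polish of the best few discrete candidates
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def neg_tm(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        d = np.linalg.norm(model @ rot.T + x[3:] - native, axis=1)
        return -tm_from_distances(d)

    for tf in scored[:5]:
        x0 = np.concatenate(
            [Rotation.from_matrix(tf.rotation).as_rotvec(), tf.translation]
        )
        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-9})
        best = max(best, float(-res.fun))
    return best


ALL_GDT_CUTOFFS = tuple(sorted(set(GDT_TS_CUTOFFS) | set(GDT_HA_CUTOFFS)))


def gdt_fractions(
    model,
    native,
    cutoffs,
    chain_id: str | None = None,
    superposition: str = "search",
    pool_cutoffs=ALL_GDT_CUTOFFS,
) -> np.ndarray:
    """Best within-cutoff CA fractions per cutoff.

    ``superposition`` is one of 'search' (seeded window fits + per-cutoff
    inlier refinement, all cutoffs sharing one candidate pool so fractions
    are monotone in the cutoff), 'global' (single full-length Kabsch fit)
    or 'none' (score in the given frame). The shared pool refines at
    ``pool_cutoffs`` (TS and HA cutoffs by default) so GDT-HA can never
    exceed GDT-TS on the same pair.
    """
    model, native = _ca_pair(model, native, chain_id)
    if len(model) == 0:
        raise StructureError("empty selection")
    if superposition == "none":
        d = np.linalg.norm(model - native, axis=1)
        return np.array([np.mean(d <= c) for c in cutoffs])
    if superposition == "global":
        tf = kabsch(model, native)
        d = np.linalg.norm(tf.apply(model) - native, axis=1)
        return np.array([np.mean(d <= c) for c in cutoffs])
    if superposition != "search":
        raise ValueError(f"unknown superposition mode {superposition!r}")
    refine_fns = [
        (lambda d, c=c: d <= c) for c in sorted(set(pool_cutoffs) | set(cutoffs))
    ]
    candidates = _candidate_transforms(model, native, refine_fns)
    dists = [np.linalg.norm(tf.apply(model) - native, axis=1) for tf in candidates]
    return np.array(
        [max(float(np.mean(d <= c)) for d in dists) for c in cutoffs]
    )


def gdt(
    model,
    native,
    cutoffs=GDT_TS_CUTOFFS,
    chain_id: str | None = None,
    superposition: str = "search",
) -> float:
    """Global distance test: mean over cutoffs of the best inlier fraction."""
    return float(np.mean(gdt_fractions(model, native, cutoffs, chain_id, superposition)))


def gdt_ts(model, native, **kw) -> float:
    return gdt(model, native, cutoffs=GDT_TS_CUTOFFS, **kw)


def gdt_ha(model, native, **kw) -> float:
    return gdt(model, native, cutoffs=GDT_HA_CUTOFFS, **kw)


# ---------------------------------------------------------------------------
# Z-scores


def z_average(z_gdt_ts: float, z_gdt_ha: float, z_tm: float) -> float:
    """Equal-weight mean of the three similarity Z-scores."""
    return (z_gdt_ts + z_gdt_ha + z_tm) / 3.0


def zscores_across_methods(values: dict[str, float]) -> dict[str, float]:
    """Standardise one target's metric across methods (sample sd, ddof=1)."""
    if len(values) < 2:
        raise ValueError("need >= 2 methods to standardise")
    arr = np.array(list(values.values()), dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0 or np.all(arr == arr[0]):
        return {k: 0.0 for k in values}
    mean = arr.mean()
    return {k: float((v - mean) / sd) for k, v in values.items()}


# ---------------------------------------------------------------------------
# one-call report


def evaluate_model(
    model: AntibodyStructure,
    native: AntibodyStructure,
    ann: H3Annotation,
    mode: SuperpositionMode = SuperpositionMode.VH_BACKBONE_NO_H3,
    gdt_search: bool = True,
) -> MetricReport:
    """Loop RMSDs plus whole-chain TM/GDT for a model/native pair."""
    ca_m = model.ca_coords(ann.chain_id)
    ca_n = native.ca_coords(ann.chain_id)
    return MetricReport(
        rmsd_ca=h3_rmsd(model, native, ann, "CA", mode),
        rmsd_backbone=h3_rmsd(model, native, ann, "backbone", mode),
        rmsd_heavy=h3_rmsd(model, native, ann, "heavy", mode),
        rmsd_sidechain=h3_rmsd(model, native, ann, "sidechain", mode),
        tm_score=tm_score(ca_m, ca_n),
        gdt_ts=gdt_ts(ca_m, ca_n, superposition="search" if gdt_search else "global"),
        gdt_ha=gdt_ha(ca_m, ca_n, superposition="search" if gdt_search else "global"),
        superposition_mode=mode.value,
    )
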