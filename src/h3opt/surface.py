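"""Surface accessibility and antibody-antigen contact analytics.

SASA uses the Shrake-Rupley rolling-probe algorithm (biotite's
implementation; Fibonacci point meshes, Bondi single-atom vdW radii, probe
1.4 A by default). Relative accessibility (rASA) normalises per-residue
SASA by the Tien et al. (2013) theoretical maxima; residues with
rASA strictly above 0.25 count as surface. Contacts between antibody and
antigen residues are defined by a minimum heavy-atom distance of at most
5 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .structures import AntibodyStructure, Residue, StructureError, ONE_TO_THREE

# Tien et al. 2013 theoretical maximum ASA per residue type (A^2)
MAX_ASA_TIEN2013 = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

SURFACE_RASA_CUTOFF = 0.25
CONTACT_THRESHOLD = 5.0  # Angstrom, min heavy-atom distance

# residue property classes; His is neutral-polar by default (configurable)
DEFAULT_PROPERTY_CLASSES = {
    "hydrophobic": set("AVLIMFWPG"),
    "positive": set("KR"),
    "negative": set("DE"),
    "neutral-polar": set("STNQYCH"),
}


class RadiusTableError(KeyError):
    pass


def _to_atom_array(residues: list[Residue], chain_id: str = "A") -> struc.AtomArray:
    atoms = [(i, r, a) for i, r in enumerate(residues) for a in r.heavy_atoms()]
    arr = struc.AtomArray(len(atoms))
    for k, (i, r, a) in enumerate(atoms):
        arr.coord[k] = a.coord
        arr.chain_id[k] = chain_id
        arr.res_id[k] = i + 1
        arr.res_name[k] = ONE_TO_THREE.get(r.aa, "UNK")
        arr.atom_name[k] = a.name
        arr.element[k] = a.element.upper()
    return arr


def sasa(
    structure_or_residues,
    chain_id: str | None = None,
    probe: float = 1.4,
    sphere_points: int = 960,
) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2).

    Deterministic for a fixed ``sphere_points`` (Fibonacci mesh). Raises
    :class:`RadiusTableError` for elements without a bundled vdW radius.
    """
    if isinstance(structure_or_residues, AntibodyStructure):
        cid = chain_id or next(iter(structure_or_residues.chains))
        residues = structure_or_residues.chain(cid)
    else:
        residues = structure_or_residues
    arr = _to_atom_array(residues)
    from biotite.structure.info import vdw_radius_single

    for el in np.unique(arr.element):
        if vdw_radius_single(str(el)) is None:
            raise RadiusTableError(f"no vdW radius for element {el!r}")
    atom_sasa = struc.sasa(
        arr, probe_radius=probe, point_number=sphere_points,
        vdw_radii="Single", ignore_ions=False,
    )
    out = np.zeros(len(residues))
    np.add.at(out, arr.res_id - 1, np.nan_to_num(atom_sasa))
    return out


def rasa(sasa_per_residue: np.ndarray, sequence: str) -> np.ndarray:
    """Relative accessibility: SASA over the residue-type theoretical max."""
    vals = np.asarray(sasa_per_residue, dtype=float)
    if len(vals) != len(sequence):
        raise ValueError("one SASA value per residue required")
    out = np.empty(len(vals))
    for i, (s, aa) in enumerate(zip(vals, sequence)):
        if aa not in MAX_ASA_TIEN2013:
            raise StructureError(f"no max-ASA normalisation for residue {aa!r}")
        out[i] = s / MAX_ASA_TIEN2013[aa]
    return out


@dataclass
class SurfaceProfile:
    sequence: str
    sasa: np.ndarray  # per residue, A^2
    rasa: np.ndarray  # fraction

    @property
    def is_surface(self) -> np.ndarray:
        return self.rasa > SURFACE_RASA_CUTOFF


def surface_profile(
    structure_or_residues, chain_id: str | None = None,
    probe: float = 1.4, sphere_points: int = 960,
) -> SurfaceProfile:
    if isinstance(structure_or_residues, AntibodyStructure):
        cid = chain_id or next(iter(structure_or_residues.chains))
        residues = structure_or_residues.chain(cid)
    else:
        residues = structure_or_residues
    seq = "".join(r.aa for r in residues)
    s = sasa(residues, probe=probe, sphere_points=sphere_points)
    return SurfaceProfile(sequence=seq, sasa=s, rasa=rasa(s, seq))


def surface_residues(
    profile: SurfaceProfile,
    cutoff: float = SURFACE_RASA_CUTOFF,
    classes: dict[str, set] = DEFAULT_PROPERTY_CLASSES,
) -> tuple[list[int], dict[str, int]]:
    """Indices with rASA strictly above ``cutoff`` plus per-class counts."""
    idx = [i for i, r in enumerate(profile.rasa) if r > cutoff]
    counts = {name: 0 for name in classes}
    for i in idx:
        aa = profile.sequence[i]
        for name, members in classes.items():
            if aa in members:
                counts[name] += 1
    return idx, counts


# ---------------------------------------------------------------------------
# contacts


@dataclass
class ContactMap:
    min_dist: np.ndarray  # [n_ab, n_ag] min heavy-atom distance, A
    threshold: float
    ab_sequence: str = ""
    ag_sequence: str = ""

    @property
    def contacts(self) -> np.ndarray:
        return self.min_dist <= self.threshold


def contact_map(
    ab_residues: list[Residue],
    ag_residues: list[Residue],
    threshold: float = CONTACT_THRESHOLD,
) -> ContactMap:
    """Minimum heavy-atom distance per antibody/antigen residue pair."""
    if not ab_residues or not ag_residues:
        raise StructureError("contact map requires non-empty residue lists")
    md = np.empty((len(ab_residues), len(ag_residues)))
    ag_coords = [np.array([a.coord for a in r.heavy_atoms()]) for r in ag_residues]
    for i, ra in enumerate(ab_residues):
        ca = np.array([a.coord for a in ra.heavy_atoms()])
        for j, cg in enumerate(ag_coords):
            diff = ca[:, None, :] - cg[None, :, :]
            md[i, j] = np.sqrt((diff**2).sum(axis=-1)).min()
    return ContactMap(
        min_dist=md,
        threshold=threshold,
        ab_sequence="".join(r.aa for r in ab_residues),
        ag_sequence="".join(r.aa for r in ag_residues),
    )


def binding_site_metrics(
    predicted: ContactMap, native: ContactMap
) -> dict[str, float | None]:
    """Epitope-level precision/recall/accuracy.

    Antigen residues are labelled contact/non-contact by whether any
    antibody (loop) residue touches them; the confusion matrix is taken
    over antigen residues. An empty predicted set yields precision None
    (0/0 convention).
    """
    if predicted.min_dist.shape != native.min_dist.shape:
        raise ValueError("contact maps must share residue sets")
    pred = predicted.contacts.any(axis=0)
    nat = native.contacts.any(axis=0)
    tp = int(np.sum(pred & nat))
    fp = int(np.sum(pred & ~nat))
    fn = int(np.sum(~pred & nat))
    tn = int(np.sum(~pred & ~nat))
    total = tp + fp + fn + tn
    return {
        "precision": tp / (tp + fp) if (tp + fp) else None,
        "recall": tp / (tp + fn) if (tp + fn) else None,
        "accuracy": (tp + tn) / total if total else None,
    }


def distance_mse(
    pred: ContactMap, native: ContactMap, thresholds=(4.0, 5.0, 6.0, 8.0)
) -> dict[float, float | None]:
    """Per-threshold MSE of predicted vs native minimum distances.

    For each threshold t the MSE runs over residue pairs whose *native*
    minimum distance is <= t; thresholds with no qualifying pairs map to
    None.
    """
    if pred.min_dist.shape != native.min_dist.shape:
        raise ValueError("contact maps must share residue sets")
    out: dict[float, float | None] = {}
    err2 = (pred.min_dist - native.min_dist) ** 2
    for t in thresholds:
        mask = native.min_dist <= t
        out[t] = float(err2[mask].mean()) if mask.any() else None
    return out


def contact_propensity(maps: list[ContactMap]) -> tuple[np.ndarray, bool]:
    """20x20 (alphabetical one-letter) contact-pair frequency matrix.

    Counts (antibody-aa, antigen-aa) pairs over all contacts in all maps,
    normalised to sum to 1. The flag is False when no contacts exist (zero
    matrix returned).
    """
    from .structures import AMINO_ACIDS

    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20))
    for m in maps:
        ii, jj = np.nonzero(m.contacts)
        for i, j in zip(ii, jj):
            a, g = m.ab_sequence[i], m.ag_sequence[j]
            if a in idx and g in idx:
                counts[idx[a], idx[g]] += 1
    total = counts.sum()
    if total == 0:
        return counts, False
    return counts / total, True
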