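"""Deterministic synthetic antibody fixtures.

Builds toy V_H-like chains from ideal backbone internal coordinates: two
beta-strand framework segments flanking a seeded random-coil CDR-H3 loop,
with the conserved Cys ... Trp-Gly flank placed so the motif-based
annotation heuristic recovers the loop span. "Predicted model" companions
are made by deforming the loop with a smooth displacement field that
vanishes at the loop ends (so junction geometry stays intact) and scaling it
to a requested loop CA-RMSD; per-residue confidence is anticorrelated with
the local displacement, emulating the empirical confidence-vs-error
relationship of structure predictors.

Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import (
    AntibodyStructure,
    AtomRecord,
    H3Annotation,
    Residue,
    StructureError,
)

# Engh/Huber-style ideal backbone internal coordinates (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

BETA_PHI_PSI = (-120.0, 130.0)
HELIX_PHI_PSI = (-57.0, -47.0)

# random-residue alphabet for fixtures: no C or W, so the single framework
# Cys and the Trp-Gly flank stay unambiguous for the annotation heuristic
_FIXTURE_ALPHABET = "ADEFGHIKLMNPQRSTVY"


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Natural extension reference frame (NeRF) atom placement.

    Returns the point d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
    chain_id: str = "H",
) -> AntibodyStructure:
    """Build an all-residue backbone (N, CA, C, O, CB except GLY) chain.

    ``phi[0]`` and ``psi[-1]`` are unused (undefined at the termini);
    ``omega`` defaults to 180 degrees everywhere.
    """
    n = len(sequence)
    if not (len(phi) == len(psi) == n):
        raise StructureError("phi/psi must match sequence length")
    if omega is None:
        omega = np.full(n, 180.0)
    coords_n = np.zeros((n, 3))
    coords_ca = np.zeros((n, 3))
    coords_c = np.zeros((n, 3))
    # seed the first residue in a canonical pose
    coords_n[0] = (0.0, 0.0, 0.0)
    coords_ca[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords_c[0] = coords_ca[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        coords_n[i] = place_atom(
            coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
            BOND_C_N, ANGLE_CA_C_N, psi[i - 1],
        )
        coords_ca[i] = place_atom(
            coords_ca[i - 1], coords_c[i - 1], coords_n[i],
            BOND_N_CA, ANGLE_C_N_CA, omega[i - 1],
        )
        coords_c[i] = place_atom(
            coords_c[i - 1], coords_n[i], coords_ca[i],
            BOND_CA_C, ANGLE_N_CA_C, phi[i],
        )
    residues = []
    for i, aa in enumerate(sequence):
        atoms = [
            AtomRecord("N", "N", coords_n[i]),
            AtomRecord("CA", "C", coords_ca[i]),
            AtomRecord("C", "C", coords_c[i]),
        ]
        # carbonyl O: anti-periplanar to the next N (psi + 180); for the
        # final residue place it from the last psi anyway
        o_tors = psi[i] + 180.0 if i < n - 1 else 120.0
        atoms.append(
            AtomRecord(
                "O", "O",
                place_atom(coords_n[i], coords_ca[i], coords_c[i],
                           BOND_C_O, ANGLE_CA_C_O, o_tors),
            )
        )
        if aa != "G":
            # improper C-N-CA-CB of about -122.5 deg gives L-chirality
            cb = place_atom(coords_c[i], coords_n[i], coords_ca[i],
                            BOND_CA_CB, 110.4, -122.5)
            atoms.append(AtomRecord("CB", "C", cb))
        residues.append(Residue(aa=aa, author_number=i + 1, seq_index=i, atoms=atoms))
    return AntibodyStructure(chains={chain_id: residues}, source="synthetic fixture")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic native/model pair."""

    n_framework: int = 100
    h3_length: int = 12
    perturbation_rmsd_target: float = 3.0  # Angstrom, loop CA-RMSD of the "model"
    confidence_noise: float = 5.0  # sd of Gaussian noise on the 0-100 scale
    seed: int = 0

    def __post_init__(self):
        if self.h3_length < 4:
            raise StructureError("h3_length must be >= 4")
        if self.n_framework < 12:
            raise StructureError("n_framework must be >= 12")


def make_toy_fv(spec: FixtureSpec) -> tuple[AntibodyStructure, H3Annotation]:
    """Build a native toy V_H structure and its CDR-H3 annotation."""
    rng = np.random.default_rng(spec.seed)
    n_pre = spec.n_framework // 2
    n_post = spec.n_framework - n_pre
    n_total = n_pre + spec.h3_length + n_post

    seq = list(rng.choice(list(_FIXTURE_ALPHABET), size=n_total))
    start = n_pre
    end = n_pre + spec.h3_length - 1
    seq[start - 3] = "C"  # framework 3 Cys; heuristic: span starts Cys + 3
    seq[end + 1] = "W"  # Trp-Gly flank; heuristic: span ends at Trp - 1
    seq[end + 2] = "G"
    sequence = "".join(seq)

    phi = np.empty(n_total)
    psi = np.empty(n_total)
    phi[:], psi[:] = BETA_PHI_PSI
    sep = np.abs(np.arange(n_total)[:, None] - np.arange(n_total)[None, :])
    best: tuple[float, AntibodyStructure] | None = None
    for attempt in range(96):
        phi[start : end + 1] = rng.uniform(-150.0, -45.0, spec.h3_length)
        psi[start : end + 1] = rng.uniform(-60.0, 150.0, spec.h3_length)
        candidate = build_backbone(sequence, phi, psi)
        ca = candidate.ca_coords("H")
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        if np.any(d[sep >= 2] < 3.0):
            continue
        # score by heavy-atom clearance (>= 2 residues apart) so natives
        # are geometrically clean, not just CA-separated
        coords, res_of = [], []
        for r in candidate.chains["H"]:
            for a in r.atoms:
                coords.append(a.coord)
                res_of.append(r.seq_index)
        coords = np.array(coords)
        res_of = np.array(res_of)
        dh = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        seph = np.abs(res_of[:, None] - res_of[None, :])
        clearance = float(dh[seph >= 2].min())
        if best is None or clearance > best[0]:
            best = (clearance, candidate)
        if clearance >= 3.0:  # comfortably clash-free; stop early
            break
    if best is None or best[0] < 2.8:
        raise StructureError(
            "loop generation failed: persistent steric clashes after retries"
        )
    native = best[1]
    for r in native.chains["H"]:
        r.confidence = 100.0
    return native, H3Annotation("H", start, end)


def perturb_model(
    native: AntibodyStructure,
    ann: H3Annotation,
    target_rmsd: float,
    seed: int,
    confidence_noise: float = 5.0,
) -> AntibodyStructure:
    """Derive a "predicted model" by deforming the loop of a native structure.

    Loop residues are rigidly displaced by a sine-windowed smooth vector
    field (zero at the loop ends) scaled so the achieved loop CA-RMSD equals
    ``target_rmsd``; the framework is untouched. Per-residue confidence is
    set to clamp(100 * (1 - displacement / 8) + noise, 0, 100) so confidence
    anticorrelates with local error.
    """
    if target_rmsd < 0:
        raise StructureError("target_rmsd must be >= 0")
    rng = np.random.default_rng(seed)
    model = native.copy()
    chain = model.chain(ann.chain_id)
    span = list(ann.indices)
    m = len(span)

    t = np.arange(1, m + 1) / (m + 1)
    window = np.sin(np.pi * t)
    a = rng.normal(size=3)
    b = rng.normal(size=3)
    a /= np.linalg.norm(a)
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    directions = (
        np.outer(np.cos(0.5 * np.pi * t), a) + np.outer(np.sin(0.5 * np.pi * t), b)
    )
    disp = window[:, None] * directions
    scale = 0.0
    if target_rmsd > 0:
        scale = target_rmsd / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    disp = scale * disp

    disp_norm = np.zeros(len(chain))
    for k, i in enumerate(span):
        disp_norm[i] = np.linalg.norm(disp[k])
        for atom in chain[i].atoms:
            atom.coord = atom.coord + disp[k]
    noise = rng.normal(scale=confidence_noise, size=len(chain))
    for r in chain:
        r.confidence = float(np.clip(100.0 * (1.0 - disp_norm[r.seq_index] / 8.0)
                                     + noise[r.seq_index], 0.0, 100.0))
    model.source = f"synthetic model (target loop CA-RMSD {target_rmsd:.2f} A)"
    return model


@dataclass
class DatasetItem:
    target_id: str
    native: AntibodyStructure
    model: AntibodyStructure
    annotation: H3Annotation
    spec: FixtureSpec
    split: str = ""


# split proportions mirror a ~1021/134/131 train/validation/test partition
DEFAULT_SPLIT_RATIOS = (1021 / 1286, 134 / 1286, 131 / 1286)


def split_sizes(n: int, ratios=DEFAULT_SPLIT_RATIOS) -> tuple[int, int, int]:
    """Round train/val to nearest (min 1 each); test takes the remainder."""
    if n < 3:
        raise StructureError("dataset needs n >= 3 for three non-empty splits")
    n_train = max(1, round(n * ratios[0]))
    n_val = max(1, round(n * ratios[1]))
    if n_train + n_val >= n:
        n_train = n - 2
        n_val = 1
    return n_train, n_val, n - n_train - n_val


def make_dataset(
    n: int,
    seed: int = 0,
    h3_length_range: tuple[int, int] = (8, 16),
    rmsd_range: tuple[float, float] = (0.5, 6.0),
    n_framework: int = 60,
    confidence_noise: float = 5.0,
    ratios=DEFAULT_SPLIT_RATIOS,
) -> tuple[list[DatasetItem], pd.DataFrame]:
    """Generate ``n`` native/model pairs with disjoint train/val/test splits.

    Returns the items plus a manifest DataFrame (one row per item with the
    per-item seed, loop length, target RMSD and split) suitable for TSV
    round-tripping.
    """
    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = split_sizes(n, ratios)
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    items: list[DatasetItem] = []
    rows = []
    for i in range(n):
        item_seed = int(rng.integers(0, 2**31 - 1))
        h3_len = int(rng.integers(h3_length_range[0], h3_length_range[1] + 1))
        target = float(rng.uniform(*rmsd_range))
        spec = FixtureSpec(
            n_framework=n_framework,
            h3_length=h3_len,
            perturbation_rmsd_target=target,
            confidence_noise=confidence_noise,
            seed=item_seed,
        )
        native, ann = make_toy_fv(spec)
        model = perturb_model(native, ann, target, seed=item_seed + 1,
                              confidence_noise=confidence_noise)
        tid = f"toy{i:04d}"
        items.append(DatasetItem(tid, native, model, ann, spec, splits[i]))
        rows.append(
            {
                "target_id": tid,
                "seed": item_seed,
                "h3_length": h3_len,
                "target_rmsd": round(target, 4),
                "split": splits[i],
            }
        )
    manifest = pd.DataFrame(rows)
    return items, manifest


def mock_embeddings(sequence: str, dim: int = 32, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in for per-residue language-model embeddings.

    Each row is drawn from a generator keyed by a hash of
    (seed, sequence, position), giving identical matrices for identical
    sequences and (asymptotically) zero-mean unit-variance channels.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    out = np.empty((len(sequence), dim))
    for i in range(len(sequence)):
        key = hashlib.sha256(f"{seed}:{sequence}:{i}".encode()).digest()[:8]
        row_rng = np.random.default_rng(int.from_bytes(key, "little"))
        out[i] = row_rng.standard_normal(dim)
    return out
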