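"""Residue-level and pairwise feature encodings for the coordinate network.

A chain of length L in the aligned frame is encoded as:

* residue features [L, 34] = one-hot amino-acid type (21, UNK last)
  ++ CA coordinates (3, Angstrom) ++ sin/cos of (phi, psi, omega) (6)
  ++ torsion-presence mask (3) ++ CDR-H3 membership mask (1)
* pair features [L, L, 60] = one-hot CA-CA distance bin (39)
  ++ one-hot amino-acid type of residue j (21)

Distance binning covers 3.25-50.75 Angstrom in 38 equal 1.25 Angstrom bins;
the 39th bin absorbs anything larger, and sub-range distances (clashes,
the diagonal) clamp into bin 0 so every slice stays a valid one-hot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral
from .structures import AMINO_ACIDS, AntibodyStructure, H3Annotation, Residue

N_AA_TYPES = 21  # 20 standard + UNK
N_RESIDUE_CHANNELS = 34
N_DISTANCE_BINS = 39
N_PAIR_CHANNELS = N_DISTANCE_BINS + N_AA_TYPES  # 60
DIST_MIN = 3.25
DIST_MAX = 50.75
DIST_BIN_WIDTH = (DIST_MAX - DIST_MIN) / 38  # 1.25 A

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}  # UNK -> 20


class FeaturizationError(ValueError):
    pass


def aa_one_hot(aa: str) -> np.ndarray:
    v = np.zeros(N_AA_TYPES)
    v[AA_INDEX.get(aa, 20)] = 1.0
    return v


@dataclass
class FeatureBundle:
    residue_feats: np.ndarray  # [L, 34]
    pair_feats: np.ndarray  # [L, L, 60]
    h3_mask: np.ndarray  # [L] binary
    torsion_mask: np.ndarray  # [L, 3] binary
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.residue_feats.shape[0]

    def manifest(self, frame_reference: str = "") -> str:
        """JSON manifest describing the channel layout for array export."""
        return json.dumps(
            {
                "L": self.length,
                "channel_map": {
                    "residue": {
                        "aa_one_hot": [0, 21],
                        "ca_coords_A": [21, 24],
                        "torsion_sincos": [24, 30],
                        "torsion_mask": [30, 33],
                        "h3_mask": [33, 34],
                    },
                    "pair": {
                        "distance_one_hot": [0, 39],
                        "aa_one_hot_j": [39, 60],
                    },
                },
                "coordinate_channels": "raw Angstrom in the aligned frame",
                "frame_reference": frame_reference,
            }
        )


def backbone_torsions(chain: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi, omega) in radians with a presence mask.

    The mask is 0 (and the angle 0) wherever a flanking atom is missing:
    phi at the first residue, psi and omega at the last, and anywhere a
    backbone atom is absent.
    """
    n = len(chain)
    angles = np.zeros((n, 3))
    mask = np.zeros((n, 3))

    def bb(i: int, name: str) -> np.ndarray | None:
        a = chain[i].atom(name)
        return None if a is None else a.coord

    for i in range(n):
        n_i, ca_i, c_i = bb(i, "N"), bb(i, "CA"), bb(i, "C")
        # phi: C(i-1) - N(i) - CA(i) - C(i)
        if i > 0:
            c_prev = bb(i - 1, "C")
            if all(x is not None for x in (c_prev, n_i, ca_i, c_i)):
                angles[i, 0] = dihedral(c_prev, n_i, ca_i, c_i)
                mask[i, 0] = 1.0
        if i < n - 1:
            n_next, ca_next = bb(i + 1, "N"), bb(i + 1, "CA")
            # psi: N(i) - CA(i) - C(i) - N(i+1)
            if all(x is not None for x in (n_i, ca_i, c_i, n_next)):
                angles[i, 1] = dihedral(n_i, ca_i, c_i, n_next)
                mask[i, 1] = 1.0
            # omega: CA(i) - C(i) - N(i+1) - CA(i+1)
            if all(x is not None for x in (ca_i, c_i, n_next, ca_next)):
                angles[i, 2] = dihedral(ca_i, c_i, n_next, ca_next)
                mask[i, 2] = 1.0
    return angles, mask


def bin_distance(d: float) -> int:
    """Map a CA-CA distance (Angstrom) to its one-hot bin index in {0..38}."""
    if not np.isfinite(d) or d < 0:
        raise FeaturizationError(f"distance must be finite and >= 0, got {d}")
    if d < DIST_MIN:
        return 0
    if d >= DIST_MAX:
        return N_DISTANCE_BINS - 1
    return int((d - DIST_MIN) // DIST_BIN_WIDTH)


def _require_ca(chain: list[Residue]) -> np.ndarray:
    coords = []
    for r in chain:
        a = r.atom("CA")
        if a is None:
            raise FeaturizationError(
                f"residue {r.aa}{r.author_number} (index {r.seq_index}) has no CA atom"
            )
        coords.append(a.coord)
    return np.array(coords)


def residue_features(s: AntibodyStructure, ann: H3Annotation) -> np.ndarray:
    """The [L, 34] residue feature matrix for the annotated chain."""
    chain = s.chain(ann.chain_id)
    ca = _require_ca(chain)
    angles, tmask = backbone_torsions(chain)
    l = len(chain)
    feats = np.zeros((l, N_RESIDUE_CHANNELS))
    for i, r in enumerate(chain):
        feats[i, :21] = aa_one_hot(r.aa)
    feats[:, 21:24] = ca
    feats[:, 24:30] = np.stack(
        [np.sin(angles), np.cos(angles)], axis=-1
    ).reshape(l, 6) * np.repeat(tmask, 2, axis=1)
    feats[:, 30:33] = tmask
    for i in ann.indices:
        feats[i, 33] = 1.0
    return feats


def pair_features(s: AntibodyStructure, chain_id: str) -> np.ndarray:
    """The [L, L, 60] pairwise feature tensor for one chain."""
    chain = s.chain(chain_id)
    ca = _require_ca(chain)
    l = len(chain)
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    feats = np.zeros((l, l, N_PAIR_CHANNELS))
    bins = np.clip(((d - DIST_MIN) // DIST_BIN_WIDTH).astype(int), 0, N_DISTANCE_BINS - 1)
    bins[d < DIST_MIN] = 0
    bins[d >= DIST_MAX] = N_DISTANCE_BINS - 1
    ii, jj = np.meshgrid(np.arange(l), np.arange(l), indexing="ij")
    feats[ii, jj, bins] = 1.0
    aa_oh = np.array([aa_one_hot(r.aa) for r in chain])  # [L, 21]
    feats[:, :, N_DISTANCE_BINS:] = np.broadcast_to(aa_oh[None, :, :], (l, l, N_AA_TYPES))
    return feats


def featurize(s: AntibodyStructure, ann: H3Annotation) -> FeatureBundle:
    """Full feature bundle for the annotated chain, in the current frame."""
    chain = s.chain(ann.chain_id)
    _, tmask = backbone_torsions(chain)
    h3 = np.zeros(len(chain))
    h3[list(ann.indices)] = 1.0
    return FeatureBundle(
        residue_feats=residue_features(s, ann),
        pair_feats=pair_features(s, ann.chain_id),
        h3_mask=h3,
        torsion_mask=tmask,
        sequence=s.sequence(ann.chain_id),
    )
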