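"""Antibody structure I/O and framing.

Structures are held as plain per-chain residue lists with 0-based contiguous
``seq_index`` (author numbering is kept only for round-tripping PDB files).
Parsing and writing go through biotite's PDB reader/writer; waters and
heteroatoms are dropped and alternate locations are resolved to the
highest-occupancy conformer ('A'/blank wins ties by occupancy order).

Per-residue confidence (a pLDDT-like score in [0, 100]) rides in the PDB
B-factor column, the convention used by structure-prediction pipelines.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .geometry import RigidTransform, kabsch, rmsd

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20, one-letter


class StructureError(ValueError):
    """Raised for malformed or contract-violating structure input."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) float, Angstrom
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    aa: str  # one-letter code, 'X' for UNK
    author_number: int
    seq_index: int
    atoms: list[AtomRecord] = field(default_factory=list)
    confidence: float | None = None  # pLDDT-like, [0, 100]
    insertion_code: str = ""

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise StructureError(
                f"residue {self.aa}{self.author_number} has no atom {name!r}"
            )
        return a.coord

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class AntibodyStructure:
    chains: dict[str, list[Residue]]
    source: str = ""

    def __post_init__(self):
        if not self.chains:
            raise StructureError("structure must contain at least one chain")

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise StructureError(f"no chain {chain_id!r} in structure") from None

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chain(chain_id))

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.coord("CA") for r in self.chain(chain_id)])

    def confidences(self, chain_id: str) -> list[float | None]:
        return [r.confidence for r in self.chain(chain_id)]

    def copy(self) -> "AntibodyStructure":
        chains = {
            cid: [
                replace(
                    r,
                    atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms],
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return AntibodyStructure(chains=chains, source=self.source)

    def transformed(self, tf: RigidTransform) -> "AntibodyStructure":
        out = self.copy()
        for residues in out.chains.values():
            for r in residues:
                for a in r.atoms:
                    a.coord = tf.apply(a.coord)
        return out


@dataclass(frozen=True)
class H3Annotation:
    """Inclusive 0-based CDR-H3 span on a heavy chain, plus grafting anchors."""

    chain_id: str
    start_index: int
    end_index: int

    def __post_init__(self):
        if self.end_index < self.start_index:
            raise StructureError(
                f"H3 span end {self.end_index} precedes start {self.start_index}"
            )

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def anchor_n(self) -> tuple[int, int]:
        return (self.start_index, self.start_index + 1)

    @property
    def anchor_c(self) -> tuple[int, int]:
        return (self.end_index - 1, self.end_index)

    @property
    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)

    def require_graftable(self) -> None:
        if self.length < 4:
            raise StructureError(
                f"H3 span of length {self.length} < 4 cannot carry two anchors per side"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "chain_id": self.chain_id,
                "h3_start": self.start_index,
                "h3_end": self.end_index,
                "numbering": "0-based inclusive",
            }
        )

    @staticmethod
    def from_json(text: str) -> "H3Annotation":
        d = json.loads(text)
        return H3Annotation(d["chain_id"], int(d["h3_start"]), int(d["h3_end"]))


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_atom_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureError(f"malformed ATOM record at line {lineno}: too short")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise StructureError(
                    f"malformed ATOM record at line {lineno}: bad coordinate field"
                ) from None


def parse_structure(pdb_text: str, source: str = "") -> AntibodyStructure:
    """Parse PDB text into an :class:`AntibodyStructure`.

    Waters and heteroatoms are dropped; altlocs resolved by occupancy
    (ties keep the first conformer, i.e. 'A' or blank); residues are ordered
    by author numbering within each chain and renumbered with a contiguous
    0-based ``seq_index``. B-factors populate per-residue confidence as the
    mean over the residue's atoms.
    """
    _validate_atom_lines(pdb_text)
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    try:
        arr = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # biotite raises various subclasses
        raise StructureError(f"PDB parse failure: {exc}") from exc
    arr = arr[struc.filter_amino_acids(arr) & ~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError("no protein residues in PDB input")

    chains: dict[str, list[Residue]] = {}
    for cid in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == cid]
        residues: list[Residue] = []
        starts = struc.get_residue_starts(sub, add_exclusive_stop=True)
        for seq_index, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
            res = sub[lo:hi]
            aa = THREE_TO_ONE.get(str(res.res_name[0]), "X")
            atoms = [
                AtomRecord(
                    name=str(res.atom_name[k]),
                    element=str(res.element[k]).capitalize() or "C",
                    coord=np.array(res.coord[k], dtype=float),
                    occupancy=float(res.occupancy[k]),
                )
                for k in range(res.array_length())
            ]
            conf = float(np.mean(res.b_factor)) if res.array_length() else None
            residues.append(
                Residue(
                    aa=aa,
                    author_number=int(res.res_id[0]),
                    seq_index=seq_index,
                    atoms=atoms,
                    confidence=conf,
                    insertion_code=str(res.ins_code[0]) if hasattr(res, "ins_code") else "",
                )
            )
        chains[str(cid)] = residues
    return AntibodyStructure(chains=chains, source=source)


def write_structure(s: AntibodyStructure) -> str:
    """Serialise to PDB text (ATOM/TER/END records, 8.3 fixed-point coords)."""
    n_atoms = sum(len(r.atoms) for residues in s.chains.values() for r in residues)
    if n_atoms == 0:
        raise StructureError("cannot write a structure with no atoms")
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    i = 0
    for cid in s.chains:
        for r in s.chains[cid]:
            for a in r.atoms:
                if np.any(np.abs(a.coord) >= 10000.0):
                    raise StructureError(
                        f"coordinate magnitude >= 10000 A not representable in PDB "
                        f"(atom {a.name} of residue {r.aa}{r.author_number})"
                    )
                arr.coord[i] = a.coord
                arr.chain_id[i] = cid
                arr.res_id[i] = r.author_number
                arr.res_name[i] = ONE_TO_THREE.get(r.aa, "UNK")
                arr.atom_name[i] = a.name
                arr.element[i] = a.element.upper()
                arr.hetero[i] = False
                arr.b_factor[i] = r.confidence if r.confidence is not None else 0.0
                arr.occupancy[i] = a.occupancy
                i += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    return "\n".join(pdb_file.lines) + "\n"


# ---------------------------------------------------------------------------
# CDR-H3 annotation


def annotate_h3(
    s: AntibodyStructure,
    chain_id: str,
    span: tuple[int, int] | None = None,
) -> H3Annotation:
    """Locate the CDR-H3 span on a heavy chain.

    An explicit 0-based inclusive ``span`` is passed through verbatim (after
    bounds checking). In auto mode a motif heuristic is applied: the span
    starts three residues after the last cysteine in the first ~90 positions
    of the chain and ends one residue before the first Trp of a 'WG' motif
    following that cysteine (the conserved framework Cys ... Trp-Gly flank of
    immunoglobulin CDR-H3). Explicit spans always override the heuristic.
    """
    chain = s.chain(chain_id)
    n = len(chain)
    if span is not None:
        start, end = span
        if not (0 <= start <= end < n):
            raise StructureError(f"explicit span {span} outside chain of length {n}")
        return H3Annotation(chain_id, start, end)

    seq = s.sequence(chain_id)
    search_limit = min(n, 90)
    cys = seq.rfind("C", 0, search_limit)
    if cys == -1:
        raise StructureError(
            "auto H3 annotation failed: no framework Cys found; pass an explicit span"
        )
    wg = seq.find("WG", cys + 3)
    if wg == -1:
        raise StructureError(
            "auto H3 annotation failed: no Trp-Gly motif after framework Cys; "
            "pass an explicit span"
        )
    start, end = cys + 3, wg - 1
    if end < start:
        raise StructureError(
            "auto H3 annotation failed: motif yields an empty span; pass an explicit span"
        )
    return H3Annotation(chain_id, start, end)


# ---------------------------------------------------------------------------
# Framework alignment


def align_to_reference(
    mobile: AntibodyStructure,
    reference: AntibodyStructure,
    mobile_ann: H3Annotation | None = None,
    reference_ann: H3Annotation | None = None,
    chain_id: str | None = None,
) -> tuple[AntibodyStructure, RigidTransform, float]:
    """Rigidly fit ``mobile`` onto ``reference`` using framework CA atoms.

    The fit selection is every residue of the paired chain(s) *outside* the
    CDR-H3 span (when annotations are given); the reported RMSD is the
    post-fit RMSD over that same framework selection. Chains are matched by
    id (or the single ``chain_id``); matched chains must have equal residue
    counts — length mismatches surface as errors rather than being gapped.
    """
    if chain_id is not None:
        cids = [chain_id]
    else:
        cids = [c for c in mobile.chains if c in reference.chains]
        if not cids:
            raise StructureError("no common chain ids between mobile and reference")

    excluded_m: set[tuple[str, int]] = set()
    excluded_r: set[tuple[str, int]] = set()
    if mobile_ann is not None:
        excluded_m = {(mobile_ann.chain_id, i) for i in mobile_ann.indices}
    if reference_ann is not None:
        excluded_r = {(reference_ann.chain_id, i) for i in reference_ann.indices}

    mob_pts, ref_pts = [], []
    for cid in cids:
        mc, rc = mobile.chain(cid), reference.chain(cid)
        if len(mc) != len(rc):
            raise StructureError(
                f"chain {cid}: residue count mismatch ({len(mc)} vs {len(rc)}); "
                "equal-length matched selections are required"
            )
        for mr, rr in zip(mc, rc):
            if (cid, mr.seq_index) in excluded_m or (cid, rr.seq_index) in excluded_r:
                continue
            if mr.has_ca and rr.has_ca:
                mob_pts.append(mr.coord("CA"))
                ref_pts.append(rr.coord("CA"))
    if len(mob_pts) < 3:
        raise StructureError(
            f"alignment requires >= 3 matched framework CA pairs, got {len(mob_pts)}"
        )
    mob_pts = np.array(mob_pts)
    ref_pts = np.array(ref_pts)
    tf = kabsch(mob_pts, ref_pts)
    fit_rmsd = rmsd(tf.apply(mob_pts), ref_pts)
    return mobile.transformed(tf), tf, fit_rmsd
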