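"""Template-module routing: confidence gating, template lookup and grafting.

The router decides, per input model, between three routes:

* ``KEEP_AF2`` — the mean CDR-H3 confidence (pLDDT/100) strictly exceeds the
  cutoff (default 0.80), so the input loop is kept as-is;
* ``GRAFT`` — an experimentally derived loop with an *identical* CDR-H3
  sequence exists in the template database and is grafted onto the model by
  a rigid anchor-atom fit;
* ``PSPM`` — neither applies; the coordinate network takes over.

Grafting anchors are the CA and carbonyl C atoms of the first two loop
residues plus the CA and backbone N atoms of the last two (8 atoms total).
The template is rigidly fitted onto those anchors (Kabsch) and its residues
replace the model's loop residues; everything outside the span is untouched.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import kabsch, rmsd
from .structures import (
    AntibodyStructure,
    H3Annotation,
    Residue,
    StructureError,
    parse_structure,
    write_structure,
)

DEFAULT_CONFIDENCE_CUTOFF = 0.80


class GraftError(StructureError):
    pass


class Route(str, enum.Enum):
    KEEP_AF2 = "KEEP_AF2"
    GRAFT = "GRAFT"
    PSPM = "PSPM"


@dataclass(frozen=True)
class RoutingDecision:
    route: Route
    mean_confidence: float  # [0, 1]
    template_id: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "route": self.route.value,
                "mean_confidence": self.mean_confidence,
                "template_id": self.template_id,
            }
        )


@dataclass
class LoopTemplate:
    """An experimentally derived CDR-H3 loop keyed by its sequence."""

    sequence: str
    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self):
        if len(self.residues) < 4:
            raise StructureError("template loop must have length >= 4")
        seq = "".join(r.aa for r in self.residues)
        if seq.upper() != self.sequence.upper():
            raise StructureError(
                f"template key {self.sequence!r} does not match stored loop {seq!r}"
            )


@dataclass
class H3TemplateDB:
    entries: dict[str, LoopTemplate] = field(default_factory=dict)

    def add(self, template: LoopTemplate) -> None:
        self.entries[template.sequence.upper()] = template

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, directory: str | Path) -> None:
        """Serialise as a directory of loop PDB files plus a JSON index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = {}
        for i, (seq, tpl) in enumerate(sorted(self.entries.items())):
            fname = f"loop_{i:04d}.pdb"
            loop_struct = AntibodyStructure(chains={"H": tpl.residues},
                                            source=tpl.source_id)
            (directory / fname).write_text(write_structure(loop_struct))
            index[seq] = {"file": fname, "source_pdb_id": tpl.source_id}
        (directory / "index.json").write_text(json.dumps(index, indent=1))

    @staticmethod
    def load(directory: str | Path) -> "H3TemplateDB":
        directory = Path(directory)
        index = json.loads((directory / "index.json").read_text())
        db = H3TemplateDB()
        for seq, meta in index.items():
            s = parse_structure((directory / meta["file"]).read_text())
            (chain,) = s.chains.values()
            db.add(LoopTemplate(sequence=seq, residues=chain,
                                source_id=meta.get("source_pdb_id", "")))
        return db


def extract_loop(s: AntibodyStructure, ann: H3Annotation, source_id: str = "") -> LoopTemplate:
    """Cut the annotated loop out of a structure as a graftable template."""
    ann.require_graftable()
    chain = s.chain(ann.chain_id)
    residues = [
        replace(r, atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms])
        for r in chain[ann.start_index : ann.end_index + 1]
    ]
    seq = "".join(r.aa for r in residues)
    return LoopTemplate(sequence=seq, residues=residues, source_id=source_id)


def cbm_decide(
    confidences: list[float | None],
    ann: H3Annotation,
    cutoff: float = DEFAULT_CONFIDENCE_CUTOFF,
) -> tuple[float, bool]:
    """Mean H3 confidence on the 0-1 scale and the strict-> acceptance flag.

    ``confidences`` is the full per-residue list (0-100 scale) for the
    annotated chain; every H3 residue must carry a value (no imputation).
    """
    vals = []
    for i in ann.indices:
        if i >= len(confidences) or confidences[i] is None:
            raise StructureError(
                f"missing confidence for H3 residue index {i}; no imputation is applied"
            )
        vals.append(confidences[i] / 100.0)
    mean_conf = float(np.mean(vals))
    return mean_conf, mean_conf > cutoff


def tgm_lookup(h3_seq: str, db: H3TemplateDB) -> LoopTemplate | None:
    """Exact (case-insensitive, full-sequence) template match, else None."""
    if len(h3_seq) < 4:
        raise StructureError("template lookup requires a loop sequence of length >= 4")
    return db.entries.get(h3_seq.upper())


_ANCHOR_ATOMS = (("n", 0, "CA"), ("n", 0, "C"), ("n", 1, "CA"), ("n", 1, "C"),
                 ("c", -2, "CA"), ("c", -2, "N"), ("c", -1, "CA"), ("c", -1, "N"))


def _anchor_coords(residues: list[Residue]) -> np.ndarray:
    coords = []
    for _, off, name in _ANCHOR_ATOMS:
        r = residues[off]
        a = r.atom(name)
        if a is None:
            raise GraftError(
                f"missing anchor atom {name} on loop residue {r.aa}{r.author_number}"
            )
        coords.append(a.coord)
    return np.array(coords)


def graft_loop(
    model: AntibodyStructure,
    ann: H3Annotation,
    template: LoopTemplate,
) -> tuple[AntibodyStructure, float]:
    """Replace the model's H3 loop with a rigidly fitted template copy.

    Returns the grafted structure and the achieved anchor RMSD (the
    Kabsch-optimal RMSD over the 8 anchor atoms). Atoms outside the span are
    byte-for-byte unchanged; grafted side chains come from the template
    verbatim.
    """
    ann.require_graftable()
    chain = model.chain(ann.chain_id)
    loop = chain[ann.start_index : ann.end_index + 1]
    model_seq = "".join(r.aa for r in loop)
    if model_seq.upper() != template.sequence.upper():
        raise GraftError(
            f"template sequence {template.sequence!r} does not match "
            f"model H3 sequence {model_seq!r}"
        )
    tpl_anchor = _anchor_coords(template.residues)
    mdl_anchor = _anchor_coords(loop)
    tf = kabsch(tpl_anchor, mdl_anchor)
    anchor_rmsd = rmsd(tf.apply(tpl_anchor), mdl_anchor)

    out = model.copy()
    new_chain = out.chain(ann.chain_id)
    for k, i in enumerate(ann.indices):
        src = template.residues[k]
        keep = new_chain[i]
        new_chain[i] = replace(
            src,
            seq_index=keep.seq_index,
            author_number=keep.author_number,
            atoms=[replace(a, coord=tf.apply(a.coord)) for a in src.atoms],
        )
    return out, anchor_rmsd


def route(
    model: AntibodyStructure,
    ann: H3Annotation,
    confidences: list[float | None],
    db: H3TemplateDB | None,
    cutoff: float = DEFAULT_CONFIDENCE_CUTOFF,
    cbm_first: bool = True,
) -> RoutingDecision:
    """Total routing decision: confidence gate, then template, else network.

    ``cbm_first=False`` flips the precedence so an exact-sequence template
    wins even over a high-confidence loop.
    """
    mean_conf, accept = cbm_decide(confidences, ann, cutoff=cutoff)
    h3_seq = model.sequence(ann.chain_id)[ann.start_index : ann.end_index + 1]
    template = tgm_lookup(h3_seq, db) if db is not None and len(db) else None
    if cbm_first:
        if accept:
            return RoutingDecision(Route.KEEP_AF2, mean_conf)
        if template is not None:
            return RoutingDecision(Route.GRAFT, mean_conf,
                                   template_id=template.source_id or template.sequence)
    else:
        if template is not None:
            return RoutingDecision(Route.GRAFT, mean_conf,
                                   template_id=template.source_id or template.sequence)
        if accept:
            return RoutingDecision(Route.KEEP_AF2, mean_conf)
    return RoutingDecision(Route.PSPM, mean_conf)
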