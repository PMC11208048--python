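"""End-to-end loop optimization: route, then keep / graft / predict+refine."""

from __future__ import annotations

from dataclasses import dataclass, field

from .featurize import featurize
from .refine import RestraintSpec, apply_predicted_calphas, idealize_loop
from .structures import AntibodyStructure, H3Annotation
from .templates import (
    DEFAULT_CONFIDENCE_CUTOFF,
    H3TemplateDB,
    Route,
    RoutingDecision,
    graft_loop,
    route,
    tgm_lookup,
)


@dataclass
class PipelineReport:
    decision: RoutingDecision
    anchor_rmsd: float | None = None
    geometry: dict | None = None
    metrics: dict | None = None

    def as_dict(self) -> dict:
        return {
            "route": self.decision.route.value,
            "mean_confidence": self.decision.mean_confidence,
            "template_id": self.decision.template_id,
            "anchor_rmsd": self.anchor_rmsd,
            "geometry": self.geometry,
            "metrics": self.metrics,
        }


def run_pipeline(
    model: AntibodyStructure,
    ann: H3Annotation,
    confidences: list[float | None] | None = None,
    template_db: H3TemplateDB | None = None,
    pspm_model=None,
    cutoff: float = DEFAULT_CONFIDENCE_CUTOFF,
    cbm_first: bool = True,
    restraints: RestraintSpec = RestraintSpec(),
    native: AntibodyStructure | None = None,
) -> tuple[AntibodyStructure, PipelineReport]:
    """Optimize one model's CDR-H3 loop.

    High-confidence loops pass through untouched; exact-sequence templates
    are grafted; otherwise the coordinate network predicts the loop CA
    trace, which is written back and geometrically idealized. When a
    ``native`` reference is supplied the report carries loop metrics.
    """
    if confidences is None:
        confidences = model.confidences(ann.chain_id)
    decision = route(model, ann, confidences, template_db,
                     cutoff=cutoff, cbm_first=cbm_first)
    report = PipelineReport(decision=decision)

    if decision.route is Route.KEEP_AF2:
        result = model.copy()
    elif decision.route is Route.GRAFT:
        h3_seq = model.sequence(ann.chain_id)[ann.start_index : ann.end_index + 1]
        template = tgm_lookup(h3_seq, template_db)
        result, anchor_rmsd = graft_loop(model, ann, template)
        report.anchor_rmsd = anchor_rmsd
    else:
        if pspm_model is None:
            raise ValueError(
                "routing selected the coordinate network but no trained "
                "PSPM checkpoint/model was provided"
            )
        feats = featurize(model, ann)
        coords = pspm_model.forward(feats)
        moved = apply_predicted_calphas(model, ann, coords)
        result, geom = idealize_loop(moved, ann, restraints)
        report.geometry = {
            "max_bond_dev_A": geom.max_bond_dev_after,
            "clash_count_before": geom.clash_count_before,
            "clash_count_after": geom.clash_count_after,
            "converged": geom.converged,
        }

    if native is not None:
        from .metrics import evaluate_model

        report.metrics = evaluate_model(result, native, ann).__dict__
    return result, report
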