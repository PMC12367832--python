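"""End-to-end classification of a chemical through all three lines of evidence.

Order of evaluation: (1) in silico indications and hazard tags; (2) the
bioactivity matrix of the parent and any metabolites, with the outlier
rule, worst-cased across the family and forced to High when an indicated
hazard has no matching assay; (3) simulated and/or externally supplied
Cmax predictions aggregated worst-case; (4) the TD x TK combination matrix
and the weight-of-evidence review.  Coverage gaps are absorbed into the
bioactivity axis (then the matrix applies), so a high-bioactivity /
low-bioavailability chemical lands at Medium overall even when its panel
was incomplete — matching the published worked examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .bioactivity import (
    CapabilityMap,
    SeverityLexicon,
    apply_outlier_rule,
    coverage_check,
    worst_case_family,
)
from .bioavailability import aggregate_models, simulate_cmax
from .datamodel import (
    AssayResult,
    CmaxPrediction,
    FrameworkConfig,
    IndicationLevel,
    Level,
    LevelOfConcern,
    ModelPrediction,
    OverallResult,
    PKParameters,
    Provenance,
    WoEChecklist,
)
from .insilico import categorize_insilico, indicated_hazards
from .overall import combine, evaluate_woe

log = logging.getLogger("namloc.pipeline")


@dataclass
class ChemicalAssessment:
    """Everything the framework concluded about one chemical."""

    chem_id: str
    indication: Optional[IndicationLevel]
    td_loc: LevelOfConcern
    tk_level: Level
    overall_result: OverallResult
    uncovered: list[str]
    outlier_flag: Optional[str] = None
    cmax_um: Optional[float] = None


def classify_chemical(
    *,
    chem_id: str,
    config: Optional[FrameworkConfig] = None,
    lexicon: Optional[SeverityLexicon] = None,
    capability_map: Optional[CapabilityMap] = None,
    predictions: Optional[Sequence[ModelPrediction]] = None,
    insilico_override: Optional[str] = None,
    assays: Optional[Sequence[AssayResult]] = None,
    metabolite_assays: Optional[Mapping[str, Sequence[AssayResult]]] = None,
    pk: Optional[PKParameters] = None,
    cmax_predictions: Optional[Sequence[CmaxPrediction]] = None,
    hazard_indications: Optional[Sequence[str]] = None,
    woe: Optional[WoEChecklist] = None,
) -> ChemicalAssessment:
    """Classify one chemical from whatever evidence is available.

    Missing evidence never lowers concern: absent bioactivity or
    bioavailability data defaults the corresponding axis to High through
    insufficient evidence.
    """
    cfg = config or FrameworkConfig()
    lexicon = lexicon or SeverityLexicon.default()
    cmap = capability_map or CapabilityMap.default()
    audit_extra: list[str] = []

    # 1. in silico indication and hazard tags for the coverage check
    indication = None
    if predictions:
        indication = categorize_insilico(
            predictions,
            strong_min_endpoints=cfg.strong_min_endpoints,
            negative_predominance=cfg.negative_predominance,
            override=insilico_override,
        )
    if hazard_indications is not None:
        hazards = list(hazard_indications)
    elif predictions:
        hazards = indicated_hazards(predictions)
    else:
        hazards = []

    # 2. bioactivity (TD), worst-cased over the parent/metabolite family
    metabolite_assays = metabolite_assays or {}
    outlier_flag = None
    all_panels: list[AssayResult] = list(assays or [])
    for panel in metabolite_assays.values():
        all_panels.extend(panel)
    if assays is None and not metabolite_assays:
        td_loc = LevelOfConcern(Level.HIGH, Provenance.DEFAULT_INSUFFICIENT_EVIDENCE)
        audit_extra.append("no bioactivity data: TD defaulted to High")
        uncovered = list(hazards)
    else:
        parent_loc, outlier_flag = apply_outlier_rule(
            list(assays or []), cfg.potency_cutoffs, lexicon, cfg.ruleset,
            cfg.outlier_min_concordant,
        ) if assays else (LevelOfConcern(Level.LOW), None)
        family = []
        for met_id, panel in metabolite_assays.items():
            met_loc, _ = apply_outlier_rule(
                list(panel), cfg.potency_cutoffs, lexicon, cfg.ruleset,
                cfg.outlier_min_concordant,
            )
            family.append(met_loc)
            audit_extra.append(f"metabolite {met_id}: bioactivity {met_loc.level.value}")
        td_loc = worst_case_family(parent_loc, family)
        uncovered = coverage_check(hazards, all_panels, cmap)
        if uncovered:
            audit_extra.append(
                f"hazard indications {uncovered} have no matching assay: "
                f"TD {td_loc.level.value} -> High (insufficient evidence)"
            )
            td_loc = LevelOfConcern(Level.HIGH, Provenance.DEFAULT_INSUFFICIENT_EVIDENCE)

    # 3. bioavailability (TK), worst case over simulated + external models
    cmax = None
    preds: list[CmaxPrediction] = list(cmax_predictions or [])
    if pk is not None:
        cmax = simulate_cmax(pk, cfg.protocol(), cfg.physiology())
        preds.append(CmaxPrediction(chem_id, "one_compartment_ivive", cmax,
                                    pk.input_source))
    tk_defaulted = False
    if preds:
        tk_level = aggregate_models(preds, cfg.bioavailability_cutoffs, cfg.insilico_uf)
    else:
        tk_level = Level.HIGH
        tk_defaulted = True
        audit_extra.append("no bioavailability data: TK defaulted to High")

    # 4. combination matrix + weight of evidence
    woe = woe or WoEChecklist.all_yes()
    preliminary = combine(td_loc.level, tk_level, cfg.epaa_matrix)
    # coverage gaps were absorbed into the TD axis above; pass none here so
    # the matrix (not a blanket High) decides, per the worked examples
    result = evaluate_woe(
        preliminary, woe, uncovered_hazards=(),
        chem_id=chem_id, td=td_loc.level, tk=tk_level,
        raise_policy=cfg.woe_raise_policy,
    )
    result.audit = audit_extra + result.audit
    if (td_loc.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE
            or tk_defaulted) and result.overall.provenance is Provenance.EVIDENCE_BASED:
        result.overall = LevelOfConcern(
            result.overall.level, Provenance.DEFAULT_INSUFFICIENT_EVIDENCE
        )
        result.audit.append("provenance: insufficiency default propagated from an axis")
    log.info("%s: TD=%s TK=%s overall=%s", chem_id, td_loc.level.value,
             tk_level.value, result.overall.label)
    return ChemicalAssessment(
        chem_id=chem_id,
        indication=indication,
        td_loc=td_loc,
        tk_level=tk_level,
        overall_result=result,
        uncovered=list(uncovered),
        outlier_flag=outlier_flag,
        cmax_um=cmax,
    )


def classify_dataset(
    chemicals: Sequence[Mapping],
    config: Optional[FrameworkConfig] = None,
    lexicon: Optional[SeverityLexicon] = None,
    capability_map: Optional[CapabilityMap] = None,
) -> list[ChemicalAssessment]:
    """Classify a sequence of per-chemical keyword mappings."""
    lexicon = lexicon or SeverityLexicon.default()
    cmap = capability_map or CapabilityMap.default()
    return [
        classify_chemical(config=config, lexicon=lexicon, capability_map=cmap, **chem)
        for chem in chemicals
    ]
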