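"""Rule engine turning per-model (Q)SAR outputs into a toxicity indication.

Predictions are screened for usability (in the applicability domain,
reliable, relevant, non-equivocal) and then combined across endpoints into
a five-band indication: low < low_moderate < moderate < moderate_high <
strong.  Only the conservative promotion onto Low/Medium/High propagates
downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

from .datamodel import IndicationLevel, ModelPrediction
from .errors import InsufficientInputError, ValidationError

log = logging.getLogger("namloc.insilico")


def categorize_insilico(
    predictions: Sequence[ModelPrediction],
    *,
    strong_min_endpoints: int = 2,
    negative_predominance: float = 0.75,
    override: Optional[str] = None,
) -> IndicationLevel:
    """Assign a toxicity-indication band from one chemical's predictions.

    A *strong* indication requires at least ``strong_min_endpoints``
    endpoints each showing a usable positive with no usable negative for the
    same endpoint from another model.  A *low* indication requires every
    usable prediction to be negative and every endpoint to carry at least
    one usable prediction.  Everything else is *moderate*, refined to
    *moderate_high* when at least one endpoint is consistently positive, or
    to *low_moderate* when usable predictions are predominantly negative
    (> ``negative_predominance`` of usable predictions) without any
    consistently positive endpoint.

    An explicit expert ``override`` band is honoured and logged.
    """
    if not predictions:
        raise InsufficientInputError(
            "no (Q)SAR predictions supplied; the chemical is not assessable in silico"
        )
    chems = {p.chem_id for p in predictions}
    if len(chems) > 1:
        raise ValidationError(f"predictions span multiple chemicals: {sorted(chems)}")

    if override is not None:
        log.info("%s: expert override -> %s", predictions[0].chem_id, override)
        return IndicationLevel(override, rationale=("expert_override",))

    by_endpoint: dict[str, list[ModelPrediction]] = defaultdict(list)
    for p in predictions:
        by_endpoint[p.endpoint].append(p)

    usable = [p for p in predictions if p.usable]
    n_pos = sum(1 for p in usable if p.outcome == "positive")
    n_neg = sum(1 for p in usable if p.outcome == "negative")
    unusable_positives = sum(
        1 for p in predictions if not p.usable and p.outcome == "positive"
    )

    # endpoints with >=1 usable positive and no usable negative from any model
    consistent_positive = []
    for ep, preds in by_endpoint.items():
        ep_usable = [p for p in preds if p.usable]
        if any(p.outcome == "positive" for p in ep_usable) and not any(
            p.outcome == "negative" for p in ep_usable
        ):
            consistent_positive.append(ep)

    every_endpoint_usable = all(
        any(p.usable for p in preds) for preds in by_endpoint.values()
    )

    rationale: list[str] = []
    if len(consistent_positive) >= strong_min_endpoints:
        band = "strong"
        rationale.append(
            f"strong: {len(consistent_positive)} endpoints consistently positive "
            f"({', '.join(sorted(consistent_positive))})"
        )
    elif usable and n_pos == 0 and every_endpoint_usable:
        band = "low"
        rationale.append(
            f"low: all {len(usable)} usable predictions negative across "
            f"{len(by_endpoint)} endpoints, every endpoint covered"
        )
    elif consistent_positive and len(consistent_positive) < len(by_endpoint):
        band = "moderate_high"
        rationale.append(
            "moderate_high: endpoint(s) "
            f"{', '.join(sorted(consistent_positive))} consistently positive, "
            "remaining endpoints mixed or unusable"
        )
    elif usable and n_neg / len(usable) > negative_predominance:
        band = "low_moderate"
        rationale.append(
            f"low_moderate: {n_neg}/{len(usable)} usable predictions negative "
            f"(> {negative_predominance:.0%}), residual positives unusable "
            f"({unusable_positives})"
        )
    else:
        band = "moderate"
        rationale.append("moderate: indeterminate mixture of signals")

    level = IndicationLevel(band, rationale=tuple(rationale))
    log.info(
        "%s: in silico indication %s -> conservative %s (%s)",
        predictions[0].chem_id, band, level.conservative_level.value, rationale[0],
    )
    return level


def indicated_hazards(predictions: Sequence[ModelPrediction]) -> list[str]:
    """Endpoints carrying at least one usable positive prediction.

    These hazard tags drive the in vitro coverage check: an indicated hazard
    with no matching assay forces the bioactivity level to High through
    insufficient evidence.
    """
    tags = []
    by_endpoint: dict[str, list[ModelPrediction]] = defaultdict(list)
    for p in predictions:
        by_endpoint[p.endpoint].append(p)
    for ep, preds in sorted(by_endpoint.items()):
        if any(p.usable and p.outcome == "positive" for p in preds):
            tags.append(ep)
    return tags
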