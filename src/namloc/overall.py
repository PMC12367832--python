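"""Overall assessment: the TD x TK combination matrix and the exclusionary
weight-of-evidence review.

The preliminary level comes from a 3x3 matrix over the bioactivity (TD) and
bioavailability (TK) categories.  Eight structured questions then challenge
it: an uncovered hazard indication or doubt about whether the right
molecule / assay range was assessed defaults the chemical to High through
insufficient evidence; failed consistency questions raise the level one
step.  No path through this module lowers a level on missing information.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .datamodel import (
    DEFAULT_EPAA_MATRIX,
    EPAAMatrix,
    Level,
    LevelOfConcern,
    OverallResult,
    Provenance,
    WoEChecklist,
)
from .errors import ValidationError

log = logging.getLogger("namloc.overall")


def combine(td: Level, tk: Level, matrix: Optional[EPAAMatrix] = None) -> Level:
    """Preliminary overall level from the TD x TK combination matrix."""
    matrix = matrix or DEFAULT_EPAA_MATRIX
    level = matrix[(td, tk)]
    log.info("combine TD=%s TK=%s -> %s", td.value, tk.value, level.value)
    return level


def evaluate_woe(
    preliminary: Level,
    woe: WoEChecklist,
    uncovered_hazards: Sequence[str] = (),
    *,
    chem_id: str = "",
    td: Optional[Level] = None,
    tk: Optional[Level] = None,
    raise_policy: str = "raise_one",
) -> OverallResult:
    """Apply the exclusion principle to a preliminary level.

    Forcing clauses, in order:

    * uncovered hazard indications, or q1 (correct molecule) / q4 (assay
      range sufficient) answered no/unknown -> High with
      default-through-insufficiency provenance;
    * any of q5-q8 (consistency and strength-of-evidence questions)
      answered no -> the preliminary level raised per ``raise_policy``
      (default one step, capped at High), citing the question;
    * otherwise the preliminary level stands with evidence-based provenance.

    q2 (in silico indicator) and q3 (studied analogues) are contextual and
    recorded in the audit without forcing.
    """
    if raise_policy not in ("ignore", "raise_one", "force_high"):
        raise ValidationError(f"unknown raise_policy {raise_policy!r}")
    audit: list[str] = []
    a = woe.answers

    insufficient = list(uncovered_hazards)
    for q in ("q1_correct_molecule", "q4_assay_range_sufficient"):
        if a[q] in ("no", "unknown"):
            audit.append(f"{q}={a[q]}: insufficient evidence, defaulting to High")
    if insufficient:
        audit.append(
            f"uncovered hazard indications {sorted(insufficient)}: "
            "insufficient evidence, defaulting to High"
        )
    if audit:
        overall = LevelOfConcern(Level.HIGH, Provenance.DEFAULT_INSUFFICIENT_EVIDENCE)
        return _result(chem_id, td, tk, preliminary, overall, woe, audit)

    failed = [q for q in ("q5_subcytotoxic_effects", "q6_bioactivity_consistency",
                          "q7_bioavailability_evidence", "q8_bioavailability_consistency")
              if a[q] == "no"]
    for q in ("q2_insilico_indicator", "q3_studied_analogues"):
        if a[q] != "yes":
            audit.append(f"{q}={a[q]} (contextual, not forcing)")
    if failed:
        if raise_policy == "force_high":
            level = Level.HIGH
        elif raise_policy == "raise_one":
            level = preliminary.raised(1)
        else:
            level = preliminary
        audit.append(
            f"{'+'.join(failed)}=no: preliminary {preliminary.value} "
            f"-> {level.value} ({raise_policy})"
        )
        overall = LevelOfConcern(level, Provenance.EVIDENCE_BASED)
    else:
        audit.append("all forcing questions answered yes: preliminary level stands")
        overall = LevelOfConcern(preliminary, Provenance.EVIDENCE_BASED)
    return _result(chem_id, td, tk, preliminary, overall, woe, audit)


def _result(chem_id, td, tk, preliminary, overall, woe, audit) -> OverallResult:
    log.info("%s: preliminary %s -> overall %s", chem_id or "<chemical>",
             preliminary.value, overall.label)
    return OverallResult(
        chem_id=chem_id,
        td=td if td is not None else preliminary,
        tk=tk if tk is not None else preliminary,
        overall=overall,
        woe=woe,
        audit=audit,
    )


def label_insufficiency(result: OverallResult) -> str:
    """Display label distinguishing evidence-based from defaulted outcomes."""
    loc = result.overall
    if loc.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE:
        if loc.level is Level.HIGH:
            return "H* — assumed to be of high concern through lack of evidence"
        return f"{loc.level.value}* — an axis was defaulted through lack of evidence"
    return loc.level.value
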