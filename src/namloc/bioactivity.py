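"""Bioactivity assessment: potency banding, severity assignment and the
potency x severity matrix mapped to a level of concern.

Each active assay is banded by its AC50 (High < 0.1 µM, Medium 0.1-10 µM,
Low > 10 µM by default; boundaries belong to the closed middle band) and
assigned an implied severity from its ToxCast-style descriptors via a
first-match-wins lexicon.  The cross-tabulated matrix is mapped to a level
of concern by a selectable rule set, with an outlier demotion rule, a
coverage check against in silico hazard indications, and worst-casing
across a parent/metabolite family.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .datamodel import (
    AssayResult,
    BioactivityMatrix,
    Level,
    LevelOfConcern,
    Provenance,
    RuleSet,
)
from .errors import ValidationError

log = logging.getLogger("namloc.bioactivity")


def band_potency(ac50_um: float, cutoffs: tuple[float, float] = (0.1, 10.0)) -> Level:
    """Band an AC50 (µM): High below ``high_below``, Low above ``low_above``,
    Medium otherwise (boundaries inclusive in Medium)."""
    if not (isinstance(ac50_um, (int, float)) and math.isfinite(ac50_um) and ac50_um > 0):
        raise ValidationError(f"AC50 must be positive and finite, got {ac50_um!r}")
    high_below, low_above = cutoffs
    if ac50_um < high_below:
        return Level.HIGH
    if ac50_um > low_above:
        return Level.LOW
    return Level.MEDIUM


# --- severity lexicon ------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    target_family: str
    target_subfamily: str
    biological_process: str
    severity: Level
    note: str = ""

    def matches(self, assay: AssayResult) -> bool:
        def ok(pattern: str, value: str) -> bool:
            return pattern == "*" or pattern.strip().lower() == value.strip().lower()
        return (
            ok(self.target_family, assay.target_family)
            and ok(self.target_subfamily, assay.target_subfamily)
            and ok(self.biological_process, assay.biological_process)
        )


class SeverityLexicon:
    """Ordered list of descriptor->severity rules; first match wins.

    A total fallback entry (all wildcards) is required so every assay is
    resolvable.  The shipped default rates cytotoxicity/proliferation and
    steroid-receptor agonism High, steroidogenesis and transcription-factor
    modulation Medium, and metabolic-enzyme / antagonist-reporter /
    PPAR-type readouts Low, with unknown descriptors falling back to Medium.
    """

    def __init__(self, entries: Sequence[LexiconEntry]):
        if not entries:
            raise ValidationError("severity lexicon must not be empty")
        last = entries[-1]
        if not (last.target_family == "*" and last.target_subfamily == "*"
                and last.biological_process == "*"):
            raise ValidationError("severity lexicon must end with a fallback (*,*,*) entry")
        self.entries = list(entries)

    def lookup(self, assay: AssayResult) -> tuple[Level, int]:
        """Return (severity, index of matched entry)."""
        for i, entry in enumerate(self.entries):
            if entry.matches(assay):
                return entry.severity, i
        raise AssertionError("unreachable: fallback entry guarantees totality")

    @classmethod
    def from_csv(cls, path) -> "SeverityLexicon":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries.append(LexiconEntry(
                    row["target_family"], row["target_subfamily"],
                    row["biological_process"], Level.from_str(row["severity"]),
                    row.get("note", ""),
                ))
        return cls(entries)

    @classmethod
    def default(cls) -> "SeverityLexicon":
        ref = resources.files("namloc.data").joinpath("severity_lexicon.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def assign_severity(assay: AssayResult, lexicon: SeverityLexicon) -> Level:
    """Implied severity of an assay from its descriptors (total by fallback)."""
    severity, idx = lexicon.lookup(assay)
    log.debug("%s/%s: severity %s (lexicon entry %d: %s)",
              assay.chem_id, assay.assay_name, severity.value, idx,
              lexicon.entries[idx].note)
    return severity


# --- matrix ----------------------------------------------------------------

def build_matrix(
    assays: Sequence[AssayResult],
    cutoffs: tuple[float, float],
    lexicon: SeverityLexicon,
) -> BioactivityMatrix:
    """Cross-tabulate active assays into (potency, severity) cells.

    Every active assay increments exactly one cell; inactive assays count
    toward ``n_inactive``.  All assays must share one chem_id.
    """
    chems = {a.chem_id for a in assays}
    if len(chems) > 1:
        raise ValidationError(f"assays span multiple chemicals: {sorted(chems)}")
    counts: dict[tuple[Level, Level], int] = {}
    n_inactive = 0
    for a in assays:
        if not a.active:
            n_inactive += 1
            continue
        cell = (band_potency(a.ac50_um, cutoffs), assign_severity(a, lexicon))
        counts[cell] = counts.get(cell, 0) + 1
    return BioactivityMatrix(counts=counts, n_inactive=n_inactive, n_assays=len(assays))


def matrix_to_loc(matrix: BioactivityMatrix, ruleset: RuleSet) -> LevelOfConcern:
    """Map a matrix to its level of concern: the maximum of the rule set over
    occupied cells.  A matrix with no active assays is Low on this axis
    (panel coverage is judged separately by the coverage check)."""
    occupied = matrix.occupied
    if not occupied:
        return LevelOfConcern(Level.LOW, Provenance.EVIDENCE_BASED)
    level = max(ruleset[cell] for cell in occupied)
    log.info("bioactivity matrix -> %s under ruleset %s", level.value, ruleset.name)
    return LevelOfConcern(level, Provenance.EVIDENCE_BASED)


def apply_outlier_rule(
    assays: Sequence[AssayResult],
    cutoffs: tuple[float, float],
    lexicon: SeverityLexicon,
    ruleset: RuleSet,
    min_concordant: int = 3,
) -> tuple[LevelOfConcern, Optional[str]]:
    """Level of concern with the single-outlier demotion rule applied.

    If the level-setting cell is occupied by exactly one assay and at least
    ``min_concordant`` other active assays of the same target family sit one
    or more potency bands lower, the lone assay is demoted to the highest
    band among its concordant family and the level recomputed.  Returns the
    (possibly adjusted) level and the demoted assay's name, or ``None`` when
    the rule did not fire.
    """
    matrix = build_matrix(assays, cutoffs, lexicon)
    baseline = matrix_to_loc(matrix, ruleset)
    occupied = matrix.occupied
    if not occupied:
        return baseline, None
    top_cells = [c for c in occupied if ruleset[c] == baseline.level]
    if len(top_cells) != 1 or matrix.counts[top_cells[0]] != 1:
        return baseline, None
    top_cell = top_cells[0]

    active = [a for a in assays if a.active]
    lone = next(
        a for a in active
        if (band_potency(a.ac50_um, cutoffs), assign_severity(a, lexicon)) == top_cell
    )
    family = [
        a for a in active
        if a is not lone and a.target_family.lower() == lone.target_family.lower()
    ]
    lower = [a for a in family if band_potency(a.ac50_um, cutoffs) < top_cell[0]]
    if len(lower) < min_concordant:
        return baseline, None

    concordant_band = max(band_potency(a.ac50_um, cutoffs) for a in lower)
    demoted_counts = dict(matrix.counts)
    demoted_counts[top_cell] -= 1
    new_cell = (concordant_band, top_cell[1])
    demoted_counts[new_cell] = demoted_counts.get(new_cell, 0) + 1
    demoted = BioactivityMatrix(
        counts=demoted_counts, n_inactive=matrix.n_inactive, n_assays=matrix.n_assays
    )
    adjusted = matrix_to_loc(demoted, ruleset)
    log.info(
        "outlier rule: %s demoted from %s to %s potency (%d concordant %s assays); "
        "LoC %s -> %s",
        lone.assay_name, top_cell[0].value, concordant_band.value, len(lower),
        lone.target_family, baseline.level.value, adjusted.level.value,
    )
    return adjusted, lone.assay_name


# --- coverage --------------------------------------------------------------

class CapabilityMap:
    """Maps hazard tags to assay-descriptor patterns for the coverage check.

    A pattern is a case-insensitive substring tested against the assay name,
    descriptor fields and tissue; a hazard is covered when any of its
    patterns matches any assay in the panel.
    """

    def __init__(self, patterns: dict[str, list[str]]):
        self.patterns = {k.lower(): [p.lower() for p in v] for k, v in patterns.items()}

    @classmethod
    def from_csv(cls, path) -> "CapabilityMap":
        patterns: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                patterns.setdefault(row["hazard"].strip(), []).append(row["pattern"].strip())
        return cls(patterns)

    @classmethod
    def default(cls) -> "CapabilityMap":
        ref = resources.files("namloc.data").joinpath("capability_map.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def covers(self, hazard: str, panel: Iterable[AssayResult]) -> bool:
        pats = self.patterns.get(hazard.lower())
        if pats is None:
            log.warning("unknown hazard tag %r: treated as uncovered (conservative)", hazard)
            return False
        for assay in panel:
            haystack = " ".join([
                assay.assay_name, assay.target_family, assay.target_subfamily,
                assay.biological_process, assay.tissue,
            ]).lower()
            if any(p in haystack for p in pats):
                return True
        return False


def coverage_check(
    indications: Sequence[str],
    panel: Sequence[AssayResult],
    capability_map: Optional[CapabilityMap] = None,
) -> list[str]:
    """Hazard indications with no matching assay in the panel.

    A non-empty result means the panel cannot interrogate an indicated
    hazard; the caller must force the chemical's bioactivity level to High
    with default-through-insufficiency provenance.
    """
    cmap = capability_map or CapabilityMap.default()
    uncovered = [h for h in indications if not cmap.covers(h, panel)]
    if uncovered:
        log.info("uncovered hazard indications: %s", uncovered)
    return uncovered


def worst_case_family(
    parent: LevelOfConcern, metabolites: Sequence[LevelOfConcern] = ()
) -> LevelOfConcern:
    """Worst case across a parent and its metabolites (max level; keeps the
    insufficiency flag if the maximum carries it)."""
    return LevelOfConcern.worst_case([parent, *metabolites])
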