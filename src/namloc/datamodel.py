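"""Domain types for NAM-based level-of-concern classification.

The framework classifies chemicals into three ordered levels of concern
(Low < Medium < High) for repeat-dose systemic toxicity by combining three
lines of evidence: in silico toxicity indications, an in vitro bioactivity
potency x severity matrix, and a simulated 14-day oral Cmax as the
bioavailability metric.  Everything downstream is driven by the types
defined here.

Units are fixed by schema and never auto-converted: AC50 and Cmax in µM,
molecular weight in g/mol, intrinsic clearance in µL/min/10^6 hepatocytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, ValidationError


@total_ordering
class Level(Enum):
    """Ordered level of concern: Low < Medium < High."""

    LOW = "L"
    MEDIUM = "M"
    HIGH = "H"

    @property
    def rank(self) -> int:
        """Numeric rank (L=1, M=2, H=3) used for agreement offsets."""
        return {"L": 1, "M": 2, "H": 3}[self.value]

    def __lt__(self, other: "Level") -> bool:
        if not isinstance(other, Level):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def from_str(cls, s: str) -> "Level":
        key = s.strip().upper()
        aliases = {
            "L": "L", "LOW": "L",
            "M": "M", "MID": "M", "MEDIUM": "M",
            "H": "H", "HIGH": "H",
        }
        if key not in aliases:
            raise ValidationError(f"unknown level {s!r}; expected one of L/M/H")
        return cls(aliases[key])

    def raised(self, steps: int = 1) -> "Level":
        """Level raised by ``steps``, capped at High."""
        ranks = [Level.LOW, Level.MEDIUM, Level.HIGH]
        return ranks[min(self.rank - 1 + steps, 2)]


class Provenance(Enum):
    """How a level of concern was reached."""

    EVIDENCE_BASED = "evidence_based"
    DEFAULT_INSUFFICIENT_EVIDENCE = "default_insufficient_evidence"


@dataclass(frozen=True)
class LevelOfConcern:
    """A level of concern together with its provenance.

    The exclusionary weight-of-evidence method distinguishes a High that is
    supported by data from a High assumed through lack of evidence; reports
    must render the two differently.
    """

    level: Level
    provenance: Provenance = Provenance.EVIDENCE_BASED

    @property
    def label(self) -> str:
        if self.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE:
            return f"{self.level.value}* (defaulted through lack of evidence)"
        return self.level.value

    @staticmethod
    def worst_case(locs: Sequence["LevelOfConcern"]) -> "LevelOfConcern":
        """Maximum level across ``locs``; keeps the insufficiency flag of the max."""
        if not locs:
            raise ValidationError("worst_case requires at least one level")
        top = max(loc.level for loc in locs)
        at_top = [loc for loc in locs if loc.level == top]
        prov = Provenance.EVIDENCE_BASED
        if any(l.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE for l in at_top):
            prov = Provenance.DEFAULT_INSUFFICIENT_EVIDENCE
        return LevelOfConcern(top, prov)


@dataclass
class ChemicalRecord:
    """A chemical under assessment, optionally linked to metabolites."""

    chem_id: str
    name: str
    molecular_weight: float
    metabolite_ids: list[str] = field(default_factory=list)
    is_metabolite_of: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.molecular_weight > 0 and math.isfinite(self.molecular_weight)):
            raise ValidationError(
                f"{self.chem_id}: molecular_weight must be a positive finite g/mol value"
            )


@dataclass
class AssayResult:
    """One in vitro assay outcome with the descriptor fields used for severity.

    The six descriptor columns follow ToxCast summary exports; ``ac50_um``
    is present iff the assay is active.
    """

    chem_id: str
    assay_name: str
    target_family: str
    target_subfamily: str
    biological_process: str
    tissue: str
    active: bool
    ac50_um: Optional[float] = None
    row: Optional[int] = None  # source row, for error messages

    def __post_init__(self) -> None:
        where = f" (row {self.row})" if self.row is not None else ""
        if self.active:
            if self.ac50_um is None:
                raise ValidationError(
                    f"{self.chem_id}/{self.assay_name}{where}: active assay without AC50"
                )
            if not (self.ac50_um > 0 and math.isfinite(self.ac50_um)):
                raise ValidationError(
                    f"{self.chem_id}/{self.assay_name}{where}: AC50 must be positive and finite, "
                    f"got {self.ac50_um}"
                )
        elif self.ac50_um is not None:
            raise ValidationError(
                f"{self.chem_id}/{self.assay_name}{where}: inactive assay must not carry an AC50"
            )


# --- in silico -------------------------------------------------------------

OUTCOMES = ("positive", "negative", "equivocal")
TRISTATE = ("yes", "no", "unknown")


@dataclass
class ModelPrediction:
    """A single (Q)SAR model output for one chemical and endpoint."""

    chem_id: str
    model_id: str
    endpoint: str
    outcome: str
    in_domain: str = "unknown"
    reliable: str = "unknown"
    relevant: str = "unknown"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"outcome {self.outcome!r} not in {OUTCOMES}")
        for name in ("in_domain", "reliable", "relevant"):
            if getattr(self, name) not in TRISTATE:
                raise ValidationError(f"{name} {getattr(self, name)!r} not in {TRISTATE}")

    @property
    def usable(self) -> bool:
        """Usable evidence: not out-of-domain, not unreliable, not irrelevant,
        and not equivocal.  Equivocal outcomes are treated as unusable for
        both the strong and the low clause (conservative)."""
        return (
            self.in_domain != "no"
            and self.reliable != "no"
            and self.relevant != "no"
            and self.outcome != "equivocal"
        )


INDICATION_BANDS = ("low", "low_moderate", "moderate", "moderate_high", "strong")

#: Conservative promotion of intermediate indication bands onto the three
#: levels that feed the downstream assessment.
PROMOTION = {
    "low": Level.LOW,
    "low_moderate": Level.MEDIUM,
    "moderate": Level.MEDIUM,
    "moderate_high": Level.HIGH,
    "strong": Level.HIGH,
}


@dataclass(frozen=True)
class IndicationLevel:
    """Outcome of the in silico assessment: a five-band indication plus its
    conservative promotion to L/M/H and the rules that fired."""

    band: str
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.band not in INDICATION_BANDS:
            raise ValidationError(f"unknown indication band {self.band!r}")

    @property
    def conservative_level(self) -> Level:
        return PROMOTION[self.band]


# --- bioactivity -----------------------------------------------------------

@dataclass
class BioactivityMatrix:
    """Counts of active assays per (potency band, severity band) cell.

    Conservation invariant: the nine cells plus ``n_inactive`` sum to
    ``n_assays``.
    """

    counts: dict[tuple[Level, Level], int]
    n_inactive: int
    n_assays: int

    def __post_init__(self) -> None:
        full = {}
        for p in Level:
            for s in Level:
                full[(p, s)] = int(self.counts.get((p, s), 0))
                if full[(p, s)] < 0:
                    raise ValidationError("matrix cell counts must be non-negative")
        self.counts = full
        if self.n_inactive < 0:
            raise ValidationError("n_inactive must be non-negative")
        if sum(full.values()) + self.n_inactive != self.n_assays:
            raise ValidationError(
                "matrix does not conserve assays: "
                f"{sum(full.values())} active + {self.n_inactive} inactive != {self.n_assays}"
            )

    @property
    def occupied(self) -> list[tuple[Level, Level]]:
        return [cell for cell, n in self.counts.items() if n > 0]

    @property
    def n_active(self) -> int:
        return self.n_assays - self.n_inactive


@dataclass(frozen=True)
class RuleSet:
    """A total map from (potency, severity) cells to a level of concern.

    Three named rule sets are shipped: ``min_red`` (High only for high
    potency with high severity), ``max_red`` (more cells promoted, uniformly
    at least as conservative) and ``pot_only`` (severity ignored).
    """

    name: str
    cell_map: Mapping[tuple[Level, Level], Level]

    def __post_init__(self) -> None:
        for p in Level:
            for s in Level:
                if (p, s) not in self.cell_map:
                    raise ConfigError(f"ruleset {self.name!r} missing cell ({p.value},{s.value})")
        if self.name == "pot_only":
            for p in Level:
                vals = {self.cell_map[(p, s)] for s in Level}
                if len(vals) > 1:
                    raise ConfigError("pot_only ruleset must ignore severity")

    def __getitem__(self, cell: tuple[Level, Level]) -> Level:
        return self.cell_map[cell]


def _cells(spec: dict[tuple[str, str], str]) -> dict[tuple[Level, Level], Level]:
    return {
        (Level(p), Level(s)): Level(v) for (p, s), v in spec.items()
    }


#: Original matrix: High concern only when high potency meets high severity.
MIN_RED = RuleSet(
    "min_red",
    _cells({
        ("H", "H"): "H",
        ("H", "M"): "M", ("M", "H"): "M",
        ("H", "L"): "L", ("M", "M"): "L", ("M", "L"): "L",
        ("L", "H"): "L", ("L", "M"): "L", ("L", "L"): "L",
    }),
)

#: Revised matrix promoting more cells.  Uniformly >= min_red and <= pot_only
#: cell-by-cell, which keeps the three assessments ordered for every matrix;
#: low-potency cells therefore stay Low regardless of severity.
MAX_RED = RuleSet(
    "max_red",
    _cells({
        ("H", "H"): "H",
        ("H", "M"): "M", ("M", "H"): "M",
        ("H", "L"): "M", ("M", "M"): "M",
        ("M", "L"): "L", ("L", "H"): "L", ("L", "M"): "L", ("L", "L"): "L",
    }),
)

#: Potency-only assessment; severity dropped.
POT_ONLY = RuleSet(
    "pot_only",
    _cells({(p, s): p for p in ("H", "M", "L") for s in ("H", "M", "L")}),
)

RULESETS: dict[str, RuleSet] = {r.name: r for r in (MIN_RED, MAX_RED, POT_ONLY)}


# --- toxicokinetics --------------------------------------------------------

@dataclass
class PKParameters:
    """Minimal chemical-specific toxicokinetic inputs.

    clint is intrinsic hepatic clearance in µL/min/10^6 hepatocytes, fup the
    fraction unbound in plasma.  ``input_source`` records whether the inputs
    were measured in vitro or predicted in silico; the latter attracts an
    uncertainty factor on the simulated Cmax.
    """

    chem_id: str
    molecular_weight: float
    clint: float
    fup: float
    input_source: str = "in_vitro"
    ka: float = 1.0           # 1/h, first-order absorption
    vd: float = 1.0           # L/kg
    f_abs: float = 1.0        # fraction absorbed
    renal_mode: str = "gfr_fup"

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValidationError(f"{self.chem_id}: molecular_weight must be > 0")
        if self.clint < 0:
            raise ValidationError(f"{self.chem_id}: clint must be >= 0")
        if not (0 < self.fup <= 1):
            raise ValidationError(f"{self.chem_id}: fup must be in (0, 1]")
        if self.input_source not in ("in_vitro", "in_silico"):
            raise ValidationError(f"{self.chem_id}: input_source must be in_vitro or in_silico")
        if not self.ka > 0:
            raise ValidationError(f"{self.chem_id}: ka must be > 0")
        if not self.vd > 0:
            raise ValidationError(f"{self.chem_id}: vd must be > 0")
        if not (0 < self.f_abs <= 1):
            raise ValidationError(f"{self.chem_id}: f_abs must be in (0, 1]")
        if self.renal_mode not in ("gfr_fup", "none"):
            raise ValidationError(f"{self.chem_id}: renal_mode must be gfr_fup or none")


@dataclass
class Physiology:
    """Reference human physiology (default: 70 kg healthy adult male)."""

    body_weight: float = 70.0          # kg
    liver_blood_flow: float = 90.0     # L/h
    liver_mass: float = 1470.0         # g
    hepatocellularity: float = 110.0   # 10^6 cells per g liver
    gfr: float = 6.7                   # L/h

    def __post_init__(self) -> None:
        for name in ("body_weight", "liver_blood_flow", "liver_mass",
                     "hepatocellularity", "gfr"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"physiology field {name} must be > 0")


@dataclass
class DosingProtocol:
    """Standardised repeat-dose oral regimen: 0.1 mmol/kg once daily, 14 days."""

    dose: float = 0.1      # mmol/kg/day
    n_days: int = 14
    route: str = "oral"

    def __post_init__(self) -> None:
        from .errors import UnsupportedRouteError
        if not self.dose > 0:
            raise ValidationError("dose must be > 0")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.route != "oral":
            raise UnsupportedRouteError(
                f"route {self.route!r} not supported; only oral dosing is simulated"
            )


@dataclass
class CmaxPrediction:
    """An externally supplied per-model Cmax prediction (µM)."""

    chem_id: str
    model_name: str
    cmax_um: float
    input_source: str = "in_vitro"

    def __post_init__(self) -> None:
        if not (self.cmax_um >= 0 and math.isfinite(self.cmax_um)):
            raise ValidationError(f"{self.chem_id}/{self.model_name}: cmax_um must be finite and >= 0")
        if self.input_source not in ("in_vitro", "in_silico"):
            raise ValidationError(f"{self.chem_id}: input_source must be in_vitro or in_silico")


# --- overall assessment ----------------------------------------------------

WOE_QUESTIONS = (
    "q1_correct_molecule",
    "q2_insilico_indicator",
    "q3_studied_analogues",
    "q4_assay_range_sufficient",
    "q5_subcytotoxic_effects",
    "q6_bioactivity_consistency",
    "q7_bioavailability_evidence",
    "q8_bioavailability_consistency",
)


@dataclass
class WoEChecklist:
    """The eight structured weight-of-evidence questions, answered
    yes/no/unknown with free-text notes."""

    answers: dict[str, str]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [q for q in WOE_QUESTIONS if q not in self.answers]
        if missing:
            raise ValidationError(f"incomplete WoE checklist; missing {missing}")
        extra = [q for q in self.answers if q not in WOE_QUESTIONS]
        if extra:
            raise ValidationError(f"unknown WoE questions {extra}")
        for q, a in self.answers.items():
            if a not in TRISTATE:
                raise ValidationError(f"{q}: answer {a!r} not in {TRISTATE}")

    @classmethod
    def all_yes(cls) -> "WoEChecklist":
        return cls({q: "yes" for q in WOE_QUESTIONS})


@dataclass(frozen=True)
class EPAAMatrix:
    """The 3x3 toxicodynamics x toxicokinetics combination matrix.

    Must be total over the nine cells and monotone in both arguments:
    raising bioactivity or bioavailability never lowers the overall level.
    """

    cells: Mapping[tuple[Level, Level], Level]

    def __post_init__(self) -> None:
        for td in Level:
            for tk in Level:
                if (td, tk) not in self.cells:
                    raise ConfigError(f"EPAA matrix missing cell ({td.value},{tk.value})")
        order = [Level.LOW, Level.MEDIUM, Level.HIGH]
        for i, td in enumerate(order):
            for j, tk in enumerate(order):
                if i + 1 < 3 and self.cells[(order[i + 1], tk)] < self.cells[(td, tk)]:
                    raise ConfigError("EPAA matrix not monotone in TD")
                if j + 1 < 3 and self.cells[(td, order[j + 1])] < self.cells[(td, tk)]:
                    raise ConfigError("EPAA matrix not monotone in TK")

    def __getitem__(self, cell: tuple[Level, Level]) -> Level:
        return self.cells[cell]


#: Default combination matrix, anchored to the two worked examples:
#: (TD High, TK Mid) -> High and (TD High, TK Low) -> Mid.
DEFAULT_EPAA_MATRIX = EPAAMatrix(_cells({
    ("L", "L"): "L", ("L", "M"): "L", ("L", "H"): "M",
    ("M", "L"): "L", ("M", "M"): "M", ("M", "H"): "H",
    ("H", "L"): "M", ("H", "M"): "H", ("H", "H"): "H",
}))


@dataclass
class OverallResult:
    """Final per-chemical outcome with a full audit trail of rule firings."""

    chem_id: str
    td: Level
    tk: Level
    overall: LevelOfConcern
    woe: WoEChecklist
    audit: list[str] = field(default_factory=list)


@dataclass
class HeadingSet:
    """A chemical's set of CLP classification headings for the audit."""

    chem_id: str
    headings: frozenset[str]

    VOCABULARY = frozenset({"Carc", "Muta", "Repro", "STOT"})

    def __post_init__(self) -> None:
        self.headings = frozenset(self.headings)
        if not self.headings:
            raise ValidationError(f"{self.chem_id}: heading set must be non-empty")
        bad = self.headings - self.VOCABULARY
        if bad:
            raise ValidationError(f"{self.chem_id}: unknown headings {sorted(bad)}")


# --- configuration ---------------------------------------------------------

@dataclass
class FrameworkConfig:
    """All tunable knobs of the framework, with the published defaults.

    potency_cutoffs: (high_below, low_above) in µM — AC50 < high_below is
    High potency, > low_above is Low, boundaries belong to Medium.
    bioavailability_cutoffs: (low_below, high_above) in µM on the simulated
    14-day Cmax.  insilico_uf multiplies Cmax when the TK inputs were
    predicted in silico.
    """

    potency_cutoffs: tuple[float, float] = (0.1, 10.0)
    bioavailability_cutoffs: tuple[float, float] = (50.0, 500.0)
    ruleset_name: str = "min_red"
    epaa_matrix: EPAAMatrix = field(default_factory=lambda: DEFAULT_EPAA_MATRIX)
    insilico_uf: float = 3.0
    dose_mmol_per_kg: float = 0.1
    n_days: int = 14
    body_weight_kg: float = 70.0
    quantiles: tuple[float, float] = (0.25, 0.75)
    # secondary, config-exposed knobs
    woe_raise_policy: str = "raise_one"   # ignore | raise_one | force_high
    strong_min_endpoints: int = 2
    negative_predominance: float = 0.75
    outlier_min_concordant: int = 3

    def __post_init__(self) -> None:
        hi, lo = self.potency_cutoffs
        if not (0 < hi < lo):
            raise ConfigError(f"potency cutoffs must satisfy 0 < high_below < low_above, got {self.potency_cutoffs}")
        lo_b, hi_b = self.bioavailability_cutoffs
        if not (0 < lo_b < hi_b):
            raise ConfigError(f"bioavailability cutoffs must satisfy 0 < low_below < high_above, got {self.bioavailability_cutoffs}")
        if self.ruleset_name not in RULESETS:
            raise ConfigError(f"unknown ruleset {self.ruleset_name!r}")
        if self.insilico_uf < 1:
            raise ConfigError("insilico_uf must be >= 1")
        q_lo, q_hi = self.quantiles
        if not (0 < q_lo < q_hi < 1):
            raise ConfigError(f"quantiles must satisfy 0 < q_low < q_high < 1, got {self.quantiles}")
        if self.woe_raise_policy not in ("ignore", "raise_one", "force_high"):
            raise ConfigError(f"unknown woe_raise_policy {self.woe_raise_policy!r}")
        if not self.dose_mmol_per_kg > 0:
            raise ConfigError("dose_mmol_per_kg must be > 0")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not self.body_weight_kg > 0:
            raise ConfigError("body_weight_kg must be > 0")

    @property
    def ruleset(self) -> RuleSet:
        return RULESETS[self.ruleset_name]

    def protocol(self) -> DosingProtocol:
        return DosingProtocol(dose=self.dose_mmol_per_kg, n_days=self.n_days)

    def physiology(self) -> Physiology:
        return Physiology(body_weight=self.body_weight_kg)
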