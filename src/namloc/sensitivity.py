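"""Sensitivity sweeps, agreement tabulation and the heading-combination audit.

``sweep_criteria`` reclassifies a dataset under grids of potency cutoffs,
rule sets and bioavailability cutoffs and tabulates the category
distribution per setting.  ``agreement_table`` compares a NAM-derived
categorisation against a reference (offsets in category ranks).  The
heading audit partitions high-concern chemicals by their exact combination
of CLP headings (Carc / Muta / Repro / STOT) and evaluates how much of the
roster a battery of heading-specific test systems would identify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import FrameworkConfig, HeadingSet, Level
from .errors import ValidationError

log = logging.getLogger("namloc.sensitivity")


# --- criteria sweep --------------------------------------------------------

def sweep_criteria(
    dataset: Sequence[Mapping],
    config: FrameworkConfig,
    potency_grid: Sequence[tuple[float, float]] = ((0.1, 10.0),),
    rulesets: Sequence[str] = ("min_red",),
    bioavailability_grid: Sequence[tuple[float, float]] = ((50.0, 500.0),),
) -> pd.DataFrame:
    """Reclassify ``dataset`` under every grid setting; one row per setting
    with counts of chemicals per overall level.

    ``dataset`` is a sequence of per-chemical keyword mappings accepted by
    :func:`namloc.pipeline.classify_chemical`.
    """
    from dataclasses import replace
    from .pipeline import classify_chemical

    rows = []
    for pot in potency_grid:
        for rs in rulesets:
            for bio in bioavailability_grid:
                cfg = replace(config, potency_cutoffs=tuple(pot),
                              ruleset_name=rs,
                              bioavailability_cutoffs=tuple(bio))
                counts = {lvl: 0 for lvl in Level}
                for chem in dataset:
                    res = classify_chemical(config=cfg, **chem)
                    counts[res.overall_result.overall.level] += 1
                rows.append({
                    "potency_cutoffs": f"{pot[0]:g}/{pot[1]:g}",
                    "ruleset": rs,
                    "bioavailability_cutoffs": f"{bio[0]:g}/{bio[1]:g}",
                    "n_low": counts[Level.LOW],
                    "n_medium": counts[Level.MEDIUM],
                    "n_high": counts[Level.HIGH],
                })
    return pd.DataFrame(rows)


# --- agreement with a reference categorisation -----------------------------

@dataclass
class AgreementTable:
    """Offsets of a NAM categorisation relative to a reference.

    Offsets are rank(nam) - rank(reference) with L=1, M=2, H=3; counts sum
    to the number of compared chemicals.
    """

    counts: dict[int, int] = field(default_factory=dict)
    chemicals: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def agreement_table(nam: Mapping[str, Level], reference: Mapping[str, Level]) -> AgreementTable:
    """Tabulate per-chemical category offsets between two categorisations."""
    if set(nam) != set(reference):
        only_nam = sorted(set(nam) - set(reference))
        only_ref = sorted(set(reference) - set(nam))
        raise ValidationError(
            f"chemical sets differ: only in NAM {only_nam}, only in reference {only_ref}"
        )
    table = AgreementTable({o: 0 for o in (-2, -1, 0, 1, 2)},
                           {o: [] for o in (-2, -1, 0, 1, 2)})
    for chem in sorted(nam):
        offset = nam[chem].rank - reference[chem].rank
        table.counts[offset] += 1
        table.chemicals[offset].append(chem)
    return table


# --- CLP heading-combination audit -----------------------------------------

def combination_counts(sets: Sequence[HeadingSet]) -> dict[frozenset[str], int]:
    """Exact partition of chemicals by their full heading combination."""
    counts: dict[frozenset[str], int] = {}
    for hs in sets:
        counts[hs.headings] = counts.get(hs.headings, 0) + 1
    return counts


def subset_coverage(
    counts: Mapping[frozenset[str], int], battery: Sequence[str]
) -> tuple[int, int]:
    """Chemicals a battery of heading-specific test systems would identify.

    A chemical is covered when its heading combination intersects the
    battery.  Returns (covered count, percentage of the total roster,
    rounded half-up to a whole percent).
    """
    if not counts:
        raise ValidationError("combination counts must be non-empty")
    battery_set = frozenset(battery)
    bad = battery_set - HeadingSet.VOCABULARY
    if bad:
        raise ValidationError(f"battery outside vocabulary: {sorted(bad)}")
    total = sum(counts.values())
    covered = sum(n for combo, n in counts.items() if combo & battery_set)
    pct = int(math.floor(100.0 * covered / total + 0.5))
    return covered, pct


def multiplicity_counts(counts: Mapping[frozenset[str], int]) -> dict[str, int]:
    """Chemicals listed under exactly one, two, or three-to-four headings."""
    out = {"one": 0, "two": 0, "three_or_four": 0}
    for combo, n in counts.items():
        if len(combo) == 1:
            out["one"] += n
        elif len(combo) == 2:
            out["two"] += n
        else:
            out["three_or_four"] += n
    return out
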