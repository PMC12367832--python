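"""Published worked-example fixtures.

``fixture_chloroaniline`` transcribes the 19 active assays of
4-chloroaniline (major metabolite of 1-chloro-4-nitrobenzene) with their
ToxCast descriptors, implied severity and potency letters.  AC50 values are
synthetic band-midpoint placeholders consistent with the printed potency
letters — the source table prints letters, not concentrations.

``fixture_designathon_headings`` builds a synthetic roster of 48
high-concern chemicals whose CLP heading combinations reproduce the
published combination counts exactly.  ``fixture_category_pairs`` gives the
12 assessed chemicals' NAM and conventional levels; the offsets per
chemical are as published, the absolute levels of the agreeing chemicals
are a synthetic reconstruction consistent with the narrative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import AssayResult, HeadingSet, Level

#: Synthetic AC50 placeholders (µM) at the log-midpoint of each potency band.
_BAND_AC50 = {"H": 0.03, "M": 1.0, "L": 100.0}

# columns: assay, family, subfamily, process, tissue, severity, potency, ambiguous
_CHLOROANILINE_ROWS = (
    ("CEETOX_H295R_MTT_cell_viability", "Cell cycle", "Proliferation", "Cell death",
     "Adrenal gland", "H", "M", False),
    ("CEETOX_H295R_DOC", "Steroid hormone", "Glucocorticoids",
     "Regulation of steroid hormone biosynthetic process", "Adrenal gland", "M", "L", False),
    ("CEETOX_H295R_OHPROG", "Steroid hormone", "Progestagens",
     "Regulation of steroid hormone biosynthetic process", "Adrenal gland", "M", "L", False),
    ("CEETOX_H295R_PROG", "Steroid hormone", "Progestagens",
     "Regulation of steroid hormone biosynthetic process", "Adrenal gland", "M", "L", False),
    ("OT_FXR_FXRSRC1_1440", "Nuclear receptor", "Non-steroidal", "Protein stabilisation",
     "Kidney", "M", "M", False),
    ("OT_NURR1_NURR1RXRa_1440", "Nuclear receptor", "Non-steroidal", "Protein stabilisation",
     "Kidney", "M", "M", False),
    ("TOX21_ERR_Antagonist", "Nuclear receptor", "Orphan",
     "Regulation of transcription factor activity", "Kidney", "L", "L", False),
    ("TOX21_ERa_BLA_Antagonist_ratio", "Nuclear receptor", "Steroidal",
     "Regulation of transcription factor activity", "Kidney", "L", "L", False),
    ("TOX21_ERb_BLA_Antagonist_ratio", "Nuclear receptor", "Steroidal",
     "Regulation of transcription factor activity", "Kidney", "L", "L", False),
    # The next three rows print as concatenated letter runs in the source
    # table; the encoded reading is the unambiguous one (the following assay
    # name itself starts with "L"), but they are flagged for manual
    # confirmation against the typeset table.
    ("TOX21_AhR_LUC_Agonist", "DNA binding", "Basic helix-loop-helix protein",
     "Regulation of transcription factor activity", "Liver", "M", "L", True),
    ("LTEA_HepaRG_UGT1A1", "Transferase", "Glucuronosyltransferase",
     "Regulation of transcription factor activity", "Liver", "L", "L", True),
    ("LTEA_HepaRG_CYP1A2", "Cyp", "Xenobiotic metabolism",
     "Regulation of transcription factor activity", "Liver", "L", "L", True),
    ("LTEA_HepaRG_CYP1A1", "Cyp", "Xenobiotic metabolism",
     "Regulation of transcription factor activity", "Liver", "L", "M", False),
    ("ACEA_AR_agonist_AUC_viability", "Cell cycle", "Cytotoxicity", "Cell proliferation",
     "Prostate", "H", "M", False),
    ("ACEA_AR_antagonist_AUC_viability", "Cell cycle", "Cytotoxicity", "Cell proliferation",
     "Prostate", "H", "M", False),
    ("ACEA_AR_antagonist_80hr", "Nuclear receptor", "Steroidal", "Cell proliferation",
     "Prostate", "H", "M", False),
    ("BSK_hDFCGF_Proliferation", "Cell cycle", "Proliferation", "Cell proliferation",
     "Skin", "H", "M", False),
    ("CCTE_Simmons_AUR_TPO", "Oxidoreductase", "Peroxidase",
     "Regulation of catalytic activity", "Thyroid gland", "L", "M", False),
    ("BSK_3C_Proliferation", "Cell cycle", "Proliferation", "Cell proliferation",
     "Vascular", "H", "L", False),
)


@dataclass(frozen=True)
class FixtureAssay:
    """An assay row with its printed severity/potency letters."""

    assay: AssayResult
    implied_severity: Level
    potency: Level
    ambiguous: bool


def fixture_chloroaniline() -> list[FixtureAssay]:
    """The 19 active chloroaniline assays with implied severity and potency."""
    out = []
    for name, fam, sub, proc, tissue, sev, pot, amb in _CHLOROANILINE_ROWS:
        out.append(FixtureAssay(
            assay=AssayResult(
                chem_id="chloroaniline", assay_name=name, target_family=fam,
                target_subfamily=sub, biological_process=proc, tissue=tissue,
                active=True, ac50_um=_BAND_AC50[pot],
            ),
            implied_severity=Level(sev),
            potency=Level(pot),
            ambiguous=amb,
        ))
    return out


def fixture_chloroaniline_assays() -> list[AssayResult]:
    """Just the assay records (synthetic band-midpoint AC50s)."""
    return [f.assay for f in fixture_chloroaniline()]


def fixture_chloronitrobenzene_assays() -> list[AssayResult]:
    """Parent-compound panel: no activity in 534 assays, low activity in one
    low-severity assay.  Synthetic reconstruction of the narrative; inactive
    assay descriptors are schematic."""
    panel = [
        AssayResult(
            chem_id="chloronitrobenzene", assay_name=f"SYN_inactive_{i:03d}",
            target_family="Background", target_subfamily="Panel",
            biological_process="None", tissue="Various", active=False,
        )
        for i in range(534)
    ]
    panel.append(AssayResult(
        chem_id="chloronitrobenzene", assay_name="LTEA_HepaRG_CYP1A2",
        target_family="Cyp", target_subfamily="Xenobiotic metabolism",
        biological_process="Regulation of transcription factor activity",
        tissue="Liver", active=True, ac50_um=100.0,
    ))
    return panel


def fixture_ouabain_assays() -> list[AssayResult]:
    """Synthetic reconstruction of the ouabain panel: one high-potency
    high-severity oestrogen-receptor hit plus five mid-potency assays of the
    same target family (the published outlier pattern), and a handful of
    low cells.  No cardiac assays are present, so a cardiotoxicity
    indication is uncovered."""
    panel = [
        AssayResult(
            chem_id="ouabain", assay_name="TOX21_ERa_BLA_Agonist_ratio",
            target_family="Nuclear receptor", target_subfamily="Steroidal - agonist",
            biological_process="Receptor agonist activity", tissue="Kidney",
            active=True, ac50_um=0.05,
        ),
    ]
    for i in range(5):
        panel.append(AssayResult(
            chem_id="ouabain", assay_name=f"SYN_ER_mid_{i}",
            target_family="Nuclear receptor", target_subfamily="Steroidal - agonist",
            biological_process="Receptor agonist activity", tissue="Kidney",
            active=True, ac50_um=1.0 + 0.5 * i,
        ))
    for i in range(3):
        panel.append(AssayResult(
            chem_id="ouabain", assay_name=f"SYN_low_{i}",
            target_family="Cyp", target_subfamily="Xenobiotic metabolism",
            biological_process="Regulation of transcription factor activity",
            tissue="Liver", active=True, ac50_um=50.0,
        ))
    return panel


def fixture_carbaryl_assays() -> list[AssayResult]:
    """Synthetic panel realising the carbaryl pattern: activity only in the
    high-potency / low-severity cell, which the three rule sets map to
    Low / Medium / High respectively."""
    return [
        AssayResult(
            chem_id="carbaryl", assay_name=f"SYN_HL_{i}",
            target_family="Nuclear receptor", target_subfamily="PPAR",
            biological_process="Receptor binding", tissue="Liver",
            active=True, ac50_um=0.02 + 0.01 * i,
        )
        for i in range(2)
    ]


# --- heading audit roster --------------------------------------------------

#: Published combination counts for the 48 high-concern roster chemicals.
HEADING_COMBINATIONS: dict[frozenset[str], int] = {
    frozenset({"Carc"}): 3,
    frozenset({"Muta"}): 7,
    frozenset({"Repro"}): 11,
    frozenset({"STOT"}): 12,
    frozenset({"Carc", "Muta"}): 4,
    frozenset({"Carc", "Repro"}): 1,
    frozenset({"Carc", "STOT"}): 1,
    frozenset({"Repro", "STOT"}): 5,
    frozenset({"Carc", "Muta", "Repro"}): 1,
    frozenset({"Carc", "Muta", "Repro", "STOT"}): 3,
}


def fixture_designathon_headings() -> list[HeadingSet]:
    """48 synthetic chemicals whose heading combinations reproduce the
    published per-combination counts exactly."""
    sets = []
    i = 0
    for combo in sorted(HEADING_COMBINATIONS, key=lambda c: (len(c), sorted(c))):
        for _ in range(HEADING_COMBINATIONS[combo]):
            i += 1
            sets.append(HeadingSet(chem_id=f"designathon_{i:02d}", headings=combo))
    return sets


# --- 12-chemical category pairs --------------------------------------------

#: (NAM level, conventional level) per chemical.  Offsets per chemical match
#: the published comparison (+1 benzoic acid; 0 for seven chemicals; -1
#: carbaryl, chlorpropham, ouabain; -2 nitrobenzene); absolute levels are a
#: synthetic reconstruction consistent with a 4 high / 4 mid / 4 low
#: conventional split.
CATEGORY_PAIRS: dict[str, tuple[Level, Level]] = {
    "nitrobenzene": (Level.LOW, Level.HIGH),
    "ouabain": (Level.MEDIUM, Level.HIGH),
    "colchicine": (Level.HIGH, Level.HIGH),
    "chloronitrobenzene": (Level.HIGH, Level.HIGH),
    "carbaryl": (Level.LOW, Level.MEDIUM),
    "chlorpropham": (Level.LOW, Level.MEDIUM),
    "phenol": (Level.MEDIUM, Level.MEDIUM),
    "nitrophenol": (Level.MEDIUM, Level.MEDIUM),
    "benzoic_acid": (Level.MEDIUM, Level.LOW),
    "safrole": (Level.LOW, Level.LOW),
    "diethylphthalate": (Level.LOW, Level.LOW),
    "tertiary_butylphenol": (Level.LOW, Level.LOW),
}


def fixture_category_pairs() -> tuple[dict[str, Level], dict[str, Level]]:
    """(NAM map, conventional map) for the 12 assessed chemicals."""
    nam = {chem: pair[0] for chem, pair in CATEGORY_PAIRS.items()}
    ref = {chem: pair[1] for chem, pair in CATEGORY_PAIRS.items()}
    return nam, ref
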