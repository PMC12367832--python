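"""Classify the two narrative worked examples end-to-end.

Chloronitrobenzene: the metabolite chloroaniline is Mid for bioactivity,
but the indicated methemoglobinemia hazard has no matching assay, so the
toxicodynamic axis defaults to High; with Mid bioavailability the chemical
lands at High overall.  Ouabain: a lone high-potency oestrogen-receptor hit
is demoted as an outlier, but the cardiotoxicity coverage gap keeps
bioactivity at High; with Low oral bioavailability the matrix yields
Medium overall.
"""

from namloc import CmaxPrediction, FrameworkConfig
from namloc.fixtures import (
    fixture_chloroaniline_assays,
    fixture_chloronitrobenzene_assays,
    fixture_ouabain_assays,
)
from namloc.overall import label_insufficiency
from namloc.pipeline import classify_chemical

cfg = FrameworkConfig()

cnb = classify_chemical(
    chem_id="chloronitrobenzene", config=cfg,
    assays=fixture_chloronitrobenzene_assays(),
    metabolite_assays={"chloroaniline": fixture_chloroaniline_assays()},
    hazard_indications=["methemoglobinemia"],
    cmax_predictions=[CmaxPrediction("chloronitrobenzene", "httk", 120.0, "in_silico")],
)
oua = classify_chemical(
    chem_id="ouabain", config=cfg,
    assays=fixture_ouabain_assays(),
    hazard_indications=["cardiotoxicity"],
    cmax_predictions=[CmaxPrediction("ouabain", "httk", 10.0, "in_silico")],
)

for res in (cnb, oua):
    print(f"{res.chem_id}:")
    print(f"  bioactivity (TD) : {res.td_loc.label}")
    print(f"  bioavailability  : {res.tk_level.value}")
    print(f"  uncovered hazards: {res.uncovered}")
    print(f"  overall          : {label_insufficiency(res.overall_result)}")
    for line in res.overall_result.audit:
        print(f"    - {line}")
    print()

print("TD/TK letters are Low/Medium/High bands; a starred overall level was")
print("reached by defaulting on insufficient evidence, not by positive data.")
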