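# namloc

Classification of chemicals into **levels of concern for repeat-dose
systemic toxicity** using non-animal methods (NAMs). The package
implements a tiered, exclusionary weight-of-evidence framework that
integrates three lines of evidence:

1. **In silico indications** — per-model (Q)SAR outputs (outcome,
   applicability domain, reliability, relevance per endpoint) combined
   into a five-band toxicity indication (low → strong) that is promoted
   conservatively onto Low/Medium/High.
2. **In vitro bioactivity** — ToxCast-style assay results banded by
   potency (AC50: High < 0.1 µM, Medium 0.1–10 µM, Low > 10 µM) and rated
   for implied severity from assay descriptors, cross-tabulated into a
   potency × severity matrix and mapped to a level of concern by a
   selectable rule set (`min_red`, `max_red`, `pot_only`), with outlier
   demotion, metabolite worst-casing and an assay-coverage check against
   the in silico hazard indications.
3. **Bioavailability** — the maximum plasma concentration (Cmax, µM)
   after a standardised 14-day once-daily oral regimen of 0.1 mmol/kg in
   a 70 kg adult, simulated with a one-compartment IVIVE model
   (well-stirred hepatic clearance from CLint and fup, renal filtration
   of the unbound fraction) and/or supplied by external PBK platforms,
   categorised as Low < 50 µM, Mid 50–500 µM, High > 500 µM, aggregated
   worst-case across models, with a 3× uncertainty factor on in
   silico-derived inputs.

The bioactivity (TD) and bioavailability (TK) categories are combined
through a monotone 3×3 matrix and challenged by eight structured
weight-of-evidence questions. The framework is exclusionary: every
chemical starts at High concern and moves down only on sufficient
evidence; a missing assay, an unassessed metabolite or absent kinetic
data defaults the corresponding axis to *High through lack of evidence*,
which reports render distinctly from an evidence-based High.

The intended audience is toxicologists and cheminformaticians exploring
NAM-based hazard classification (STOT-RE-like endpoints), sensitivity of
the category boundaries, and audits of how classification headings
(Carc/Muta/Repro/STOT) overlap.

## Worked example

`examples/classify_worked_examples.py` classifies the two narrative
cases end-to-end:

```text
chloronitrobenzene:
  bioactivity (TD) : H* (defaulted through lack of evidence)
  bioavailability  : M
  uncovered hazards: ['methemoglobinemia']
  overall          : H* — assumed to be of high concern through lack of evidence
    - metabolite chloroaniline: bioactivity M
    - hazard indications ['methemoglobinemia'] have no matching assay: TD M -> High (insufficient evidence)

ouabain:
  bioactivity (TD) : H* (defaulted through lack of evidence)
  bioavailability  : L
  uncovered hazards: ['cardiotoxicity']
  overall          : M* — an axis was defaulted through lack of evidence
```

Chloronitrobenzene's metabolite is Mid for bioactivity, but the indicated
methemoglobinemia hazard has no matching assay in the panel, so the TD
axis defaults to High; combined with Mid bioavailability the chemical is
High concern overall. Ouabain's lone high-potency oestrogen-receptor hit
is demoted as an outlier against five concordant mid-potency assays, yet
the cardiotoxicity coverage gap keeps TD at High; with Low oral
bioavailability the combination matrix yields Medium overall.

Other example scripts cover the bioactivity matrix
(`bioactivity_matrix.py`), the kinetic simulator
(`simulate_bioavailability.py`), the heading-combination audit
(`heading_audit.py`) and ground-truth recovery on synthetic data
(`synthetic_recovery.py`). A thin CLI exposes the same capabilities:
`namloc classify|bioactivity|bioavailability|insilico|sensitivity|audit|synth`.

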