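# Methods

## The classification model

A chemical's level of concern (LoC) for repeat-dose systemic toxicity is
an ordered category, Low < Medium < High, produced by combining a
toxicodynamic (TD) axis and a toxicokinetic (TK) axis through a 3×3
matrix and reviewing the result with eight weight-of-evidence questions.
The governing assumption is the **exclusion principle**: every chemical
is of High concern until evidence moves it down, so every operation in
the package is monotone with respect to missing information — an absent
assay, an unassessed metabolite or missing kinetic inputs can keep or
raise a level, never lower it. Outcomes reached this way carry a
distinct provenance (`default_insufficient_evidence`) so that an
"assumed High" is never conflated with a demonstrated one.

### In silico indications

Per-model (Q)SAR predictions carry an outcome (positive / negative /
equivocal) and three usability screens (applicability domain,
reliability, relevance). A prediction is *usable* when none of the
screens is "no" and the outcome is not equivocal; equivocal outcomes are
deliberately unusable for both the strengthening and the exculpating
clause. The five indication bands are:

* **strong** — at least `strong_min_endpoints` (default 2) endpoints
  each with a usable positive and no usable negative from another model;
* **low** — every usable prediction negative and every endpoint covered
  by at least one usable prediction;
* **moderate_high** — at least one consistently positive endpoint
  coexisting with other endpoints that are mixed or unusable;
* **low_moderate** — usable predictions predominantly negative (more
  than `negative_predominance`, default 75%) with no consistently
  positive endpoint and at least one endpoint lacking usable evidence;
* **moderate** — everything else.

Only the conservative promotion (low→Low, low_moderate/moderate→Medium,
moderate_high/strong→High) propagates downstream. The 75% predominance
threshold and the two-endpoint requirement are calibration choices
exposed in `FrameworkConfig`; the qualitative behaviour (monotone in
positive evidence, invariant to out-of-domain additions on covered
endpoints) is property-tested. An explicit expert override is honoured
and logged, since the banding is a structured aid, not a decision tree.

The moderate_high clause intentionally requires *other* endpoints to be
mixed or unusable: a profile whose only endpoint is consistently
positive is moderate (promoted to Medium), because a single-endpoint
signal cannot demonstrate the cross-endpoint consistency that High
demands.

### Bioactivity (TD)

Active assays are banded by AC50 — High < 0.1 µM, Medium 0.1–10 µM, Low
> 10 µM, with **boundaries belonging to the closed middle band** (the
published band definitions use strict inequalities for High and Low).
Implied severity comes from a first-match-wins lexicon over the ToxCast
descriptor triple (target family, subfamily, biological process),
shipped as editable CSV data: cytotoxicity / proliferation readouts and
steroid-receptor agonism rate High, steroidogenesis and
transcription-factor modulation Medium, metabolic-enzyme induction,
antagonist reporter readouts and PPAR binding Low, and a mandatory
wildcard fallback rates unknown descriptors Medium (neither exculpatory
nor damning). The lexicon distinguishes receptor agonist from
antagonist readouts because the assessed antagonist reporter assays are
rated Low while oestrogenic agonism is rated High; the distinction is a
design choice where the source material is ambiguous.

The potency × severity matrix maps to a LoC as the maximum of a rule-set
cell map over occupied cells:

| cell map | High | Medium |
|---|---|---|
| `min_red` | (H,H) | (H,M), (M,H) |
| `max_red` | (H,H) | (H,M), (M,H), (H,L), (M,M) |
| `pot_only` | potency H | potency M |

`max_red` promotes strictly more cells than `min_red` while staying
cell-by-cell below `pot_only`; this keeps the three assessments totally
ordered for every matrix, which is both the intended reading of
"uniformly more conservative" and a tested invariant. (Promoting
low-potency cells such as (L,H) would break the ordering against the
potency-only map and is therefore not done.) A matrix with no active
assays is Low on this axis; whether the panel could have seen anything
is judged separately by the coverage check.

Three adjustments operate on top of the matrix:

* **Outlier demotion** — if the level-setting cell holds exactly one
  assay and at least `outlier_min_concordant` (default 3) active assays
  of the same target family sit one or more potency bands lower, the
  lone assay is demoted to the highest concordant band and the level
  recomputed. The default of 3 is deliberately below the five
  concordant assays of the motivating case.
* **Coverage check** — hazard tags indicated in silico are matched
  against the panel through a capability map (case-insensitive substring
  patterns over assay name, descriptors and tissue). Any uncovered
  hazard forces the TD axis to High with insufficiency provenance.
  Unknown hazard tags are conservatively treated as uncovered.
* **Family worst-casing** — the TD level of a parent is the maximum over
  the parent and its assessed metabolites, keeping the insufficiency
  flag of whichever level sets the maximum.

### Bioavailability (TK)

The TK metric is the global maximum plasma concentration over a
standardised regimen: 0.1 mmol/kg once daily for 14 days, oral route
only, in a 70 kg adult. The molar dose makes the metric independent of
molecular weight (a tested invariant). The stand-in kinetic model is a
one-compartment system with first-order absorption:

* gut: dA_g/dt = −ka·A_g, with F·D added at each dose time;
* plasma: dA_c/dt = ka·A_g − (CL/V)·A_c, C = A_c/V (µM = mmol/L ×1000);
* CL = CL_hep + GFR·fup (renal mode configurable), with CL_hep from the
  well-stirred liver model,
  CL_hep = Q_h·fup·CL_int,whole / (Q_h + fup·CL_int,whole), and
  CL_int,whole scaled from CLint (µL/min/10⁶ cells) by hepatocellularity
  (110 ×10⁶ cells/g) and liver mass (1470 g).

Defaults: ka = 1 /h, Vd = 1 L/kg, F = 1, liver blood flow 90 L/h, GFR
6.7 L/h — literature-typical values for the reference adult, all
config-exposed; only the body weight is fixed by the protocol. The
system is integrated numerically (LSODA, rtol 1e-9) in 24 h chunks with
dense output; the peak is located on a 0.1 h grid and refined by bounded
scalar minimisation, and integration continues past the dosing horizon
until a chunk produces no new maximum. Zero total clearance is handled
exactly (the supremum is the fully absorbed amount over the volume).
The test suite checks the integrator against an independently written
closed-form superposition of one-compartment oral doses to 0.1%
relative. AUC is integrated alongside and reported but never
categorised: the single-value metric of this framework is Cmax, and AUC
is kept visible only for inspection.

Cmax is categorised as Low < 50 µM, Mid 50–500 µM, High > 500 µM (same
boundary convention as potency), after multiplying by an uncertainty
factor of 3 when the kinetic inputs were predicted in silico rather than
measured in vitro. The factor is applied to Cmax *before* categorisation
— order-preserving and conservative. Externally supplied per-model Cmax
predictions are first-class inputs; the chemical's category is the worst
case across all models, simulated or supplied. Cutoffs can be
recalibrated as empirical quantiles (default 25%/75%, linear
interpolation of order statistics) of a Cmax population.

### Overall assessment

The default TD×TK matrix is

| TD \ TK | L | M | H |
|---|---|---|---|
| **L** | L | L | M |
| **M** | L | M | H |
| **H** | M | H | H |

anchored at (H,M)→H and (H,L)→M by the worked examples; the remaining
cells are the natural monotone completion and are config-overridable
(any override is validated for monotonicity in both axes, and
assessments driven by unanchored cells are visible in the audit trail).
Coverage gaps act on the TD axis and then the matrix decides — this is
what places a high-bioactivity / low-bioavailability chemical at Medium
overall even when its panel was incomplete. When `evaluate_woe` is used
standalone with uncovered hazards passed directly, they force High, as
do "no"/"unknown" answers to the correct-molecule (q1) and
assay-sufficiency (q4) questions. Failed consistency questions (q5–q8)
raise the preliminary level by one step by default (policy configurable
as ignore / raise_one / force_high); q2–q3 are contextual and only
logged. WoE answers are curated inputs, not computed text analysis.

## Synthetic data

The generators produce seeded populations with known ground truth.
Assay panels draw AC50s log-uniformly inside the intended potency band,
at least two-fold clear of both cutoffs, with descriptor triples sampled
from lexicon entries of the intended severity; the level-setting cell is
duplicated so the outlier rule cannot fire. TK inputs are produced by
solving the elimination rate against a target Cmax (itself placed
two-fold clear of the band cutoffs, after the uncertainty factor for in
silico provenance) and inverting the well-stirred model for CLint; an
internal closed-form solver does the search and the public simulator
verifies every placement. What this emulates is the *statistical
structure* of a screening panel — band mixes, provenance mixes,
clearance ranges; what it does not emulate is assay noise,
boundary-adjacent potencies, curve-fit artefacts or real coverage gaps,
so a 100% recovery on clear-cut profiles demonstrates the pipeline's
internal consistency, not field performance on real panels.

Published fixtures are shipped as code: the 19-row chloroaniline assay
table (with three rows flagged as typographically ambiguous in the
source and synthetic band-midpoint AC50s standing in for the unprinted
concentrations), a 48-chemical roster reproducing the published heading
combination counts, the 12-chemical NAM/conventional category pairs
(offsets as published; absolute levels of the agreeing chemicals
reconstructed), and synthetic panels realising the chloronitrobenzene,
ouabain and carbaryl narratives.

## Numerical and policy choices

* Band boundaries belong to the middle category throughout (potency and
  bioavailability), matching the strict inequalities of the published
  band definitions.
* Percentages in the heading audit round half-up to whole percent.
  Recomputing the battery coverages from the combination counts yields
  21 for a STOT-only battery, 33 for STOT+Muta and 36 for
  Carc+Repro+Muta, which differ from some published cells (19, 32, 37);
  the package reports the recomputed values, and the discrepancy most
  plausibly traces to acute-toxicity pooling in the STOT column of the
  source tabulation.
* Agreement offsets rank L=1, M=2, H=3; intermediate in silico bands
  never reach the offset stage (only their conservative promotions
  propagate).
* The acceptance script uses a 200-chemical synthetic population and a
  panel size of 8 active assays per chemical, sizes at which every
  stage's behaviour is fully exercised while the whole run stays fast.

## Known limitations

* The kinetic stand-in is deliberately minimal: no multi-compartment
  distribution, transporters, enzyme saturation, gut first-pass beyond a
  scalar F, or population variability. Platform-specific Cmax values
  are ingested, not reproduced.
* Severity rating is a curated lexicon and inherits its subjectivity;
  the shipped entries cover the descriptor triples of the worked
  examples plus a neutral fallback.
* The oral route only; other routes raise an explicit unsupported-route
  error rather than silently extrapolating.
* WoE questions are expert prompts; the package validates and applies
  them but does not derive them from raw evidence (except q4-style
  coverage, which the capability map automates).
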