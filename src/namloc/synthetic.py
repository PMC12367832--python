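"""Seeded synthetic-data generators with known ground-truth categories.

``generate_assay_panel`` emulates a ToxCast-like assay panel: per chemical,
active assays are drawn into prescribed (potency, severity) cells with
AC50s log-uniform inside the band and clear of the cutoffs by at least a
factor of two, so the intended bioactivity level is recovered exactly by
construction.  ``generate_tk_inputs`` solves clearance parameters so the
simulated 14-day Cmax lands in the intended bioavailability band with the
same two-fold margin (verified by running the public simulator).  All
generators are pure functions of (profile, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .bioavailability import apply_insilico_uf, simulate_cmax, total_clearance
from .datamodel import (
    AssayResult,
    DosingProtocol,
    FrameworkConfig,
    Level,
    PKParameters,
    Physiology,
    RULESETS,
)
from .errors import ValidationError

# re-exported here so the synthetic module is the one-stop fixture surface
from .fixtures import (  # noqa: F401
    fixture_carbaryl_assays,
    fixture_category_pairs,
    fixture_chloroaniline,
    fixture_chloroaniline_assays,
    fixture_chloronitrobenzene_assays,
    fixture_designathon_headings,
    fixture_ouabain_assays,
)

#: Descriptor triples per severity, all resolvable by the shipped lexicon.
_DESCRIPTORS = {
    Level.HIGH: (
        ("Cell cycle", "Proliferation", "Cell death", "Adrenal gland"),
        ("Cell cycle", "Cytotoxicity", "Cell proliferation", "Prostate"),
        ("Nuclear receptor", "Steroidal - agonist", "Receptor agonist activity", "Uterus"),
    ),
    Level.MEDIUM: (
        ("Steroid hormone", "Progestagens",
         "Regulation of steroid hormone biosynthetic process", "Adrenal gland"),
        ("Nuclear receptor", "Non-steroidal", "Protein stabilisation", "Kidney"),
    ),
    Level.LOW: (
        ("Cyp", "Xenobiotic metabolism",
         "Regulation of transcription factor activity", "Liver"),
        ("Transferase", "Glucuronosyltransferase",
         "Regulation of transcription factor activity", "Liver"),
        ("Oxidoreductase", "Peroxidase", "Regulation of catalytic activity",
         "Thyroid gland"),
    ),
}

#: Cells a chemical of each intended bioactivity level may occupy under the
#: default (min_red) rule set; the first cell is the level-setting one.
_TD_CELLS = {
    Level.HIGH: [("H", "H"), ("M", "M"), ("L", "L"), ("M", "L")],
    Level.MEDIUM: [("M", "H"), ("L", "L"), ("L", "M"), ("M", "L")],
    Level.LOW: [("L", "L"), ("L", "M")],
}


@dataclass
class SyntheticProfile:
    """Specification of a synthetic study population.

    ``intended_td`` / ``intended_tk`` cycle over the chemicals when shorter
    than ``n_chemicals``.  ``panel_size`` counts active assays per chemical;
    half as many inactive assays are appended.
    """

    n_chemicals: int = 12
    intended_td: Sequence[Level] = (Level.LOW, Level.MEDIUM, Level.HIGH)
    intended_tk: Sequence[Level] = (Level.LOW, Level.MEDIUM, Level.HIGH)
    panel_size: int = 12
    insilico_fraction: float = 0.5
    coverage_gaps: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1 or self.panel_size < 1:
            raise ValidationError("n_chemicals and panel_size must be >= 1")
        if not (0 <= self.insilico_fraction <= 1):
            raise ValidationError("insilico_fraction must be in [0, 1]")
        if not self.intended_td or not self.intended_tk:
            raise ValidationError("intended level sequences must be non-empty")

    def chem_ids(self) -> list[str]:
        return [f"synth_{i:04d}" for i in range(1, self.n_chemicals + 1)]

    def td_of(self, i: int) -> Level:
        return self.intended_td[i % len(self.intended_td)]

    def tk_of(self, i: int) -> Level:
        return self.intended_tk[i % len(self.intended_tk)]


def _sample_ac50(rng: np.random.Generator, band: str,
                 cutoffs: tuple[float, float]) -> float:
    """Log-uniform AC50 inside the band, >= 2-fold clear of both cutoffs."""
    high_below, low_above = cutoffs
    if band == "H":
        lo, hi = high_below / 100.0, high_below / 2.0
    elif band == "M":
        lo, hi = high_below * 2.0, low_above / 2.0
    else:
        lo, hi = low_above * 2.0, low_above * 200.0
    if not lo < hi:
        raise ValidationError(f"band {band} unsatisfiable under cutoffs {cutoffs}")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_assay_panel(
    profile: SyntheticProfile,
    config: Optional[FrameworkConfig] = None,
) -> tuple[list[AssayResult], pd.DataFrame]:
    """Generate assay records plus a ground-truth table (chem_id, intended_td).

    Each chemical receives two assays in its level-setting cell (so the
    single-outlier demotion rule can never fire) and the remainder spread
    over cells that cannot raise the level under the default rule set.
    """
    cfg = config or FrameworkConfig()
    rng = np.random.default_rng(profile.seed)
    ruleset = RULESETS["min_red"]
    records: list[AssayResult] = []
    truth_rows = []
    for i, chem in enumerate(profile.chem_ids()):
        td = profile.td_of(i)
        cells = _TD_CELLS[td]
        achievable = max(ruleset[(Level(p), Level(s))] for p, s in cells)
        if achievable != td:
            raise ValidationError(
                f"profile error: cell mix for {chem} cannot realise TD={td.value}"
            )
        plan = [cells[0], cells[0]]  # duplicate level-setting cell
        filler = cells[1:] or cells[:1]
        for k in range(profile.panel_size - 2):
            plan.append(filler[int(rng.integers(len(filler)))])
        for j, (pot, sev) in enumerate(plan[:profile.panel_size]):
            fam, sub, proc, tissue = _DESCRIPTORS[Level(sev)][
                int(rng.integers(len(_DESCRIPTORS[Level(sev)])))]
            records.append(AssayResult(
                chem_id=chem, assay_name=f"SYN_{chem}_{j:03d}",
                target_family=fam, target_subfamily=sub,
                biological_process=proc, tissue=tissue, active=True,
                ac50_um=_sample_ac50(rng, pot, cfg.potency_cutoffs),
            ))
        for j in range(profile.panel_size // 2):
            records.append(AssayResult(
                chem_id=chem, assay_name=f"SYN_{chem}_inactive_{j:03d}",
                target_family="Background", target_subfamily="Panel",
                biological_process="None", tissue="Various", active=False,
            ))
        truth_rows.append({"chem_id": chem, "intended_td": td.value})
    return records, pd.DataFrame(truth_rows)


# --- toxicokinetic inputs --------------------------------------------------

def _closed_form_cmax(ke: float, ka: float, dose_mmol: float, v: float,
                      n_days: int, tau: float = 24.0) -> float:
    """Closed-form repeat-dose oral Cmax (µM) used only for parameter search."""
    t0 = (n_days - 1) * tau

    def conc(t: float) -> float:
        c = 0.0
        for i in range(n_days):
            dt = t - i * tau
            if dt < 0:
                continue
            if abs(ka - ke) < 1e-12 * ka:
                c += dose_mmol * ka * dt * math.exp(-ka * dt)
            else:
                c += dose_mmol * ka / (ka - ke) * (
                    math.exp(-ke * dt) - math.exp(-ka * dt))
        return c / v * 1000.0

    horizon = t0 + min(10.0 / max(ke, 1e-6), 2400.0)
    ts = np.linspace(t0, horizon, 400)
    vals = [conc(t) for t in ts]
    k = int(np.argmax(vals))
    lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, len(ts) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda t: -conc(t), bounds=(lo, hi), method="bounded")
        return float(max(vals[k], -res.fun))
    return float(vals[k])


def _solve_pk(chem: str, target_um: float, fup: float, source: str,
              cfg: FrameworkConfig, phys: Physiology) -> PKParameters:
    """Solve clint (and f_abs) so the simulated raw Cmax equals ``target_um``."""
    v = phys.body_weight  # vd = 1 L/kg
    dose_mmol = cfg.dose_mmol_per_kg * phys.body_weight
    ka = 1.0
    ke_max = 0.99 * phys.liver_blood_flow / v
    floor = _closed_form_cmax(ke_max, ka, dose_mmol, v, cfg.n_days)
    f_abs = 1.0
    if target_um < 1.2 * floor:
        f_abs = target_um / (10.0 * floor)   # re-centre the target mid-range
    eff_dose = dose_mmol * f_abs

    def gap(ke: float) -> float:
        return _closed_form_cmax(ke, ka, eff_dose, v, cfg.n_days) - target_um

    ke = brentq(gap, 1e-9, ke_max, xtol=1e-12, rtol=1e-10)
    cl = ke * v
    qh = phys.liver_blood_flow
    clu_whole = qh * cl / (fup * (qh - cl))
    clint = clu_whole * 1e6 / (phys.hepatocellularity * phys.liver_mass * 60.0)
    return PKParameters(
        chem_id=chem, molecular_weight=250.0, clint=float(clint), fup=float(fup),
        input_source=source, ka=ka, vd=1.0, f_abs=float(f_abs), renal_mode="none",
    )


def generate_tk_inputs(
    profile: SyntheticProfile,
    config: Optional[FrameworkConfig] = None,
) -> tuple[list[PKParameters], pd.DataFrame]:
    """Generate TK inputs whose simulated (UF-adjusted) Cmax lands in the
    intended band with a >= 2-fold margin from both cutoffs.

    Band placement is verified by running the public simulator on every
    record; an intended band that cannot be reached under the configured
    dose raises a profile error.
    """
    cfg = config or FrameworkConfig()
    phys = cfg.physiology()
    rng = np.random.default_rng(profile.seed + 1)
    lo_cut, hi_cut = cfg.bioavailability_cutoffs
    ceiling = cfg.dose_mmol_per_kg * cfg.n_days * 1000.0  # µM, vd = 1 L/kg
    windows = {
        Level.LOW: (lo_cut / 10.0, lo_cut / 2.0),
        Level.MEDIUM: (lo_cut * 2.0, hi_cut / 2.0),
        Level.HIGH: (hi_cut * 2.0, 0.95 * ceiling),
    }
    records: list[PKParameters] = []
    rows = []
    for i, chem in enumerate(profile.chem_ids()):
        tk = profile.tk_of(i)
        w_lo, w_hi = windows[tk]
        if not w_lo < w_hi:
            raise ValidationError(
                f"profile error: intended TK={tk.value} unreachable under "
                f"cutoffs {cfg.bioavailability_cutoffs} and dose {cfg.dose_mmol_per_kg}"
            )
        target_eff = float(np.exp(rng.uniform(np.log(w_lo), np.log(w_hi))))
        source = "in_silico" if rng.random() < profile.insilico_fraction else "in_vitro"
        raw_target = target_eff / cfg.insilico_uf if source == "in_silico" else target_eff
        fup = float(rng.uniform(0.2, 1.0))
        pk = _solve_pk(chem, raw_target, fup, source, cfg, phys)
        cmax = simulate_cmax(pk, cfg.protocol(), phys)
        eff = apply_insilico_uf(cmax, pk.input_source, cfg.insilico_uf)
        if not (w_lo * 0.9 <= eff <= w_hi * 1.1):
            raise ValidationError(
                f"profile error: solved Cmax {eff:.3g} µM for {chem} missed the "
                f"intended {tk.value} window [{w_lo:.3g}, {w_hi:.3g}]"
            )
        records.append(pk)
        rows.append({"chem_id": chem, "intended_tk": tk.value,
                     "cmax_um": cmax, "effective_cmax_um": eff,
                     "input_source": source})
    return records, pd.DataFrame(rows)
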