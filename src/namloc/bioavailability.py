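"""Simulated systemic bioavailability: 14-day repeat-dose oral Cmax.

A one-compartment model with first-order absorption stands in for the
platform PBK engines: hepatic clearance is scaled from intrinsic hepatocyte
clearance via the well-stirred liver model, renal clearance defaults to
glomerular filtration of the unbound fraction, and the standardised regimen
is 0.1 mmol/kg once daily for 14 days in a 70 kg adult.  The metric is the
global maximum plasma concentration in µM; the AUC is reported alongside
but never categorised.  Externally supplied per-model Cmax predictions are
ingestible and aggregated worst-case.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .datamodel import (
    CmaxPrediction,
    DosingProtocol,
    Level,
    PKParameters,
    Physiology,
)
from .errors import NamlocError, ValidationError

log = logging.getLogger("namloc.bioavailability")


class DoseEquivalence(NamedTuple):
    mg_per_kg: float
    g_per_person: float
    total_mmol: float


def dose_equivalence(mw: float, dose_mmol_per_kg: float = 0.1,
                     body_weight_kg: float = 70.0) -> DoseEquivalence:
    """Convert a molar dose to mass units for a given molecular weight.

    mg/kg = dose x MW; g/person = mg/kg x BW / 1000; total mmol = dose x BW.
    The molar dose deliberately does not penalise high molecular weight.
    """
    if not (mw > 0 and dose_mmol_per_kg > 0 and body_weight_kg > 0):
        raise ValidationError("mw, dose and body weight must all be positive")
    mg_per_kg = dose_mmol_per_kg * mw
    return DoseEquivalence(
        mg_per_kg=mg_per_kg,
        g_per_person=mg_per_kg * body_weight_kg / 1000.0,
        total_mmol=dose_mmol_per_kg * body_weight_kg,
    )


def scale_clearance(pk: PKParameters, phys: Optional[Physiology] = None) -> float:
    """Whole-body hepatic clearance (L/h) by IVIVE and the well-stirred model.

    CLint (µL/min/10^6 cells) is scaled by hepatocellularity and liver mass
    to a whole-liver unbound intrinsic clearance, then combined with liver
    blood flow Q_h:  CL_hep = Q_h * fup * CLint,whole / (Q_h + fup * CLint,whole).
    The result is bounded by liver blood flow.
    """
    phys = phys or Physiology()
    clint_whole = pk.clint * phys.hepatocellularity * phys.liver_mass * 60.0 / 1e6  # L/h
    if clint_whole == 0:
        return 0.0
    qh = phys.liver_blood_flow
    cl_hep = qh * pk.fup * clint_whole / (qh + pk.fup * clint_whole)
    return cl_hep


def total_clearance(pk: PKParameters, phys: Optional[Physiology] = None) -> float:
    """Hepatic plus (optional) renal clearance in L/h."""
    phys = phys or Physiology()
    cl = scale_clearance(pk, phys)
    if pk.renal_mode == "gfr_fup":
        cl += phys.gfr * pk.fup
    return cl


class SimulationResult(NamedTuple):
    cmax_um: float
    auc_um_h: float


def simulate(pk: PKParameters, protocol: Optional[DosingProtocol] = None,
             phys: Optional[Physiology] = None) -> SimulationResult:
    """Numerically integrate the repeat-dose model; return (Cmax µM, AUC µM·h).

    The state is (amount in gut, amount in plasma, cumulative AUC) in mmol
    and mmol·h/L.  Each daily dose adds ``f_abs x dose x BW`` mmol to the
    gut depot.  The global concentration maximum over the whole horizon
    (including the post-dosing tail) is located on the dense solution and
    refined by bounded scalar optimisation.

    With zero total clearance the supremum is the fully absorbed amount over
    the distribution volume, returned exactly.
    """
    protocol = protocol or DosingProtocol()
    phys = phys or Physiology()
    v = pk.vd * phys.body_weight                        # L
    cl = total_clearance(pk, phys)                      # L/h
    ke = cl / v                                         # 1/h
    ka = pk.ka
    dose_mmol = pk.f_abs * protocol.dose * phys.body_weight
    tau = 24.0

    if cl == 0.0:
        # pure accumulation: sup over the horizon is total absorbed / V
        total = dose_mmol * protocol.n_days
        # AUC over the dosing horizon only (diverges beyond it)
        auc = _integrate_zero_clearance_auc(dose_mmol, ka, v, protocol.n_days, tau)
        return SimulationResult(cmax_um=total / v * 1000.0, auc_um_h=auc)

    def rhs(t, y):
        ag, ac, _ = y
        return (-ka * ag, ka * ag - ke * ac, ac / v)

    y = np.array([0.0, 0.0, 0.0])
    best = (0.0, None, None)  # (cmax mmol, dense sol, window)
    n_chunks = 0
    chunk_start = 0.0
    dosing_chunks = protocol.n_days
    while True:
        if n_chunks < dosing_chunks:
            y = y + np.array([dose_mmol, 0.0, 0.0])
        sol = solve_ivp(rhs, (chunk_start, chunk_start + tau), y,
                        dense_output=True, rtol=1e-9, atol=1e-12, method="LSODA")
        if not sol.success:
            raise NamlocError(
                f"integration failed for {pk.chem_id} (ka={ka}, ke={ke}, vd={pk.vd}): "
                f"{sol.message}"
            )
        ts = np.linspace(chunk_start, chunk_start + tau, 241)
        ac = sol.sol(ts)[1]
        i = int(np.argmax(ac))
        if ac[i] > best[0]:
            lo = ts[max(i - 1, 0)]
            hi = ts[min(i + 1, len(ts) - 1)]
            best = (float(ac[i]), sol, (lo, hi))
        y = sol.y[:, -1]
        chunk_start += tau
        n_chunks += 1
        if n_chunks >= dosing_chunks:
            # stop once a post-dosing chunk produced no new maximum
            if ac[i] < best[0] or y[0] / v * 1000.0 < 1e-12:
                break
        if n_chunks > dosing_chunks + 100000:  # pragma: no cover
            raise NamlocError(f"no concentration peak located for {pk.chem_id}")

    cmax_mmol, sol, (lo, hi) = best
    if hi > lo:
        res = minimize_scalar(lambda t: -sol.sol(t)[1], bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        cmax_mmol = max(cmax_mmol, float(-res.fun))
    auc = float(y[2]) * 1000.0  # mmol·h/L -> µM·h
    return SimulationResult(cmax_um=cmax_mmol / v * 1000.0, auc_um_h=auc)


def _integrate_zero_clearance_auc(dose_mmol: float, ka: float, v: float,
                                  n_days: int, tau: float) -> float:
    # closed form: Ac(t) = sum_i D (1 - exp(-ka (t - t_i)))
    horizon = n_days * tau
    auc = 0.0
    for i in range(n_days):
        span = horizon - i * tau
        auc += dose_mmol * (span - (1 - math.exp(-ka * span)) / ka)
    return auc / v * 1000.0


def simulate_cmax(pk: PKParameters, protocol: Optional[DosingProtocol] = None,
                  phys: Optional[Physiology] = None) -> float:
    """Maximum plasma concentration (µM) over the dosing protocol."""
    return simulate(pk, protocol, phys).cmax_um


def apply_insilico_uf(cmax_um: float, input_source: str, uf: float = 3.0) -> float:
    """Multiply Cmax by the uncertainty factor when the toxicokinetic inputs
    were predicted in silico; measured in vitro inputs pass unchanged."""
    if uf < 1:
        raise ValidationError("uncertainty factor must be >= 1")
    if input_source == "in_silico":
        return cmax_um * uf
    return cmax_um


def categorize_bioavailability(cmax_um: float,
                               cutoffs: tuple[float, float] = (50.0, 500.0)) -> Level:
    """Band a Cmax: Low below ``low_below``, High above ``high_above``,
    Medium otherwise (boundaries inclusive in Medium)."""
    if cmax_um < 0 or not math.isfinite(cmax_um):
        raise ValidationError(f"Cmax must be finite and >= 0, got {cmax_um}")
    low_below, high_above = cutoffs
    if cmax_um < low_below:
        return Level.LOW
    if cmax_um > high_above:
        return Level.HIGH
    return Level.MEDIUM


def aggregate_models(predictions: Sequence[CmaxPrediction],
                     cutoffs: tuple[float, float] = (50.0, 500.0),
                     uf: float = 3.0) -> Level:
    """Worst-case bioavailability category across per-model predictions.

    Each prediction is adjusted by the in silico uncertainty factor where
    applicable, categorised, and the maximum category returned.
    """
    if not predictions:
        raise ValidationError("aggregate_models requires at least one prediction")
    cats = [
        categorize_bioavailability(apply_insilico_uf(p.cmax_um, p.input_source, uf), cutoffs)
        for p in predictions
    ]
    worst = max(cats)
    log.info("%s: per-model categories %s -> worst case %s",
             predictions[0].chem_id, [c.value for c in cats], worst.value)
    return worst


def calibrate_cutoffs(cmax_values: Sequence[float], q_low: float = 0.25,
                      q_high: float = 0.75) -> tuple[float, float]:
    """Empirical-quantile calibration of the bioavailability cutoffs.

    Returns (low_below, high_above) as the q_low and q_high quantiles
    (linear interpolation of order statistics) of a Cmax population, so the
    three bands split the population roughly q_low / (q_high - q_low) /
    (1 - q_high).
    """
    if len(cmax_values) < 4:
        raise ValidationError("cutoff calibration needs at least 4 Cmax values")
    if not (0 < q_low < q_high < 1):
        raise ValidationError("quantiles must satisfy 0 < q_low < q_high < 1")
    lo, hi = np.quantile(np.asarray(cmax_values, dtype=float), [q_low, q_high],
                         method="linear")
    return float(lo), float(hi)


def compare_durations(pk: PKParameters, durations: Sequence[int],
                      dose_mmol_per_kg: float = 0.1,
                      phys: Optional[Physiology] = None) -> dict[int, float]:
    """Cmax (µM) for each simulation duration in days (accumulation check)."""
    out = {}
    for d in durations:
        if d < 1:
            raise ValidationError("durations must be >= 1 day")
        out[d] = simulate_cmax(pk, DosingProtocol(dose=dose_mmol_per_kg, n_days=d), phys)
    return out
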