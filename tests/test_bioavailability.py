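"""Toxicokinetics: dose equivalence, IVIVE scaling, the repeat-dose
simulator against an independent closed-form superposition oracle, and
Cmax categorisation/calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from namloc import (
    CmaxPrediction,
    DosingProtocol,
    Level,
    PKParameters,
    Physiology,
    UnsupportedRouteError,
    ValidationError,
)
from namloc.bioavailability import (
    aggregate_models,
    apply_insilico_uf,
    calibrate_cutoffs,
    categorize_bioavailability,
    compare_durations,
    dose_equivalence,
    scale_clearance,
    simulate,
    simulate_cmax,
    total_clearance,
)


def bateman_cmax(pk: PKParameters, protocol: DosingProtocol,
                 phys: Physiology) -> float:
    """Independent oracle: exact superposition of one-compartment oral doses.

    C(t) = (F D / V) * ka/(ka-ke) * sum_i [exp(-ke(t-t_i)) - exp(-ka(t-t_i))]
    evaluated on a dense grid with local refinement.  Shares no code with
    the package's ODE integrator.
    """
    v = pk.vd * phys.body_weight
    ke = total_clearance(pk, phys) / v
    ka = pk.ka
    dose = pk.f_abs * protocol.dose * phys.body_weight
    times = np.arange(protocol.n_days) * 24.0

    def conc(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dt = t[:, None] - times[None, :]
        mask = dt >= 0
        dt = np.where(mask, dt, 0.0)  # avoid exp overflow on masked entries
        if abs(ka - ke) < 1e-9 * ka:
            terms = dose * ka * dt * np.exp(-ka * dt)
        else:
            terms = dose * ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
        return (terms * mask).sum(axis=1) / v * 1000.0

    horizon = times[-1] + min(10.0 / max(ke, 1e-6), 24.0 * 400)
    grid = np.linspace(0.0, horizon, 40001)
    vals = conc(grid)
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: -conc(t)[0], bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return max(float(vals[i]), float(-res.fun))


# --- dose equivalence ------------------------------------------------------

@pytest.mark.parametrize("mw,mg_kg,g_person", [
    (50.0, 5.0, 0.35),
    (250.0, 25.0, 1.75),
    (600.0, 60.0, 4.2),
])
def test_dose_equivalence_at_standard_protocol(mw, mg_kg, g_person):
    eq = dose_equivalence(mw, 0.1, 70.0)
    assert eq.mg_per_kg == pytest.approx(mg_kg)
    assert eq.g_per_person == pytest.approx(g_person)
    assert eq.total_mmol == pytest.approx(7.0)


def test_dose_equivalence_rejects_non_positive_inputs():
    with pytest.raises(ValidationError):
        dose_equivalence(-250.0)


# --- IVIVE scaling ---------------------------------------------------------

def test_zero_clint_gives_zero_hepatic_clearance():
    pk = PKParameters("c", 250, 0.0, 0.5)
    assert scale_clearance(pk) == 0.0


def test_flow_limited_asymptote():
    """fup = 1 with very large CLint approaches liver blood flow within 1%."""
    pk = PKParameters("c", 250, 1e7, 1.0)
    phys = Physiology()
    cl = scale_clearance(pk, phys)
    assert cl < phys.liver_blood_flow
    assert cl == pytest.approx(phys.liver_blood_flow, rel=0.01)


def test_well_stirred_formula_hand_value():
    """clint=10, fup=0.5 under default physiology, evaluated independently."""
    clu_whole = 10.0 * 110.0 * 1470.0 * 60.0 / 1e6       # L/h
    expected = 90.0 * 0.5 * clu_whole / (90.0 + 0.5 * clu_whole)
    pk = PKParameters("c", 250, 10.0, 0.5)
    assert scale_clearance(pk) == pytest.approx(expected, rel=1e-12)


# --- simulator -------------------------------------------------------------

def test_single_dose_no_elimination_is_dose_over_volume():
    pk = PKParameters("c", 250, 0.0, 1.0, ka=1000.0, renal_mode="none")
    assert simulate_cmax(pk, DosingProtocol(n_days=1)) == pytest.approx(100.0)


def test_fourteen_doses_no_elimination_accumulate_linearly():
    pk = PKParameters("c", 250, 0.0, 1.0, ka=1000.0, renal_mode="none")
    assert simulate_cmax(pk, DosingProtocol(n_days=14)) == pytest.approx(1400.0)


@pytest.mark.parametrize("ka", [0.3, 1.0, 3.0])
@pytest.mark.parametrize("clint", [1.0, 10.0, 60.0])
@pytest.mark.parametrize("n_days", [1, 14])
def test_integrator_matches_superposition_oracle(ka, clint, n_days):
    """Numerical Cmax agrees with the closed-form oracle within 0.1%."""
    pk = PKParameters("c", 250, clint, 0.5, ka=ka)
    protocol = DosingProtocol(n_days=n_days)
    phys = Physiology()
    assert simulate_cmax(pk, protocol, phys) == pytest.approx(
        bateman_cmax(pk, protocol, phys), rel=1e-3)


def test_integrator_matches_oracle_near_absorption_elimination_degeneracy():
    pk = PKParameters("c", 250, 0.0, 0.07, ka=0.0067, renal_mode="gfr_fup")
    # ke = gfr*fup/V ~ ka: exercises the near-equal-rates branch
    protocol = DosingProtocol(n_days=14)
    phys = Physiology()
    assert simulate_cmax(pk, protocol, phys) == pytest.approx(
        bateman_cmax(pk, protocol, phys), rel=1e-3)


def test_cmax_monotone_decreasing_in_clearance():
    cmaxes = [simulate_cmax(PKParameters("c", 250, clint, 0.5))
              for clint in (0.0, 5.0, 50.0)]
    assert cmaxes[0] > cmaxes[1] > cmaxes[2]


def test_molar_cmax_independent_of_molecular_weight():
    """The mmol/kg dose deliberately does not penalise heavy molecules."""
    a = simulate_cmax(PKParameters("c", 100.0, 10.0, 0.5))
    b = simulate_cmax(PKParameters("c", 800.0, 10.0, 0.5))
    assert a == pytest.approx(b, rel=1e-12)


def test_auc_reported_alongside():
    res = simulate(PKParameters("c", 250, 10.0, 0.5))
    assert res.auc_um_h > 0


def test_non_oral_route_is_rejected():
    with pytest.raises(UnsupportedRouteError):
        DosingProtocol(route="dermal")


# --- durations -------------------------------------------------------------

def test_no_elimination_cmax_scales_with_duration():
    pk = PKParameters("c", 250, 0.0, 1.0, ka=1000.0, renal_mode="none")
    out = compare_durations(pk, [1, 14, 365])
    assert out[14] / out[1] == pytest.approx(14.0)
    assert out[365] / out[1] == pytest.approx(365.0)


def test_short_half_life_saturates_by_day_14():
    """Half-life ~6 h: the accumulation ratio 1/(1-exp(-ke tau)) is fully
    saturated, so the 14- and 365-day Cmax agree within 1%."""
    phys = Physiology()
    ke = math.log(2) / 6.0
    cl = ke * 70.0  # vd=1 L/kg
    # realise the clearance through renal_mode=none and a solved clint
    clu = phys.liver_blood_flow * cl / (1.0 * (phys.liver_blood_flow - cl))
    clint = clu * 1e6 / (phys.hepatocellularity * phys.liver_mass * 60.0)
    pk = PKParameters("c", 250, clint, 1.0, renal_mode="none")
    out = compare_durations(pk, [1, 14, 365])
    tol = 1 + 1e-6  # integrator noise on fully saturated accumulation
    assert out[1] <= out[14] * tol and out[14] <= out[365] * tol
    assert out[365] == pytest.approx(out[14], rel=0.01)


def test_cmax_non_decreasing_in_duration():
    pk = PKParameters("c", 250, 2.0, 0.3)
    out = compare_durations(pk, [1, 7, 14])
    tol = 1 + 1e-6
    assert out[1] <= out[7] * tol and out[7] <= out[14] * tol


def test_population_deciles_day14_vs_day365():
    """For half-lives below ~2 days the 14-day and 365-day Cmax populations
    agree within 5% at every decile, while 1-day values sit strictly lower."""
    rng = np.random.default_rng(7)
    d1, d14, d365 = [], [], []
    for _ in range(6):
        clint = float(rng.uniform(2.0, 40.0))
        fup = float(rng.uniform(0.3, 1.0))
        pk = PKParameters("c", 250, clint, fup)
        out = compare_durations(pk, [1, 14, 365])
        d1.append(out[1]); d14.append(out[14]); d365.append(out[365])
    q = np.linspace(0.1, 0.9, 9)
    q14, q365 = np.quantile(d14, q), np.quantile(d365, q)
    assert np.all(np.abs(q365 - q14) / q14 < 0.05)
    assert all(a < b for a, b in zip(d1, d14))


# --- categorisation and calibration ----------------------------------------

def test_uncertainty_factor_applies_to_in_silico_inputs_only():
    assert apply_insilico_uf(100.0, "in_silico", 3.0) == 300.0
    assert apply_insilico_uf(100.0, "in_vitro", 3.0) == 100.0
    assert apply_insilico_uf(0.0, "in_silico", 3.0) == 0.0


@pytest.mark.parametrize("cmax,cutoffs,cat", [
    (20.0, (50.0, 500.0), Level.LOW),
    (600.0, (50.0, 500.0), Level.HIGH),
    (50.0, (50.0, 500.0), Level.MEDIUM),   # boundary belongs to Medium
    (20.0, (10.0, 100.0), Level.MEDIUM),   # alternative scheme
])
def test_categorize_bioavailability(cmax, cutoffs, cat):
    assert categorize_bioavailability(cmax, cutoffs) is cat


def test_categorize_rejects_negative_cmax():
    with pytest.raises(ValidationError):
        categorize_bioavailability(-1.0)


def test_aggregate_models_is_worst_case():
    mk = lambda v, src="in_vitro": CmaxPrediction("c", "m", v, src)
    assert aggregate_models([mk(20.0), mk(30.0), mk(100.0)]) is Level.MEDIUM
    assert aggregate_models([mk(20.0)]) is Level.LOW
    assert aggregate_models([mk(600.0), mk(20.0)]) is Level.HIGH
    # UF can push an in silico prediction across a cutoff
    assert aggregate_models([mk(20.0, "in_silico")]) is Level.MEDIUM
    with pytest.raises(ValidationError):
        aggregate_models([])


def test_calibrate_cutoffs_on_uniform_distribution():
    rng = np.random.default_rng(0)
    values = rng.uniform(0.0, 1000.0, size=1000)
    lo, hi = calibrate_cutoffs(values, 0.25, 0.75)
    assert lo == pytest.approx(250.0, abs=30.0)
    assert hi == pytest.approx(750.0, abs=30.0)


def test_calibrate_cutoffs_degenerate_and_hand_quartiles():
    lo, hi = calibrate_cutoffs([5.0] * 10)
    assert lo == hi == 5.0
    # order statistics of {10,20,30,40} with linear interpolation:
    # q25 at position 1.75 -> 17.5; q75 at position 3.25 -> 32.5
    lo, hi = calibrate_cutoffs([10.0, 20.0, 30.0, 40.0], 0.25, 0.75)
    assert (lo, hi) == (17.5, 32.5)
    with pytest.raises(ValidationError):
        calibrate_cutoffs([1.0, 2.0, 3.0])
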