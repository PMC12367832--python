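"""Potency banding, severity lexicon, matrix construction and rule sets."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from namloc import (
    AssayResult,
    BioactivityMatrix,
    Level,
    LevelOfConcern,
    MAX_RED,
    MIN_RED,
    POT_ONLY,
    Provenance,
    RULESETS,
    ValidationError,
)
from namloc.bioactivity import (
    CapabilityMap,
    apply_outlier_rule,
    assign_severity,
    band_potency,
    build_matrix,
    coverage_check,
    matrix_to_loc,
    worst_case_family,
)
from namloc.fixtures import fixture_chloroaniline, fixture_ouabain_assays

CUTOFFS = (0.1, 10.0)


@pytest.mark.parametrize("ac50,band", [
    (0.05, Level.HIGH),
    (0.1, Level.MEDIUM),   # boundaries belong to the closed middle band
    (1.0, Level.MEDIUM),
    (10.0, Level.MEDIUM),
    (50.0, Level.LOW),
])
def test_band_potency(ac50, band):
    assert band_potency(ac50, CUTOFFS) is band


@pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
def test_band_potency_rejects_degenerate_ac50(bad):
    with pytest.raises(ValidationError):
        band_potency(bad, CUTOFFS)


def test_lexicon_reproduces_all_printed_severities(lexicon):
    """The shipped lexicon assigns every chloroaniline assay its printed
    implied severity."""
    for f in fixture_chloroaniline():
        assert assign_severity(f.assay, lexicon) is f.implied_severity, f.assay.assay_name


@pytest.mark.parametrize("family,sub,process,severity", [
    ("Cell cycle", "Proliferation", "Cell death", Level.HIGH),
    ("Nuclear receptor", "Non-steroidal", "Protein stabilisation", Level.MEDIUM),
    ("Transferase", "Glucuronosyltransferase",
     "Regulation of transcription factor activity", Level.LOW),
    ("Nuclear receptor", "PPAR", "Receptor binding", Level.LOW),
    ("Nuclear receptor", "Steroidal - agonist", "Receptor agonist activity", Level.HIGH),
    ("Never", "Seen", "Descriptors", Level.MEDIUM),  # fallback
])
def test_severity_lexicon_entries(lexicon, family, sub, process, severity):
    assay = AssayResult("c", "a", family, sub, process, "t", True, 1.0)
    assert assign_severity(assay, lexicon) is severity


def test_matrix_matches_independent_tally_of_printed_letters(lexicon):
    """Cell counts equal a hand tally over the printed (severity, potency)
    letter pairs, computed here without the matrix code path."""
    fixture = fixture_chloroaniline()
    tally = Counter((f.potency, f.implied_severity) for f in fixture)
    m = build_matrix([f.assay for f in fixture], CUTOFFS, lexicon)
    for cell, n in m.counts.items():
        assert n == tally.get(cell, 0)
    assert m.n_inactive == 0 and m.n_assays == 19


def test_matrix_identity_and_single_element_cases(lexicon):
    inactive = [AssayResult("c", f"a{i}", "f", "s", "p", "t", False)
                for i in range(5)]
    m = build_matrix(inactive, CUTOFFS, lexicon)
    assert m.occupied == [] and m.n_inactive == 5

    one = [AssayResult("c", "a", "Cell cycle", "Proliferation", "Cell death",
                       "t", True, 0.01)]
    m1 = build_matrix(one, CUTOFFS, lexicon)
    assert m1.counts[(Level.HIGH, Level.HIGH)] == 1
    assert sum(m1.counts.values()) == 1


def test_matrix_rejects_mixed_chemicals(lexicon):
    assays = [AssayResult("c1", "a", "f", "s", "p", "t", False),
              AssayResult("c2", "b", "f", "s", "p", "t", False)]
    with pytest.raises(ValidationError):
        build_matrix(assays, CUTOFFS, lexicon)


def single_cell_matrix(pot, sev):
    return BioactivityMatrix({(pot, sev): 1}, n_inactive=0, n_assays=1)


def test_carbaryl_pattern_under_the_three_rulesets():
    m = single_cell_matrix(Level.HIGH, Level.LOW)
    assert matrix_to_loc(m, MIN_RED).level is Level.LOW
    assert matrix_to_loc(m, MAX_RED).level is Level.MEDIUM
    assert matrix_to_loc(m, POT_ONLY).level is Level.HIGH


def test_high_high_cell_forces_high_everywhere():
    m = single_cell_matrix(Level.HIGH, Level.HIGH)
    for rs in RULESETS.values():
        assert matrix_to_loc(m, rs).level is Level.HIGH


@pytest.mark.parametrize("pot", list(Level))
@pytest.mark.parametrize("sev", list(Level))
def test_single_cell_exhaustive_under_default_maps(pot, sev):
    """Exhaustive single-cell evaluation: the level equals the rule-set cell
    value, and the three maps are ordered min_red <= max_red <= pot_only."""
    m = single_cell_matrix(pot, sev)
    levels = [matrix_to_loc(m, rs).level for rs in (MIN_RED, MAX_RED, POT_ONLY)]
    assert levels == [MIN_RED[(pot, sev)], MAX_RED[(pot, sev)], POT_ONLY[(pot, sev)]]
    assert levels[0] <= levels[1] <= levels[2]


def test_empty_matrix_is_low_on_this_axis():
    m = BioactivityMatrix({}, n_inactive=3, n_assays=3)
    loc = matrix_to_loc(m, MIN_RED)
    assert loc.level is Level.LOW
    assert loc.provenance is Provenance.EVIDENCE_BASED


# --- outlier rule ----------------------------------------------------------

def er_assay(name, ac50):
    return AssayResult("ouabain", name, "Nuclear receptor", "Steroidal - agonist",
                       "Receptor agonist activity", "Uterus", True, ac50)


def test_lone_high_hit_with_concordant_family_is_demoted(lexicon):
    loc, flag = apply_outlier_rule(fixture_ouabain_assays(), CUTOFFS, lexicon,
                                   MIN_RED, min_concordant=3)
    assert loc.level is Level.MEDIUM
    assert flag == "TOX21_ERa_BLA_Agonist_ratio"


def test_lone_high_hit_without_family_is_kept(lexicon):
    assays = [er_assay("hit", 0.05)]
    loc, flag = apply_outlier_rule(assays, CUTOFFS, lexicon, MIN_RED, 3)
    assert loc.level is Level.HIGH and flag is None


def test_two_high_hits_are_never_demoted(lexicon):
    """Demotion requires a singleton in the level-setting cell."""
    assays = [er_assay("hit1", 0.05), er_assay("hit2", 0.06)]
    assays += [er_assay(f"mid{i}", 1.0) for i in range(5)]
    loc, flag = apply_outlier_rule(assays, CUTOFFS, lexicon, MIN_RED, 3)
    assert loc.level is Level.HIGH and flag is None


def test_too_few_concordant_assays_do_not_demote(lexicon):
    assays = [er_assay("hit", 0.05)] + [er_assay(f"mid{i}", 1.0) for i in range(2)]
    loc, flag = apply_outlier_rule(assays, CUTOFFS, lexicon, MIN_RED, 3)
    assert loc.level is Level.HIGH and flag is None


# --- coverage check --------------------------------------------------------

def test_uncovered_hazards_are_reported(capability_map):
    panel = [f.assay for f in fixture_chloroaniline()]
    assert coverage_check(["methemoglobinemia"], panel, capability_map) == \
        ["methemoglobinemia"]
    assert coverage_check(["cardiotoxicity"], panel, capability_map) == \
        ["cardiotoxicity"]
    # steroidogenesis assays are present in the panel
    assert coverage_check(["steroidogenesis"], panel, capability_map) == []
    assert coverage_check([], panel, capability_map) == []


def test_unknown_hazard_tag_is_conservatively_uncovered(capability_map):
    panel = [f.assay for f in fixture_chloroaniline()]
    assert coverage_check(["telepathy"], panel, capability_map) == ["telepathy"]


def test_worst_case_family():
    low = LevelOfConcern(Level.LOW)
    high = LevelOfConcern(Level.HIGH)
    assert worst_case_family(low, [high]).level is Level.HIGH
    assert worst_case_family(low).level is Level.LOW
    mix = worst_case_family(
        LevelOfConcern(Level.MEDIUM),
        [LevelOfConcern(Level.MEDIUM),
         LevelOfConcern(Level.HIGH, Provenance.DEFAULT_INSUFFICIENT_EVIDENCE)])
    assert mix.level is Level.HIGH
    assert mix.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE


# --- properties ------------------------------------------------------------

severities = {
    Level.HIGH: ("Cell cycle", "Proliferation", "Cell death"),
    Level.MEDIUM: ("Nuclear receptor", "Non-steroidal", "Protein stabilisation"),
    Level.LOW: ("Cyp", "Xenobiotic metabolism", "induction"),
}


@st.composite
def panels(draw):
    n = draw(st.integers(0, 25))
    out = []
    for i in range(n):
        active = draw(st.booleans())
        sev = draw(st.sampled_from(list(Level)))
        fam, sub, proc = severities[sev]
        ac50 = draw(st.floats(1e-4, 1e4)) if active else None
        out.append(AssayResult("c", f"a{i}", fam, sub, proc, "t", active, ac50))
    return out


@settings(max_examples=100, derandomize=True)
@given(panels())
def test_matrix_conserves_assay_count(lexicon, assays):
    m = build_matrix(assays, CUTOFFS, lexicon)
    assert sum(m.counts.values()) + m.n_inactive == len(assays)


cell_counts = st.dictionaries(
    st.tuples(st.sampled_from(list(Level)), st.sampled_from(list(Level))),
    st.integers(0, 5), max_size=9,
)


@settings(max_examples=200, derandomize=True)
@given(cell_counts)
def test_ruleset_ordering_on_random_matrices(counts):
    """min_red <= max_red <= pot_only for every matrix: the revised map is
    uniformly more conservative, and dropping severity more still."""
    total = sum(counts.values())
    m = BioactivityMatrix(counts, n_inactive=0, n_assays=total)
    lo = matrix_to_loc(m, MIN_RED).level
    mid = matrix_to_loc(m, MAX_RED).level
    hi = matrix_to_loc(m, POT_ONLY).level
    assert lo <= mid <= hi


@settings(max_examples=200, derandomize=True)
@given(st.floats(1e-4, 1e5), st.floats(1.0, 10.0))
def test_raising_cutoffs_never_lowers_the_potency_band(ac50, k):
    """Scaling both cutoffs by k >= 1 enlarges the High band and shrinks the
    Low band, so an assay's classification can only move toward High."""
    before = band_potency(ac50, CUTOFFS)
    after = band_potency(ac50, (CUTOFFS[0] * k, CUTOFFS[1] * k))
    assert after >= before


@settings(max_examples=200, derandomize=True)
@given(
    st.sampled_from([0.05, 2.0, 9.0, 200.0, 1e4]),  # clear of (0.1,1] and (10,100]
    st.sampled_from([1.0, 2.0, 5.0, 10.0]),
)
def test_bands_stable_when_ac50s_avoid_the_shifted_windows(ac50, k):
    """AC50s outside (cutoff, 10 x cutoff] keep their band when both cutoffs
    are raised by up to a factor of 10."""
    assert band_potency(ac50, CUTOFFS) is band_potency(
        ac50, (CUTOFFS[0] * k, CUTOFFS[1] * k))
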