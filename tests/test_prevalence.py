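"""Flagging, rounding, stratified tables, and the Fisher exact test."""

from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from sensiterm.lexicon import CATEGORIES
from sensiterm.matching import MatchRecord, compile_matcher, match_corpus
from sensiterm.prevalence import (PrevalenceError, age_category_curve,
                                  age_notetype_heatmap, compare_groups,
                                  fisher_exact, flag_notes, percent,
                                  prevalence, stratified_prevalence,
                                  top_terms)
from sensiterm.synthetic_corpus import (default_config, default_lexicon,
                                        expected_rate_by, generate_corpus)
from .conftest import make_note


# ------------------------------------------------------------------ percent

@pytest.mark.parametrize("num,den,prec,expected", [
    (501762, 1338297, 2, 37.49),
    (19854, 34771, 1, 57.1),
    (478, 1620, 0, 30.0),   # 29.506 rounds up at integer precision
    (0, 7, 2, 0.0),
    (1, 800, 2, 0.13),      # 0.125% rounds half-away-from-zero
])
def test_percent_half_away_from_zero(num, den, prec, expected):
    assert percent(num, den, prec) == expected


def test_prevalence_validation():
    with pytest.raises(PrevalenceError):
        prevalence(1, 0)
    with pytest.raises(PrevalenceError):
        prevalence(5, 4)
    assert prevalence(0, 10).formatted == "0.00%"


# ----------------------------------------------------------------- flagging

def test_flags_follow_match_categories(three_notes):
    matches = [MatchRecord("N2", "anxiety", "mental_health", [(0, 7)])]
    flags = flag_notes(matches, three_notes)
    assert bool(flags.loc["N2", "any"]) and bool(
        flags.loc["N2", "mental_health"])
    assert not flags.loc["N2", "substance_use"]
    assert not flags.loc["N1", "any"]


def test_orphan_match_rejected(three_notes):
    bad = [MatchRecord("NX", "anxiety", "mental_health", [(0, 7)])]
    with pytest.raises(PrevalenceError, match="NX"):
        flag_notes(bad, three_notes)


def test_any_flag_equals_distinct_note_count(small_corpus):
    _, notes, _ = small_corpus
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    flags = flag_notes(records, notes)
    assert int(flags["any"].sum()) == len({r.note_id for r in records})


# ------------------------------------------------------------ stratification

def test_single_stratum_equals_global(three_notes):
    matches = [MatchRecord("N1", "etoh", "substance_use", [(15, 19)])]
    flags = flag_notes(matches, three_notes)
    cells = stratified_prevalence(three_notes, flags, by=["setting"])
    total = cells["n_notes"].sum()
    assert total == 3
    amb = cells[cells["setting"] == "inpatient"].iloc[0]
    assert amb["proportion"] == 1.0


def test_partition_invariant_age_by_notetype(small_corpus):
    _, notes, _ = small_corpus
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    flags = flag_notes(records, notes)
    cells = stratified_prevalence(notes, flags,
                                  by=["age_years", "note_type"])
    assert cells["n_notes"].sum() == len(notes)
    assert ((cells["n_flagged"] >= 0) &
            (cells["n_flagged"] <= cells["n_notes"])).all()


def test_unknown_variable_rejected(three_notes):
    flags = flag_notes([], three_notes)
    with pytest.raises(PrevalenceError, match="zodiac"):
        stratified_prevalence(three_notes, flags, by=["zodiac"])


def test_stratum_rates_track_configured_note_type_rates(small_corpus):
    cfg, notes, _ = small_corpus
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    flags = flag_notes(records, notes)
    cells = stratified_prevalence(notes, flags, by=["note_type"])
    expected = expected_rate_by(cfg, "note_type")
    for _, row in cells.iterrows():
        p = expected[row["note_type"]]
        if row["n_notes"] < 200:
            continue
        se = (p * (1 - p) / row["n_notes"]) ** 0.5
        assert abs(row["proportion"] - p) < 3 * se


# ---------------------------------------------------------------- top terms

def test_top_terms_sorting_and_ties():
    agg = pd.DataFrame({
        "surface": ["b", "a", "c"],
        "category": ["mental_health"] * 3,
        "term_frequency": [5, 9, 5],
        "note_frequency": [4, 6, 3]})
    top = top_terms(agg, "mental_health", n=10)
    assert list(top["surface"]) == ["a", "b", "c"]  # tie b/c lexicographic
    with pytest.raises(PrevalenceError):
        top_terms(agg, "astrology")


# ------------------------------------------------------------- fisher exact

def _fisher_oracle(a, b, c, d):
    """Exact-rational enumeration, independent of the implementation."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
           for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def test_fisher_balanced_table_is_one():
    assert fisher_exact([[5, 5], [5, 5]]) == 1.0


def test_fisher_hand_enumerated_example():
    assert fisher_exact([[1, 9], [11, 3]]) == \
        pytest.approx(_fisher_oracle(1, 9, 11, 3), abs=1e-12)
    assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(0.00276, abs=5e-5)


def test_fisher_margin_validation():
    with pytest.raises(PrevalenceError):
        fisher_exact([[0, 0], [1, 2]])
    with pytest.raises(PrevalenceError):
        fisher_exact([[-1, 2], [3, 4]])


def test_fisher_agrees_with_scipy_on_random_tables(rng):
    from scipy.stats import fisher_exact as scipy_fisher
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        ours = fisher_exact([[a, b], [c, d]])
        theirs = scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(theirs, abs=1e-10)


def test_compare_groups_identical_cells_not_significant():
    p, sig = compare_groups((50, 100), (50, 100))
    assert p == 1.0 and not sig


def test_compare_groups_large_observed_difference():
    p, sig = compare_groups((5701, 6707), (2128, 2589))
    assert p < 0.05 and sig


def test_compare_groups_bonferroni_scales_alpha():
    p, sig = compare_groups((30, 100), (45, 100))
    _, sig_corrected = compare_groups((30, 100), (45, 100), bonferroni_m=100)
    assert sig and not sig_corrected


# -------------------------------------------------------------- figure data

def test_age_category_curve_shape(small_corpus):
    cfg, notes, _ = small_corpus
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    flags = flag_notes(records, notes)
    curve = age_category_curve(notes, flags)
    ages_present = {n.age_years for n in notes}
    assert set(curve["category"]) == set(CATEGORIES)
    per_age = curve[curve["category"] == "mental_health"].set_index(
        "age_years")
    assert set(per_age.index) == ages_present
    # denominators per age equal the age's note count
    age_counts = pd.Series([n.age_years for n in notes]).value_counts()
    for age, row in per_age.iterrows():
        assert row["n_notes"] == age_counts[age]


def test_zero_plant_curve_all_zero():
    cfg = default_config(n_patients=50, rng_seed=5)
    cfg.plant_rates = {k: 0.0 for k in cfg.plant_rates}
    notes, _ = generate_corpus(cfg)
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    flags = flag_notes(records, notes)
    curve = age_category_curve(notes, flags)
    assert (curve["proportion"] == 0).all()


def test_heatmap_single_note_and_absent_strata():
    notes = [make_note("N1", "anxiety noted", "hp", 15,
                       setting="inpatient", specialty="hospital_medicine")]
    flags = flag_notes(
        [MatchRecord("N1", "anxiety", "mental_health", [(0, 7)])], notes)
    heat = age_notetype_heatmap(notes, flags)
    assert len(heat) == 1
    row = heat.iloc[0]
    assert (row["age_years"], row["note_type"], row["proportion"]) == \
        (15, "hp", 1.0)
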