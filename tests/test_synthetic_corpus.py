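"""Generator determinism, plant-rate recovery, and spelling corruption."""

import math

import numpy as np
import pytest

from sensiterm._textutil import damerau_levenshtein
from sensiterm.corpus_io import notes_to_jsonl_str
from sensiterm.lexicon import CATEGORIES
from sensiterm.matching import compile_matcher, match_corpus
from sensiterm.synthetic_corpus import (ConfigurationError, GroundTruth,
                                        age_band, corrupt_spelling,
                                        default_config, default_lexicon,
                                        default_templates, expected_flag_rate,
                                        expected_rate_by, generate_corpus)


def test_default_config_marginals():
    cfg = default_config()
    assert sum(cfg.encounter_mix.values()) == pytest.approx(1.0, abs=1e-9)
    assert cfg.encounter_mix["ambulatory"] == pytest.approx(0.703, abs=5e-4)
    assert float(np.sum(cfg.age_distribution[:13])) == \
        pytest.approx(0.7484, abs=1e-3)
    # adolescent mental-health documentation exceeds mid-childhood
    assert cfg.plant_rates[("mental_health", age_band(16), "hp")] > \
        cfg.plant_rates[("mental_health", age_band(6), "hp")]
    # infancy elevation for substance use / reproductive health
    assert cfg.plant_rates[("substance_use", age_band(0), "apn")] > \
        cfg.plant_rates[("substance_use", age_band(6), "apn")]
    assert expected_flag_rate(cfg) == pytest.approx(0.375, abs=0.005)


def test_determinism_byte_identical():
    cfg = default_config(n_patients=50, rng_seed=3)
    n1, t1 = generate_corpus(cfg)
    n2, t2 = generate_corpus(default_config(n_patients=50, rng_seed=3))
    assert notes_to_jsonl_str(n1) == notes_to_jsonl_str(n2)
    assert t1.planted == t2.planted
    n3, _ = generate_corpus(default_config(n_patients=50, rng_seed=4))
    assert notes_to_jsonl_str(n1) != notes_to_jsonl_str(n3)


def test_zero_plant_rate_gives_pure_filler():
    cfg = default_config(n_patients=60, rng_seed=5)
    cfg.plant_rates = {k: 0.0 for k in cfg.plant_rates}
    notes, truth = generate_corpus(cfg)
    assert truth.flagged_note_ids() == set()
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    assert records == []


def test_certain_plant_rate_flags_every_note():
    cfg = default_config(n_patients=40, rng_seed=6)
    cfg.plant_rates = {k: (1.0 if k[0] == "mental_health" else 0.0)
                      for k in cfg.plant_rates}
    cfg.max_rate = 1.0
    notes, truth = generate_corpus(cfg)
    assert truth.flagged_note_ids("mental_health") == \
        {n.note_id for n in notes}


def test_planted_terms_present_verbatim(small_corpus):
    _, notes, truth = small_corpus
    by_id = {n.note_id: n for n in notes}
    for nid, terms in truth.planted.items():
        for t in terms:
            assert t.surface in by_id[nid].text.casefold()


def test_matcher_recovers_ground_truth_exactly(small_corpus):
    """Token-mode matching on the synthetic corpus has precision=recall=1,
    at note level and at per-note category level."""
    _, notes, truth = small_corpus
    records, _ = match_corpus(notes, compile_matcher(default_lexicon()))
    assert {r.note_id for r in records} == truth.flagged_note_ids()
    found: dict[str, set] = {}
    for r in records:
        found.setdefault(r.note_id, set()).add(r.category)
    for nid in truth.planted:
        assert found.get(nid, set()) == truth.categories_for(nid)


def test_plant_rate_recovery_within_3se(small_corpus):
    cfg, notes, truth = small_corpus
    flagged = truth.flagged_note_ids()
    p_exp = expected_flag_rate(cfg)
    n = len(notes)
    se = math.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(len(flagged) / n - p_exp) < 3 * se
    # per note type, where the stratum is populated enough
    by_type_exp = expected_rate_by(cfg, "note_type")
    counts: dict[str, list[int]] = {}
    for note in notes:
        tot_flag = counts.setdefault(note.note_type, [0, 0])
        tot_flag[0] += 1
        tot_flag[1] += int(note.note_id in flagged)
    for nt, (tot, flag) in counts.items():
        if tot < 200:
            continue
        p = by_type_exp[nt]
        assert abs(flag / tot - p) < 3 * math.sqrt(p * (1 - p) / tot)


def test_template_coverage_required():
    cfg = default_config(n_patients=5, rng_seed=0)
    templates = default_templates()
    del templates.headers["hp"]
    with pytest.raises(ConfigurationError, match="hp"):
        generate_corpus(cfg, templates=templates)


def test_filler_contamination_detected():
    cfg = default_config(n_patients=5, rng_seed=0)
    templates = default_templates()
    templates.filler.append("patient reports anxiety daily .")
    with pytest.raises(ConfigurationError, match="anxiety"):
        generate_corpus(cfg, templates=templates)


def test_ground_truth_round_trip(tmp_path, small_corpus):
    _, _, truth = small_corpus
    p = truth.write_jsonl(tmp_path / "gt.jsonl")
    assert GroundTruth.read_jsonl(p).planted == truth.planted


def test_corrupt_spelling_contract(rng):
    assert damerau_levenshtein(corrupt_spelling("alcohol", rng),
                               "alcohol") == 1
    with pytest.raises(ValueError):
        corrupt_spelling("si", rng)
    variants = {corrupt_spelling("marijuana", rng) for _ in range(1000)}
    assert len(variants) >= 2
    assert all(damerau_levenshtein(v, "marijuana") == 1 for v in variants)
    assert "marijuana" not in variants


def test_corrupt_spelling_deterministic():
    a = [corrupt_spelling("tobacco", np.random.default_rng(9))
         for _ in range(1)]
    b = [corrupt_spelling("tobacco", np.random.default_rng(9))
         for _ in range(1)]
    assert a == b
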