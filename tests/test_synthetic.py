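"""Synthetic corpus generator: determinism, forced regimes, ground-truth recovery."""

from __future__ import annotations

import numpy as np
import pytest

from extracteval.evaluate import evaluate_datasets
from extracteval.normalization import NormalizationPolicy
from extracteval.synthetic import (
    ChannelNotApplicableError,
    PerturbationRates,
    SyntheticSpec,
    default_mean_entries,
    generate_corpus,
    load_lexicon,
    perturb_term,
)
from extracteval.term_matching import MatchPolicy, eligible


def _zero_rates(**overrides):
    zeros = dict(
        near_typo=0, synonym_swap=0, split_compound=0, omission=0,
        spurious_addition=0, duplicate_inflation=0, both_none_reported=0,
        coordinate_jitter_within=0, coordinate_jitter_beyond=0, year_drift=0,
    )
    zeros.update(overrides)
    return PerturbationRates(**zeros)


def _assert_recovery(spec):
    manual, automated, truth = generate_corpus(spec)
    result = evaluate_datasets(manual, automated)
    assert result.confusion_by_attribute == truth.per_attribute()
    return manual, automated, truth, result


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        spec = SyntheticSpec(n_articles=6, seed=11)
        m1, a1, t1 = generate_corpus(spec)
        m2, a2, t2 = generate_corpus(spec)
        assert m1.records == m2.records
        assert a1.records == a2.records
        assert t1.cells == t2.cells

    def test_different_seed_different_corpus(self):
        m1, _, _ = generate_corpus(SyntheticSpec(n_articles=6, seed=1))
        m2, _, _ = generate_corpus(SyntheticSpec(n_articles=6, seed=2))
        assert m1.records != m2.records


class TestForcedRegimes:
    def test_pure_copies_give_perfect_metrics(self):
        spec = SyntheticSpec(n_articles=10, seed=3, rates=_zero_rates())
        manual, automated, truth, result = _assert_recovery(spec)
        pooled = result.pooled()
        assert pooled.fp == 0 and pooled.fn == 0 and pooled.tp > 0
        from extracteval.metrics import compute_metrics

        m = compute_metrics(pooled)
        assert m.precision == m.recall == m.accuracy == m.f1 == 1.0

    def test_total_omission_forces_zero_recall(self):
        spec = SyntheticSpec(n_articles=10, seed=4, rates=_zero_rates(omission=1))
        manual, automated, truth, result = _assert_recovery(spec)
        pooled = result.pooled()
        assert pooled.tp == 0 and pooled.fp == 0
        assert pooled.fn == sum(
            t.fn for t in truth.per_attribute().values()
        ) and pooled.fn > 0

    def test_all_none_reported_is_all_tn(self):
        spec = SyntheticSpec(
            n_articles=5, seed=5, rates=_zero_rates(both_none_reported=1)
        )
        manual, automated, truth, result = _assert_recovery(spec)
        pooled = result.pooled()
        assert pooled.tn == 5 * 11
        assert pooled.tp == pooled.fp == pooled.fn == 0


def test_mixed_rate_recovery_at_study_scale():
    """Pipeline confusion counts equal the generator's bookkeeping exactly."""
    _assert_recovery(SyntheticSpec(n_articles=80, seed=12345))


@pytest.mark.parametrize("seed", range(8))
def test_recovery_across_random_specs(seed):
    rng = np.random.default_rng(seed + 1000)
    rates = PerturbationRates(
        near_typo=rng.uniform(0, 0.2),
        synonym_swap=rng.uniform(0, 0.1),
        split_compound=rng.uniform(0, 0.15),
        omission=rng.uniform(0, 0.4),
        spurious_addition=rng.uniform(0, 0.4),
        duplicate_inflation=rng.uniform(0, 0.2),
        both_none_reported=rng.uniform(0, 0.3),
        coordinate_jitter_within=rng.uniform(0, 0.3),
        coordinate_jitter_beyond=rng.uniform(0, 0.2),
        year_drift=rng.uniform(0, 0.3),
    )
    _assert_recovery(SyntheticSpec(n_articles=6, seed=seed, rates=rates))


class TestPerturbTerm:
    def test_synonym_swap_examples(self):
        rng = np.random.default_rng(0)
        assert perturb_term("salt marsh", "synonym_swap", rng) == "saltmarsh"
        assert perturb_term("saltmarsh", "synonym_swap", rng) == "salt marsh"
        with pytest.raises(ChannelNotApplicableError):
            perturb_term("lagoon", "synonym_swap", rng)

    def test_split_compound(self):
        rng = np.random.default_rng(0)
        assert perturb_term("soil sampling", "split_compound", rng) == ["soil", "sampling"]
        with pytest.raises(ChannelNotApplicableError):
            perturb_term("soil", "split_compound", rng)

    def test_near_typo_stays_eligible(self):
        rng = np.random.default_rng(0)
        policy = MatchPolicy()
        norm = NormalizationPolicy()
        for _ in range(20):
            out = perturb_term(
                "spartina", "near_typo", rng, policy, norm, stemmed=False
            )
            assert out != "spartina"
            assert eligible("spartina", out.lower(), policy)

    def test_typo_rejects_too_short_terms(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ChannelNotApplicableError):
            perturb_term("mya", "near_typo", rng)


def test_metric_recovery_converges_to_closed_form():
    """With omission as the only channel, expected recall is 1 - rate and
    precision is 1; the Monte-Carlo estimate converges at corpus scale."""
    from extracteval.metrics import compute_metrics

    rate = 0.3
    spec = SyntheticSpec(
        n_articles=500, seed=77, rates=_zero_rates(omission=rate)
    )
    manual, automated, _ = generate_corpus(spec)
    result = evaluate_datasets(manual, automated)
    m = compute_metrics(result.pooled())
    assert m.precision == 1.0
    assert m.recall == pytest.approx(1.0 - rate, abs=0.02)


def test_rate_validation():
    with pytest.raises(ValueError):
        PerturbationRates(near_typo=0.5, omission=0.6)
    with pytest.raises(ValueError):
        PerturbationRates(near_typo=-0.1)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(n_articles=0)


def test_lexicon_is_clean(norm_policy):
    """Every lexicon term survives normalization (no all-stopword terms)."""
    from extracteval.normalization import normalize_cell

    lexicon = load_lexicon()
    assert sum(len(v) for v in lexicon.values()) >= 200
    for category, terms in lexicon.items():
        for term in terms:
            stemmed = category in ("ecosystem", "action", "method", "response")
            assert normalize_cell([term], norm_policy, stemmed=stemmed).total >= 1


def test_default_entry_rates_are_the_observed_manual_rates():
    rates = default_mean_entries()
    assert rates["response variables"] == 5.3
    assert rates["study site"] == 1.7
    assert set(rates) == set(default_mean_entries())
    assert len(rates) == 11
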