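import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from headache_nlp.corpus_io import write_corpus
from headache_nlp.keyness import build_frequency_table, rank_keywords
from headache_nlp.preprocess import preprocess_corpus, tokenize_corpus
from headache_nlp.synthetic_data import (
    DEFAULT_CLASS_KEYWORDS,
    GeneratorConfig,
    generate_corpus,
    generate_lexicon_fixtures,
    verify_ground_truth,
    zero_signal_config,
)


class TestGeneratorConfig:
    def test_defaults_give_study_shape(self, default_corpus):
        assert default_corpus.label_counts == {
            "migraine": 81,
            "cluster_headache": 40,
        }

    def test_infeasible_rates_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(keyword_rate=0.9, stopword_rate=0.5)
        with pytest.raises(ValueError):
            GeneratorConfig(p_negative_doc=1.7)

    def test_excess_without_attack_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(
                n_per_class={"migraine": 3, "cluster_headache": 3},
                n_without_attack={"migraine": 5, "cluster_headache": 0},
            )


class TestDeterminism:
    def test_same_seed_byte_identical_jsonl(self, tmp_path):
        config = GeneratorConfig(
            n_per_class={"migraine": 8, "cluster_headache": 5}, seed=23
        )
        paths = []
        for name in ("a.jsonl", "b.jsonl"):
            corpus, _, _ = generate_corpus(config)
            p = tmp_path / name
            write_corpus(corpus, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        small = dict(
            n_per_class={"migraine": 4, "cluster_headache": 3},
            n_without_attack={"migraine": 1, "cluster_headache": 0},
        )
        c1, _, _ = generate_corpus(GeneratorConfig(seed=1, **small))
        c2, _, _ = generate_corpus(GeneratorConfig(seed=2, **small))
        assert any(a.text != b.text for a, b in zip(c1, c2))


class TestGroundTruth:
    def test_fresh_generation_audits_clean(self, default_generation):
        corpus, _, truth = default_generation
        assert verify_ground_truth(corpus, truth).ok

    def test_tampered_record_is_flagged(self, default_generation):
        corpus, _, truth = default_generation
        tampered = [dataclasses.replace(r) for r in corpus.records]
        bad = dataclasses.replace(
            tampered[5], text=tampered[5].text + " extrawoord."
        )
        tampered[5] = bad
        from headache_nlp.corpus_io import Corpus

        audit = verify_ground_truth(Corpus(tampered), truth)
        assert not audit.ok
        assert any(bad.record_id in m for m in audit.mismatches)

    def test_random_configs_audit_clean(self):
        rng = np.random.default_rng(99)
        for _ in range(8):
            config = GeneratorConfig(
                n_per_class={"migraine": 4, "cluster_headache": 3},
                n_without_attack={"migraine": 1, "cluster_headache": 0},
                seed=int(rng.integers(0, 2**20)),
                keyword_rate=float(rng.uniform(0, 0.08)),
                sentiment_token_rate=float(rng.uniform(0.02, 0.15)),
                p_negative_doc=float(rng.uniform(0.5, 1.0)),
            )
            corpus, _, truth = generate_corpus(config)
            audit = verify_ground_truth(corpus, truth, config)
            assert audit.ok, audit.mismatches[:3]


@pytest.fixture(scope="module")
def big_generation():
    config = GeneratorConfig(
        n_per_class={"migraine": 300, "cluster_headache": 300},
        n_without_attack={"migraine": 0, "cluster_headache": 0},
        seed=17,
    )
    return config, generate_corpus(config)


class TestDistributionalTargets:
    def test_token_median_within_15pct_of_target(self, big_generation):
        config, (corpus, _, truth) = big_generation
        for label in ("migraine", "cluster_headache"):
            target = config.length_model[label][0]
            counts = [
                t.n_tokens for t in truth.records.values() if t.label == label
            ]
            assert np.median(counts) == pytest.approx(target, rel=0.15)

    def test_female_fraction_within_binomial_interval(self, big_generation):
        config, (corpus, _, _) = big_generation
        for label in ("migraine", "cluster_headache"):
            p = config.metadata_model[label][2]
            recs = [r for r in corpus if r.diagnosis == label]
            n_female = sum(1 for r in recs if r.sex == "female")
            assert binom.ppf(0.005, len(recs), p) <= n_female
            assert n_female <= binom.ppf(0.995, len(recs), p)

    def test_age_means_near_configured(self, big_generation):
        config, (corpus, _, _) = big_generation
        for label in ("migraine", "cluster_headache"):
            mean, sd, _ = config.metadata_model[label]
            ages = [r.age for r in corpus if r.diagnosis == label]
            assert np.mean(ages) == pytest.approx(mean, abs=3 * sd / np.sqrt(len(ages)) + 0.5)


class TestLexiconFixtures:
    def test_sizes_match_config(self, toy_lexicons):
        config = GeneratorConfig()
        # overlap words are added to lexicon 3 on top of its base size
        assert len(toy_lexicons[0]) == config.lexicon_sizes[0]
        assert len(toy_lexicons[1]) == config.lexicon_sizes[1]
        assert len(toy_lexicons[3]) == config.lexicon_sizes[3]

    def test_overlap_words_have_opposite_signs(self, toy_lexicons):
        first, third = toy_lexicons[0], toy_lexicons[2]
        overlaps = set(first.entries) & set(third.entries)
        assert overlaps
        assert any(
            first.entries[w] * third.entries[w] < 0 for w in overlaps
        )

    def test_both_signs_present(self, toy_lexicons):
        for lex in toy_lexicons:
            vals = list(lex.entries.values())
            assert any(v < 0 for v in vals) and any(v > 0 for v in vals)

    def test_standalone_call_matches_generation(self):
        config = GeneratorConfig(seed=31)
        a = generate_lexicon_fixtures(config)
        b = generate_lexicon_fixtures(config)
        assert [l.entries for l in a] == [l.entries for l in b]


class TestSignalDial:
    def _recovery(self, rate, seed=13):
        config = GeneratorConfig(
            n_per_class={"migraine": 20, "cluster_headache": 15},
            n_without_attack={"migraine": 0, "cluster_headache": 0},
            keyword_rate=rate,
            seed=seed,
        )
        corpus, _, _ = generate_corpus(config)
        from headache_nlp.resources import default_blocklist, default_stopwords

        docs = preprocess_corpus(
            corpus, blocklist=default_blocklist(), stopwords=default_stopwords()
        )
        labels = corpus.labels()
        table = build_frequency_table(
            [d for rid, d in docs.items() if labels[rid] == "cluster_headache"],
            [d for rid, d in docs.items() if labels[rid] == "migraine"],
        )
        rows = rank_keywords(table, min_count=2)
        top = {r.word: r.direction for r in rows[:20]}
        hits = sum(
            1
            for w in DEFAULT_CLASS_KEYWORDS["cluster_headache"]
            if top.get(w) == "target"
        ) + sum(
            1
            for w in DEFAULT_CLASS_KEYWORDS["migraine"]
            if top.get(w) == "reference"
        )
        return hits

    def test_keyword_recovery_non_decreasing_in_emission_rate(self):
        recoveries = [self._recovery(rate) for rate in (0.0, 0.02, 0.08)]
        assert recoveries == sorted(recoveries)
        assert recoveries[-1] >= 8  # strong signal recovers nearly all


class TestZeroSignal:
    def test_zero_signal_has_no_keywords_or_label_mentions(self):
        config = zero_signal_config(
            seed=5,
            n_per_class={"migraine": 6, "cluster_headache": 4},
            n_without_attack={"migraine": 0, "cluster_headache": 0},
        )
        corpus, _, truth = generate_corpus(config)
        all_keywords = {
            w for kws in DEFAULT_CLASS_KEYWORDS.values() for w in kws
        }
        for doc in tokenize_corpus(corpus).values():
            assert not set(doc.tokens) & all_keywords
            assert "migraine" not in doc.tokens
            assert "clusterhoofdpijn" not in doc.tokens
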