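"""Synthetic narrative corpora with known ground truth.

The study corpus this package analyses is not publicly deposited, so every
stage is exercised on synthetic corpora whose statistical structure matches
the study conditions: two diagnosis groups (81 migraine / 40 cluster
headache by default, of which 7 / 2 lack an attack-description section),
log-normal text lengths targeting the reported token medians and IQRs,
roughly 20 tokens per sentence, a theme mix dominated by attack
descriptions and treatment, overwhelmingly negative document-level
sentiment (90% by default) and age/sex distributions per group.

Texts are synthetic token streams, not fluent Dutch — every consumer stage
is token-based, so linguistic realism buys nothing.  Tokens mix a shared
background vocabulary of pronounceable CV-syllable words, real Dutch stop
words, class-exclusive keywords (the clinically expected word strings:
*oog, pijn, terug, linker, tanden* for cluster headache; *hoofdpijn,
stress, misselijkheid, geluid, vaak* for migraine, so keyness output is
human-checkable), occasional class-label mentions (to exercise blocklist
filtering) and valence-carrying words drawn from the generated lexicon
fixtures.  Every draw flows from a single seeded generator; the same
config yields byte-identical output.

Ground truth records, per narrative: the label, every injected keyword
occurrence, the intended polarity and the net injected valence — all
recountable from the emitted text, which :func:`verify_ground_truth`
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, NarrativeRecord, SentimentLexiconFile
from .preprocess import tokenize_text
from .sentiment import LexiconCascade
from .thematic import THEMES, ThemeAnnotationSet

#: Class-exclusive keywords, mirroring the clinically expected vocabulary.
DEFAULT_CLASS_KEYWORDS: dict[str, tuple[str, ...]] = {
    "migraine": ("hoofdpijn", "stress", "misselijkheid", "geluid", "vaak"),
    "cluster_headache": ("oog", "pijn", "terug", "linker", "tanden"),
}

#: Label-mention token the generator drops into texts of each class; both
#: appear in the bundled blocklist, so filtering removes them again.
LABEL_MENTIONS = {"migraine": "migraine", "cluster_headache": "clusterhoofdpijn"}

_CONSONANTS = "bdfghjklmnprstvwz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GeneratorConfig:
    """All dials of the corpus generator.

    Defaults encode the study conditions; see the module docstring.  Length
    models are (median token count, log-normal sigma) per class; metadata
    models are (age mean, age SD, probability female) per class.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"migraine": 81, "cluster_headache": 40}
    )
    n_without_attack: Mapping[str, int] = field(
        default_factory=lambda: {"migraine": 7, "cluster_headache": 2}
    )
    seed: int = 17
    shared_vocab_size: int = 400
    class_keywords: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_KEYWORDS)
    )
    keyword_rate: float = 0.04
    label_mention_rate: float = 0.01
    stopword_rate: float = 0.25
    sentiment_token_rate: float = 0.10
    length_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "migraine": (474.0, 0.88),
            "cluster_headache": (508.0, 1.03),
        }
    )
    mean_sentence_len: float = 20.0
    theme_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "attack_description": 0.30,
            "treatment": 0.17,
            "medical_history": 0.12,
            "burden_of_disease": 0.12,
            "triggers": 0.04,
            "comorbidities": 0.0,
            "technical_investigations": 0.0,
        }
    )
    p_negative_doc: float = 0.9
    p_match_polarity: float = 0.8
    metadata_model: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "migraine": (43.1, 12.0, 0.8),
            "cluster_headache": (48.9, 14.2, 0.2),
        }
    )
    lexicon_sizes: tuple[int, int, int, int] = (40, 20, 30, 50)
    n_overlap_words: int = 8
    negative_word_fraction: float = 0.6

    def __post_init__(self) -> None:
        for label, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"n_per_class[{label!r}] must be >= 1")
            if self.n_without_attack.get(label, 0) > n:
                raise ValueError(f"n_without_attack[{label!r}] exceeds class size")
        rates = (
            self.keyword_rate
            + self.label_mention_rate
            + self.stopword_rate
            + self.sentiment_token_rate
        )
        for r in (
            self.keyword_rate,
            self.label_mention_rate,
            self.stopword_rate,
            self.sentiment_token_rate,
            self.p_negative_doc,
            self.p_match_polarity,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and probabilities must lie in [0, 1]")
        if rates > 1.0:
            raise ValueError("token emission rates sum above 1")
        if sum(self.theme_mix.values()) > 1.0 + 1e-9:
            raise ValueError("theme_mix probabilities sum above 1")
        if set(self.theme_mix) - set(THEMES):
            raise ValueError("theme_mix contains unknown themes")


@dataclass(frozen=True)
class RecordTruth:
    """Generator-known facts about one emitted narrative."""

    record_id: str
    label: str
    n_tokens: int
    keyword_counts: Mapping[str, int]
    intended_polarity: str
    net_valence: float
    has_attack_description: bool


@dataclass(frozen=True)
class GroundTruth:
    records: Mapping[str, RecordTruth]


@dataclass(frozen=True)
class AuditReport:
    """Result of recounting ground truth from the emitted corpus."""

    ok: bool
    mismatches: tuple[str, ...]  # messages naming the record and the field


def _syllable_words(rng: np.random.Generator, n: int, n_syllables: int,
                    forbidden: set[str]) -> list[str]:
    """Unique pronounceable CV-syllable words avoiding the forbidden set."""
    words: list[str] = []
    seen = set(forbidden)
    while len(words) < n:
        w = "".join(
            rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
            for _ in range(n_syllables)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate_lexicon_fixtures(
    config: GeneratorConfig,
) -> list[SentimentLexiconFile]:
    """Four toy sentiment lexicons with controlled overlaps.

    Deterministic given ``config.seed`` (an independent sub-stream, so
    :func:`generate_corpus` and a standalone call agree).  Each lexicon uses
    its own native scale; overlap words are present in lexicons 1 and 3
    with opposite-sign valences, exercising first-match-wins semantics.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = config.lexicon_sizes
    names = ("pattern_toy", "inhouse_toy", "duoman_toy", "nrc_toy")
    scales = (1.0, 2.0, 5.0, 1.0)
    n_total = sum(sizes)
    forbidden = set()
    for kws in config.class_keywords.values():
        forbidden.update(kws)
    forbidden.update(LABEL_MENTIONS.values())
    pool = _syllable_words(rng, n_total, 3, forbidden)

    lexicons: list[dict[str, float]] = []
    it = iter(pool)
    for size in sizes:
        entries: dict[str, float] = {}
        for j in range(size):
            word = next(it)
            sign = -1.0 if rng.random() < config.negative_word_fraction else 1.0
            magnitude = 1.0 if j == 0 else float(rng.uniform(0.3, 1.0))
            entries[word] = sign * magnitude
        lexicons.append(entries)

    # overlap words: in lexicon 1 and lexicon 3 with opposite signs
    overlap = rng.choice(list(lexicons[0]), size=min(config.n_overlap_words,
                                                     len(lexicons[0])),
                         replace=False)
    for w in overlap:
        lexicons[2][w] = -lexicons[0][w]

    return [
        SentimentLexiconFile(
            name=names[i],
            entries={w: round(v * scales[i], 6) for w, v in lexicons[i].items()},
        )
        for i in range(4)
    ]


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[Corpus, dict[str, ThemeAnnotationSet], GroundTruth]:
    """Generate a labeled corpus, its theme annotations and ground truth.

    Deterministic given the config (all randomness flows from
    ``config.seed``).  See the module docstring for the emission model.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    lexicons = generate_lexicon_fixtures(config)
    cascade = LexiconCascade.from_lexicons(lexicons)
    resolved = {}
    for lex in cascade.normalized:
        for w in lex:
            resolved.setdefault(w, cascade.lookup(w))
    neg_words = sorted(w for w, v in resolved.items() if v < 0)
    pos_words = sorted(w for w, v in resolved.items() if v > 0)

    from .resources import default_stopwords

    stopword_pool = sorted(default_stopwords().words)[:30]
    forbidden = set(stopword_pool) | set(resolved) | set(LABEL_MENTIONS.values())
    for kws in config.class_keywords.values():
        forbidden.update(kws)
    background = _syllable_words(rng, config.shared_vocab_size, 2, forbidden)
    # Zipf-like weights over background and stop words
    bg_weights = 1.0 / np.arange(1, len(background) + 1)
    bg_weights /= bg_weights.sum()
    sw_weights = 1.0 / np.arange(1, len(stopword_pool) + 1)
    sw_weights /= sw_weights.sum()

    # per-record label sequence, shuffled once
    labels = [
        label for label in sorted(config.n_per_class) for _ in
        range(config.n_per_class[label])
    ]
    rng.shuffle(labels)
    # which records lack the attack-description theme
    lacking: dict[str, set[int]] = {}
    for label in sorted(config.n_per_class):
        idxs = [i for i, lb in enumerate(labels) if lb == label]
        k = config.n_without_attack.get(label, 0)
        chosen = rng.choice(idxs, size=k, replace=False) if k else []
        lacking[label] = set(int(i) for i in chosen)

    theme_names = sorted(config.theme_mix)
    theme_probs = np.array([config.theme_mix[t] for t in theme_names])

    records: list[NarrativeRecord] = []
    annotations: dict[str, ThemeAnnotationSet] = {}
    truths: dict[str, RecordTruth] = {}

    for i, label in enumerate(labels):
        record_id = f"r{i + 1:03d}"
        has_attack = i not in lacking[label]
        probs = theme_probs.copy()
        if not has_attack:
            ai = theme_names.index("attack_description")
            probs[ai] = 0.0
        intended = "negative" if rng.random() < config.p_negative_doc else "positive"

        median, sigma = config.length_model[label]
        target = int(rng.lognormal(mean=math.log(median), sigma=sigma))
        target = min(max(target, 40), 3000)

        sentences: list[list[str]] = []
        sent_themes: list[str | None] = []
        n_tokens = 0
        while n_tokens < target:
            length = max(3, int(rng.poisson(config.mean_sentence_len)))
            u = rng.random()
            cum = 0.0
            theme: str | None = None
            for t, p in zip(theme_names, probs):
                cum += p
                if u < cum:
                    theme = t
                    break
            # batched category draw: keyword | label mention | stop word |
            # sentiment word | background
            r1 = config.keyword_rate
            r2 = r1 + config.label_mention_rate
            r3 = r2 + config.stopword_rate
            r4 = r3 + config.sentiment_token_rate
            cats = np.searchsorted([r1, r2, r3, r4], rng.random(length),
                                   side="right")
            n_kw = int(np.count_nonzero(cats == 0))
            n_sw = int(np.count_nonzero(cats == 2))
            n_se = int(np.count_nonzero(cats == 3))
            n_bg = int(np.count_nonzero(cats == 4))
            kw_pool = config.class_keywords[label]
            kw_q = iter(
                [kw_pool[j] for j in rng.integers(len(kw_pool), size=n_kw)]
            )
            sw_q = iter(
                [stopword_pool[j]
                 for j in rng.choice(len(stopword_pool), size=n_sw, p=sw_weights)]
            )
            se_list: list[str] = []
            if n_se:
                match = rng.random(n_se) < config.p_match_polarity
                for m in match:
                    want_neg = (intended == "negative") == bool(m)
                    pool = neg_words if want_neg else pos_words
                    se_list.append(pool[int(rng.integers(len(pool)))])
            se_q = iter(se_list)
            bg_q = iter(
                [background[j]
                 for j in rng.choice(len(background), size=n_bg, p=bg_weights)]
            )
            tokens: list[str] = []
            for c in cats:
                if c == 0:
                    tokens.append(next(kw_q))
                elif c == 1:
                    tokens.append(LABEL_MENTIONS[label])
                elif c == 2:
                    tokens.append(next(sw_q))
                elif c == 3:
                    tokens.append(next(se_q))
                else:
                    tokens.append(next(bg_q))
            sentences.append(tokens)
            sent_themes.append(theme)
            n_tokens += length

        if has_attack and "attack_description" not in sent_themes:
            sent_themes[0] = "attack_description"

        # force the net valence sign to the intended polarity
        def net() -> float:
            return sum(
                resolved.get(tok, 0.0)
                for sent in sentences
                for tok in sent
                if tok in resolved
            )

        want_pool = neg_words if intended == "negative" else pos_words
        guard = 0
        while (net() < 0) != (intended == "negative") or net() == 0.0:
            # replace one opposite-sign or background token with a matching one
            replaced = False
            for sent in sentences:
                for k, tok in enumerate(sent):
                    val = resolved.get(tok)
                    wrong_sign = val is not None and (
                        (val > 0) == (intended == "negative")
                    )
                    if wrong_sign or (val is None and guard > 50):
                        sent[k] = str(rng.choice(want_pool))
                        replaced = True
                        break
                if replaced:
                    break
            if not replaced:
                sentences[0][0] = str(rng.choice(want_pool))
            guard += 1
            if guard > 10000:  # infeasible only for pathological configs
                raise RuntimeError("could not reach the intended polarity")

        keyword_counts = {
            kw: sum(sent.count(kw) for sent in sentences)
            for kw in config.class_keywords[label]
        }
        text = " ".join(" ".join(sent) + "." for sent in sentences)

        age_mean, age_sd, p_female = config.metadata_model[label]
        age = max(18, int(round(rng.normal(age_mean, age_sd))))
        sex = "female" if rng.random() < p_female else "male"

        records.append(
            NarrativeRecord(
                record_id=record_id, text=text, diagnosis=label, age=age, sex=sex
            )
        )
        annotations[record_id] = ThemeAnnotationSet(
            record_id=record_id,
            assignments={
                idx: frozenset({t}) for idx, t in enumerate(sent_themes)
                if t is not None
            },
        )
        truths[record_id] = RecordTruth(
            record_id=record_id,
            label=label,
            n_tokens=sum(len(s) for s in sentences),
            keyword_counts=keyword_counts,
            intended_polarity=intended,
            net_valence=net(),
            has_attack_description=has_attack,
        )

    return Corpus(records), annotations, GroundTruth(records=truths)


def zero_signal_config(seed: int = 17, **overrides) -> GeneratorConfig:
    """A config whose labels are independent of the text.

    Keyword and label-mention injection are off and the two classes share
    one length model, so no textual feature carries the diagnosis.
    """
    base = GeneratorConfig()
    shared_length = {label: base.length_model["migraine"]
                     for label in base.n_per_class}
    kwargs = dict(
        seed=seed,
        keyword_rate=0.0,
        label_mention_rate=0.0,
        length_model=shared_length,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def verify_ground_truth(
    corpus: Corpus,
    truth: GroundTruth,
    config: GeneratorConfig | None = None,
) -> AuditReport:
    """Recount keywords and valence sums from the emitted text.

    Re-tokenizes every narrative with the package tokenizer and checks the
    token count, per-keyword counts and cascade net valence against the
    GroundTruth; any mismatch means a generator bug (or a tampered corpus).
    """
    config = config or GeneratorConfig()
    cascade = LexiconCascade.from_lexicons(generate_lexicon_fixtures(config))
    mismatches: list[str] = []
    for rec in corpus:
        t = truth.records.get(rec.record_id)
        if t is None:
            mismatches.append(f"{rec.record_id}: missing from ground truth")
            continue
        doc = tokenize_text(rec.record_id, rec.text)
        tokens = doc.tokens
        if len(tokens) != t.n_tokens:
            mismatches.append(
                f"{rec.record_id}: token count {len(tokens)} != {t.n_tokens}"
            )
        for kw, expected in t.keyword_counts.items():
            observed = tokens.count(kw)
            if observed != expected:
                mismatches.append(
                    f"{rec.record_id}: keyword {kw!r} count "
                    f"{observed} != {expected}"
                )
        net = sum(
            v for tok in tokens if (v := cascade.lookup(tok)) is not None
        )
        if abs(net - t.net_valence) > 1e-9:
            mismatches.append(
                f"{rec.record_id}: net valence {net:.6f} != {t.net_valence:.6f}"
            )
    return AuditReport(ok=not mismatches, mismatches=tuple(mismatches))
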