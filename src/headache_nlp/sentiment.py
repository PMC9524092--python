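"""Lexicon-cascade sentiment scoring.

Several sentiment lexicons are consulted in a fixed order with first-match-
wins semantics: a token's valence comes from the first lexicon that lists
it.  Each lexicon's native scale is harmonised at load by dividing by the
lexicon's maximum absolute valence, mapping scores into [-1, +1] while
preserving sign.  A document's score is the plain sum of the valences of
all matched tokens (each occurrence counted); no negation or intensifier
arithmetic is applied.  Stop words should be retained in the input — they
carry the negators and intensifiers source lexicons may list.

Polarity is a strict two-way split: positive iff score > 0, otherwise
negative (a zero score, including the no-match case, maps to the majority
clinical polarity; configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import SentimentLexiconFile
from .preprocess import TokenizedDocument

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LexiconCascade:
    """Ordered lexicons with per-lexicon valences normalised into [-1, +1]."""

    names: tuple[str, ...]
    normalized: tuple[Mapping[str, float], ...]

    @classmethod
    def from_lexicons(cls, lexicons: Sequence[SentimentLexiconFile]) -> "LexiconCascade":
        if not lexicons:
            raise ValueError("cascade needs at least one lexicon")
        norm = []
        for lex in lexicons:
            scale = max(abs(v) for v in lex.entries.values())
            if scale == 0:
                scale = 1.0
            norm.append({w: v / scale for w, v in lex.entries.items()})
        return cls(names=tuple(l.name for l in lexicons), normalized=tuple(norm))

    def lookup(self, token: str) -> float | None:
        """Normalised valence from the first lexicon containing the token."""
        for lex in self.normalized:
            if token in lex:
                return lex[token]
        return None

    def __len__(self) -> int:
        return len(self.normalized)


def cascade_lookup(token: str, cascade: LexiconCascade) -> float | None:
    """First-match-wins valence lookup; None when no lexicon lists the token."""
    return cascade.lookup(token)


@dataclass(frozen=True)
class SentimentResult:
    """Summed valence and the derived polarity for one document."""

    record_id: str
    score: float
    n_matched: int
    polarity: str  # "negative" | "positive"


def score_document(
    doc: TokenizedDocument,
    cascade: LexiconCascade,
    zero_polarity: str = "negative",
) -> SentimentResult:
    """Sum the cascade valences of every matched token occurrence.

    The input document should keep its stop words; blocklist filtering (class
    label mentions) is expected to have been applied upstream.  Zero matched
    tokens gives score 0 with a logged warning.
    """
    score = 0.0
    n_matched = 0
    for token in doc.tokens:
        valence = cascade.lookup(token)
        if valence is not None:
            score += valence
            n_matched += 1
    if n_matched == 0:
        logger.warning("record %s: no token matched any lexicon", doc.record_id)
    polarity = "positive" if score > 0 else "negative" if score < 0 else zero_polarity
    return SentimentResult(
        record_id=doc.record_id, score=score, n_matched=n_matched, polarity=polarity
    )


def score_corpus(
    docs: Mapping[str, TokenizedDocument],
    cascade: LexiconCascade,
    zero_polarity: str = "negative",
) -> list[SentimentResult]:
    return [score_document(d, cascade, zero_polarity) for d in docs.values()]


def polarity_distribution(
    results: Iterable[SentimentResult], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Counts and percentages of negative/positive documents per group.

    Groups are each diagnosis label plus pooled "all"; percentages sum to
    100 within a group (the split is strictly two-way).
    """
    results = list(results)
    for r in results:
        if r.record_id not in labels:
            raise ValueError(f"record {r.record_id!r} has no label")
    groups: dict[str, list[SentimentResult]] = {"all": results}
    for r in results:
        groups.setdefault(labels[r.record_id], []).append(r)
    rows = {}
    for gname in ["all"] + sorted(g for g in groups if g != "all"):
        rs = groups[gname]
        n_neg = sum(1 for r in rs if r.polarity == "negative")
        n_pos = len(rs) - n_neg
        rows[gname] = {
            "n": len(rs),
            "n_negative": n_neg,
            "n_positive": n_pos,
            "pct_negative": 100.0 * n_neg / len(rs),
            "pct_positive": 100.0 * n_pos / len(rs),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
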