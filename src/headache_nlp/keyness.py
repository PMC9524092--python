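"""Chi-square keyness: which word types distinguish a target subcorpus.

For every word type the 2x2 table

    ================  =======  =========
                      target   reference
    ----------------  -------  ---------
    word              a        b
    all other tokens  c        d
    ================  =======  =========

is scored with the 2x2 chi-square statistic (Yates continuity correction by
default, the conservative choice for sparse word counts).  The statistic is
unsigned; the direction (which subcorpus over-uses the word) is carried
separately, so the "absolute chi-square" reported in keyword plots is the
statistic itself.  Significance tiers: ``*`` p < 1e-2, ``**`` p < 1e-5,
``***`` p < 1e-8, else ``ns``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import chi2 as _chi2_dist

from .preprocess import TokenizedDocument

logger = logging.getLogger(__name__)

#: p-value breakpoints of the significance tiers, most stringent first.
TIER_THRESHOLDS = ((1e-8, "***"), (1e-5, "**"), (1e-2, "*"))


def significance_tier(p_value: float) -> str:
    """Map a p-value onto the tier labels (strict inequalities)."""
    for threshold, label in TIER_THRESHOLDS:
        if p_value < threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class KeynessRow:
    """One word type's 2x2 counts and keyness verdict."""

    word: str
    a: int  # occurrences in target
    b: int  # occurrences in reference
    c: int  # other tokens in target
    d: int  # other tokens in reference
    chi2: float
    direction: str  # "target" | "reference"
    p_value: float
    tier: str


@dataclass(frozen=True)
class FrequencyTable:
    """Aggregated token counts per word type for a target/reference pair."""

    target_total: int
    reference_total: int
    type_counts: Mapping[str, tuple[int, int]]  # word -> (n_target, n_reference)


def build_frequency_table(
    docs_target: Iterable[TokenizedDocument],
    docs_reference: Iterable[TokenizedDocument],
) -> FrequencyTable:
    """Aggregate token counts of both groups into one frequency table."""
    from collections import Counter

    tgt: Counter[str] = Counter()
    ref: Counter[str] = Counter()
    n_t = n_r = 0
    for doc in docs_target:
        tgt.update(doc.tokens)
        n_t += 1
    for doc in docs_reference:
        ref.update(doc.tokens)
        n_r += 1
    if n_t == 0 or n_r == 0:
        raise ValueError("both target and reference groups must be non-empty")
    counts = {
        w: (tgt.get(w, 0), ref.get(w, 0)) for w in set(tgt) | set(ref)
    }
    return FrequencyTable(
        target_total=sum(tgt.values()),
        reference_total=sum(ref.values()),
        type_counts=counts,
    )


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = True) -> float:
    """Closed-form 2x2 chi-square statistic.

    With Yates correction: N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)),
    where the correction term is clipped so over-correction of near-null
    tables cannot produce a spurious positive statistic.  Without
    correction the N/2 term is dropped.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def keyness_chi2(
    a: int, b: int, c: int, d: int, correction: bool = True
) -> tuple[float, str, float, str]:
    """Score one word's 2x2 table: (chi2, direction, p_value, tier).

    ``direction`` is "target" iff the word's relative frequency is higher in
    the target subcorpus.  The p-value comes from the chi-square distribution
    with one degree of freedom.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + c == 0 or b + d == 0:
        raise ValueError("both group totals must be positive")
    stat = chi2_2x2(a, b, c, d, correction=correction)
    p_value = float(_chi2_dist.sf(stat, df=1))
    direction = "target" if a * (b + d) > b * (a + c) else "reference"
    return stat, direction, p_value, significance_tier(p_value)


def rank_keywords(
    table: FrequencyTable, min_count: int = 5, correction: bool = True
) -> list[KeynessRow]:
    """Rank word types by keyness.

    Words with combined count below ``min_count`` are dropped (single
    occurrences give unstable chi-square values); rows sort by chi2
    descending with alphabetical tie-break.  Words absent from both groups
    are excluded with a logged note.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rows: list[KeynessRow] = []
    for word, (a, b) in table.type_counts.items():
        if a == 0 and b == 0:
            logger.info("excluding %r: zero count in both groups", word)
            continue
        if a + b < min_count:
            continue
        c = table.target_total - a
        d = table.reference_total - b
        stat, direction, p, tier = keyness_chi2(a, b, c, d, correction=correction)
        rows.append(KeynessRow(word, a, b, c, d, stat, direction, p, tier))
    rows.sort(key=lambda r: (-r.chi2, r.word))
    return rows


def keyness_to_dataframe(rows: list[KeynessRow]):
    """Keyness rows as a pandas DataFrame (columns of the CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "word": r.word,
                "a": r.a,
                "b": r.b,
                "chi2": r.chi2,
                "direction": r.direction,
                "p_value": r.p_value,
                "tier": r.tier,
            }
            for r in rows
        ]
    )
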