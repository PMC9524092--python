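"""Per-group demographic and textual summaries of a corpus.

Age and sex are summarised as mean (SD) and count (percent female); token,
type and sentence counts per text as median (Q1-Q3), the right summary for
their skewed distributions.  Quartiles use linear interpolation between
order statistics (the "type 7" rule), fixed so results are deterministic
and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import Corpus
from .preprocess import TokenizedDocument, count_tokens_types


@dataclass(frozen=True)
class GroupSummary:
    """Table-1-shaped summary row for one diagnosis group (or "all")."""

    group: str
    n: int
    age_mean: float
    age_sd: float
    n_female: int
    pct_female: float
    tokens_median: float
    tokens_q1: float
    tokens_q3: float
    types_median: float
    types_q1: float
    types_q3: float
    sentences_median: float
    sentences_q1: float
    sentences_q3: float


def _quartiles(values: list[int]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize(
    corpus: Corpus, docs: Mapping[str, TokenizedDocument]
) -> list[GroupSummary]:
    """One GroupSummary per diagnosis label plus one pooled "all" row.

    Every record must be labeled, carry age/sex, and have a tokenized
    document; a missing document is an error naming the record.
    """
    for rec in corpus:
        if rec.record_id not in docs:
            raise ValueError(f"no tokenized document for record {rec.record_id!r}")
        if rec.diagnosis is None or rec.age is None or rec.sex is None:
            raise ValueError(
                f"record {rec.record_id!r} lacks diagnosis/age/sex metadata"
            )

    groups: dict[str, list] = {}
    for rec in corpus:
        groups.setdefault(rec.diagnosis, []).append(rec)
    ordered = ["all"] + sorted(groups)
    groups["all"] = list(corpus.records)

    out = []
    for name in ordered:
        recs = groups[name]
        counts = [count_tokens_types(docs[r.record_id]) for r in recs]
        tokens, types, sents = zip(*counts)
        ages = np.array([r.age for r in recs], dtype=float)
        n_female = sum(1 for r in recs if r.sex == "female")
        tok = _quartiles(list(tokens))
        typ = _quartiles(list(types))
        sen = _quartiles(list(sents))
        out.append(
            GroupSummary(
                group=name,
                n=len(recs),
                age_mean=float(ages.mean()),
                age_sd=float(ages.std(ddof=1)) if len(recs) > 1 else 0.0,
                n_female=n_female,
                pct_female=100.0 * n_female / len(recs),
                tokens_median=tok[0], tokens_q1=tok[1], tokens_q3=tok[2],
                types_median=typ[0], types_q1=typ[1], types_q3=typ[2],
                sentences_median=sen[0], sentences_q1=sen[1], sentences_q3=sen[2],
            )
        )
    return out


def summaries_to_dataframe(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame whose columns mirror the demographics table."""
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("group")
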