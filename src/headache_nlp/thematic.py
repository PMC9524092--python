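"""Theme proportions from sentence-level stand-off annotations.

Narratives are annotated at the sentence level with up to seven themes
(attack description, burden of disease, comorbidities, technical
investigations, triggers, treatment, medical history).  The weight of a
theme in a text is the fraction of the text's word tokens that fall in
sentences carrying that theme; unannotated sentences count only in the
denominator.  Sentences may carry several themes — each theme's proportion
is computed independently, so with overlap the proportions can sum above 1.

Annotations are stand-off JSON referencing sentence indices:
``{"record_id": ..., "assignments": {"0": ["attack_description"], ...}}``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus_io import Corpus, NarrativeRecord
from .preprocess import TokenizedDocument

logger = logging.getLogger(__name__)

THEMES = (
    "attack_description",
    "burden_of_disease",
    "comorbidities",
    "technical_investigations",
    "triggers",
    "treatment",
    "medical_history",
)


@dataclass(frozen=True)
class ThemeAnnotationSet:
    """Sentence-index -> set-of-themes assignments for one record."""

    record_id: str
    assignments: Mapping[int, frozenset[str]]

    def __post_init__(self) -> None:
        for idx, themes in self.assignments.items():
            if idx < 0:
                raise ValueError(f"{self.record_id}: negative sentence index {idx}")
            unknown = set(themes) - set(THEMES)
            if unknown:
                raise ValueError(
                    f"{self.record_id}: unknown theme(s) {sorted(unknown)}; "
                    f"allowed: {', '.join(THEMES)}"
                )

    def themes_of(self, sentence_index: int) -> frozenset[str]:
        return self.assignments.get(sentence_index, frozenset())

    def has_theme(self, theme: str) -> bool:
        return any(theme in ts for ts in self.assignments.values())


@dataclass(frozen=True)
class ThemeProportions:
    """Per-theme token-weight proportions (each in [0, 1]) for one record."""

    record_id: str
    proportions: Mapping[str, float]


def read_annotations(path: str | Path) -> ThemeAnnotationSet:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    return ThemeAnnotationSet(
        record_id=obj["record_id"],
        assignments={
            int(k): frozenset(v) for k, v in obj.get("assignments", {}).items()
        },
    )


def write_annotations(ann: ThemeAnnotationSet, path: str | Path) -> None:
    obj = {
        "record_id": ann.record_id,
        "assignments": {
            str(k): sorted(v) for k, v in sorted(ann.assignments.items())
        },
    }
    Path(path).write_text(
        json.dumps(obj, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )


def theme_proportions(
    doc: TokenizedDocument, ann: ThemeAnnotationSet
) -> ThemeProportions:
    """Token-weighted proportion of each theme in one document.

    proportion(theme) = tokens in sentences carrying the theme / total tokens.
    Raises on a zero-token document or an out-of-range sentence index.
    """
    total = len(doc)
    if total == 0:
        raise ValueError(f"{doc.record_id}: document has no tokens")
    n_sent = len(doc.sentences)
    for idx in ann.assignments:
        if idx >= n_sent:
            raise ValueError(
                f"{doc.record_id}: sentence index {idx} out of range "
                f"(document has {n_sent} sentences)"
            )
    sums = dict.fromkeys(THEMES, 0)
    for idx, sent in enumerate(doc.sentences):
        for theme in ann.themes_of(idx):
            sums[theme] += len(sent)
    return ThemeProportions(
        record_id=doc.record_id,
        proportions={t: sums[t] / total for t in THEMES},
    )


def summarize_themes(
    all_props: Iterable[ThemeProportions], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Median (Q1-Q3) of each theme's proportion per diagnosis group.

    Returns a DataFrame indexed by theme with per-group ``<group>_median``,
    ``<group>_q1``, ``<group>_q3`` columns; groups are each label plus the
    pooled "full_cohort".  Quartiles use linear interpolation, matching the
    corpus-level summaries.
    """
    props = list(all_props)
    for p in props:
        if p.record_id not in labels:
            raise ValueError(f"record {p.record_id!r} has no label")
    groups: dict[str, list[ThemeProportions]] = {"full_cohort": props}
    for p in props:
        groups.setdefault(labels[p.record_id], []).append(p)

    rows = {}
    for theme in THEMES:
        row = {}
        for gname in ["full_cohort"] + sorted(g for g in groups if g != "full_cohort"):
            vals = np.array([p.proportions[theme] for p in groups[gname]])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row[f"{gname}_median"] = med
            row[f"{gname}_q1"] = q1
            row[f"{gname}_q3"] = q3
        rows[theme] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def extract_theme_subcorpus(
    corpus: Corpus,
    annotations: Mapping[str, ThemeAnnotationSet],
    docs: Mapping[str, TokenizedDocument],
    theme: str,
) -> Corpus:
    """Corpus of the sentences carrying one theme, per record.

    Each output record's text is the concatenation (in order) of the
    record's theme-carrying sentences, rebuilt from the tokenized sentences;
    records with no such sentence are dropped.  Used to carve the
    attack-description subcorpus the classifier runs on.
    """
    if theme not in THEMES:
        raise ValueError(f"unknown theme {theme!r}; allowed: {', '.join(THEMES)}")
    out: list[NarrativeRecord] = []
    for rec in corpus:
        ann = annotations.get(rec.record_id)
        doc = docs.get(rec.record_id)
        if ann is None or doc is None:
            continue
        kept = [
            " ".join(sent)
            for idx, sent in enumerate(doc.sentences)
            if theme in ann.themes_of(idx)
        ]
        if not kept:
            continue
        out.append(
            NarrativeRecord(
                record_id=rec.record_id,
                text=". ".join(kept) + ".",
                diagnosis=rec.diagnosis,
                age=rec.age,
                sex=rec.sex,
            )
        )
    if not out:
        warnings.warn(f"no record carries theme {theme!r}; subcorpus is empty")
        return Corpus([])
    return Corpus(out)
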