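"""Readers and writers for narrative corpora, sentiment lexicons and word lists.

The canonical corpus format is JSONL (one record per line, UTF-8): objects
with keys ``record_id``, ``text`` and optionally ``diagnosis``, ``age``,
``sex`` and ``themes_path``.  CSV is supported for interchange with the text
column quoted.  Sentiment lexicons are two-column TSV (``word<TAB>valence``,
no header); word lists are plain text, one entry per line, ``#`` comments
allowed.

All readers validate and reject malformed input rather than silently
repairing it; unicode is normalised to composed form (NFC) on the way in.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

DIAGNOSES = ("migraine", "cluster_headache")
SEXES = ("female", "male")
WORDLIST_PURPOSES = ("stopwords", "label_blocklist")


class CorpusFormatError(ValueError):
    """Raised when an input file violates the corpus/lexicon/word-list format."""


@dataclass(frozen=True)
class NarrativeRecord:
    """One patient narrative with its diagnosis label and metadata.

    ``diagnosis``, ``age`` and ``sex`` may be absent (unlabeled inference,
    stages that do not need metadata); stages that require them reject
    records at their own boundary.
    """

    record_id: str
    text: str
    diagnosis: str | None = None
    age: int | None = None
    sex: str | None = None
    themes_path: str | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise CorpusFormatError("record_id must be a non-empty string")
        if not self.text or not self.text.strip():
            raise CorpusFormatError(
                f"record {self.record_id!r}: text is empty after whitespace stripping"
            )
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise CorpusFormatError(
                f"record {self.record_id!r}: unknown diagnosis "
                f"{self.diagnosis!r}; allowed labels: {', '.join(DIAGNOSES)}"
            )
        if self.age is not None and (not isinstance(self.age, int) or self.age <= 0):
            raise CorpusFormatError(
                f"record {self.record_id!r}: age must be a positive integer"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise CorpusFormatError(
                f"record {self.record_id!r}: sex must be one of {', '.join(SEXES)}"
            )


@dataclass
class Corpus:
    """Ordered collection of narrative records with per-label counts."""

    records: list[NarrativeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise CorpusFormatError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    @property
    def label_counts(self) -> dict[str, int]:
        return dict(Counter(r.diagnosis for r in self.records if r.diagnosis))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NarrativeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> NarrativeRecord:
        return self.records[i]

    def get(self, record_id: str) -> NarrativeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def labels(self) -> dict[str, str]:
        """record_id -> diagnosis for all labeled records."""
        return {r.record_id: r.diagnosis for r in self.records if r.diagnosis}


@dataclass(frozen=True)
class SentimentLexiconFile:
    """A named word -> raw valence mapping on the lexicon's native scale."""

    name: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise CorpusFormatError(f"lexicon {self.name!r} has no entries")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WordList:
    """A set of lowercased words used as stop words or a label blocklist."""

    purpose: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if self.purpose not in WORDLIST_PURPOSES:
            raise CorpusFormatError(
                f"word list purpose must be one of {WORDLIST_PURPOSES}"
            )
        if not self.words:
            raise CorpusFormatError("word list is empty after filtering")
        for w in self.words:
            if not w or any(ch.isspace() for ch in w):
                raise CorpusFormatError(f"word list entry {w!r} contains whitespace")

    def __contains__(self, word: str) -> bool:
        return word in self.words


def _norm(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def _record_from_mapping(obj: Mapping, where: str) -> NarrativeRecord:
    if "record_id" not in obj or "text" not in obj:
        raise CorpusFormatError(f"{where}: missing required key record_id/text")
    age = obj.get("age")
    if age not in (None, ""):
        try:
            age = int(age)
        except (TypeError, ValueError):
            raise CorpusFormatError(f"{where}: age {age!r} is not an integer") from None
    else:
        age = None
    try:
        return NarrativeRecord(
            record_id=_norm(str(obj["record_id"])),
            text=_norm(str(obj["text"])),
            diagnosis=_norm(obj["diagnosis"]) if obj.get("diagnosis") else None,
            age=age,
            sex=_norm(obj["sex"]) if obj.get("sex") else None,
            themes_path=obj.get("themes_path") or None,
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"{where}: {exc}") from None


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL (canonical) or CSV.

    The format is inferred from the file suffix when not given.  Raises
    :class:`CorpusFormatError` naming the offending line on malformed rows,
    duplicate record ids or unknown diagnosis labels.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    try:
        raw = path.read_text(encoding="utf-8", errors="strict")
    except UnicodeDecodeError as exc:
        raise CorpusFormatError(f"{path}: not valid UTF-8 ({exc})") from None

    records: list[NarrativeRecord] = []
    if format == "jsonl":
        for lineno, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: invalid JSON ({exc.msg})"
                ) from None
            if not isinstance(obj, dict):
                raise CorpusFormatError(f"{path}:{lineno}: expected a JSON object")
            records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    else:
        import io

        # stream parse: quoted text fields may span multiple lines
        reader = csv.DictReader(io.StringIO(raw))
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise CorpusFormatError(f"{path}: CSV header must include record_id")
        for row in reader:
            records.append(
                _record_from_mapping(row, f"{path}:{reader.line_num}")
            )
    if not records:
        raise CorpusFormatError(f"{path}: no records")
    return Corpus(records)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL (canonical) or CSV, preserving record order."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    fields = ["record_id", "text", "diagnosis", "age", "sex", "themes_path"]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                obj = {k: getattr(rec, k) for k in fields}
                obj = {k: v for k, v in obj.items() if v is not None}
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for rec in corpus:
                writer.writerow({k: getattr(rec, k) or "" for k in fields})
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def read_lexicon(path: str | Path, name: str | None = None) -> SentimentLexiconFile:
    """Read a two-column TSV sentiment lexicon (word<TAB>valence, no header).

    Words are lowercased and NFC-normalised; a word occurring twice is an
    error — conflict resolution belongs to the cascade, not the file.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected two tab-separated columns"
            )
        word = _norm(parts[0].strip().lower())
        try:
            valence = float(parts[1])
        except ValueError:
            raise CorpusFormatError(
                f"{path}:{lineno}: non-numeric valence {parts[1]!r}"
            ) from None
        if word in entries:
            raise CorpusFormatError(f"{path}:{lineno}: duplicate word {word!r}")
        entries[word] = valence
    return SentimentLexiconFile(name=name or path.stem, entries=entries)


def write_lexicon(lexicon: SentimentLexiconFile, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word, valence in lexicon.entries.items():
            fh.write(f"{word}\t{valence:g}\n")


def read_wordlist(path: str | Path, purpose: str) -> WordList:
    """Read a plain-text word list (one entry per line, ``#`` comments)."""
    path = Path(path)
    words: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            words.add(_norm(entry.lower()))
    if not words:
        raise CorpusFormatError(f"{path}: word list empty after filtering")
    return WordList(purpose=purpose, words=frozenset(words))


def write_wordlist(words: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for w in sorted(set(words)):
            fh.write(w + "\n")


def relabel(corpus: Corpus, labels: Mapping[str, str]) -> Corpus:
    """Return a copy of the corpus with diagnoses replaced from a mapping."""
    return Corpus(
        [replace(rec, diagnosis=labels.get(rec.record_id, rec.diagnosis))
         for rec in corpus]
    )
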