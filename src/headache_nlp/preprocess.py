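"""Text pre-processing: cleaning, sentence splitting, tokenization, filtering.

The chain mirrors a standard clinical-NLP pipeline: clean the raw narrative,
split it into sentences, tokenize each sentence into lowercased word tokens,
remove class-label mentions (so the classifier cannot read the diagnosis off
the page) and optionally remove stop words.  The tokenizer is rule-based and
pluggable: unicode word characters plus internal hyphens/apostrophes form a
token; punctuation is discarded from the word-token stream.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from .corpus_io import Corpus, WordList

#: Abbreviations (without trailing period) whose period never ends a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"dr", "dhr", "mevr", "mr", "prof", "o.a", "bijv", "evt", "ca", "nr", "e.g", "i.e"}
)

_TOKEN_RE = re.compile(r"\w+(?:['’-]\w+)*", re.UNICODE)
# C0/C1 controls except tab, newline, carriage return (those are whitespace)
_CONTROL_RE = re.compile(r"[\x00-\x08\x0b\x0c\x0e-\x1f\x7f-\x9f]")


@dataclass(frozen=True)
class TokenizedDocument:
    """Ordered sentences of lowercased word tokens for one record.

    ``provenance_flags`` records which pipeline steps produced this document
    (subset of {"cleaned", "blocklist_filtered", "stopwords_removed"}).
    Invariants: no empty sentence, no empty token; flattening the sentences
    yields the token stream in original order.
    """

    record_id: str
    sentences: tuple[tuple[str, ...], ...]
    provenance_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for sent in self.sentences:
            if not sent:
                raise ValueError(f"{self.record_id}: empty sentence")
            if any(not tok for tok in sent):
                raise ValueError(f"{self.record_id}: empty token")

    @property
    def tokens(self) -> list[str]:
        """The flattened token stream, in original order."""
        return [tok for sent in self.sentences for tok in sent]

    def __len__(self) -> int:
        return sum(len(s) for s in self.sentences)


def clean_text(text: str) -> str:
    """Normalise a raw narrative: NFC composition, strip control characters,
    collapse whitespace runs.

    A whitespace run containing a line break collapses to a single newline
    (narratives often use bare line breaks as sentence boundaries, and the
    sentence splitter honours them); any other run collapses to one space.
    Idempotent.
    """
    text = unicodedata.normalize("NFC", text)
    text = _CONTROL_RE.sub("", text)

    def _collapse(m: re.Match) -> str:
        return "\n" if "\n" in m.group(0) else " "

    return re.sub(r"\s+", _collapse, text).strip()


def split_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[str]:
    """Split cleaned text into sentences.

    ``.``, ``!`` and ``?`` end a sentence, except a period inside a decimal
    number (``8.5``) or following a known abbreviation; a bare newline also
    ends a sentence.  Text without terminators is one sentence.
    """
    sentences: list[str] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        boundary = False
        if ch == "\n":
            boundary = True
        elif ch in "!?":
            boundary = True
        elif ch == ".":
            prev_digit = i > 0 and text[i - 1].isdigit()
            next_digit = i + 1 < n and text[i + 1].isdigit()
            if prev_digit and next_digit:
                boundary = False  # decimal number
            else:
                # word immediately before the period
                m = re.search(r"[\w.]+$", text[start:i])
                word = m.group(0).lower().rstrip(".") if m else ""
                boundary = word not in abbreviations
        if boundary:
            # absorb any run of terminators ("?!", "...")
            j = i + 1
            while j < n and text[j] in ".!?":
                j += 1
            chunk = text[start:j].strip()
            if chunk:
                sentences.append(chunk)
            start = j
            i = j
        else:
            i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence: str) -> list[str]:
    """Tokenize one sentence into lowercased word tokens.

    Runs of unicode word characters, with internal hyphens and apostrophes
    kept inside the token, form tokens; all other characters are separators
    and punctuation is dropped from the word-token stream.
    """
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(sentence)]


def tokenize_text(
    record_id: str,
    text: str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> TokenizedDocument:
    """clean -> split -> tokenize for one narrative.

    Sentences that contain no word token (pure punctuation) are dropped.
    """
    cleaned = clean_text(text)
    sents = [
        tuple(toks)
        for s in split_sentences(cleaned, abbreviations)
        if (toks := tokenize(s))
    ]
    return TokenizedDocument(
        record_id=record_id,
        sentences=tuple(sents),
        provenance_flags=frozenset({"cleaned"}),
    )


def tokenize_corpus(corpus: Corpus) -> dict[str, TokenizedDocument]:
    """Tokenize every record; returns record_id -> TokenizedDocument."""
    return {rec.record_id: tokenize_text(rec.record_id, rec.text) for rec in corpus}


def count_tokens_types(doc: TokenizedDocument) -> tuple[int, int, int]:
    """(token_count, type_count, sentence_count) of a tokenized document.

    A type is the equivalence class of tokens with the same character
    sequence, so the type count is the document's vocabulary size.
    """
    tokens = doc.tokens
    return len(tokens), len(set(tokens)), len(doc.sentences)


def _filter(doc: TokenizedDocument, words: frozenset[str], flag: str) -> TokenizedDocument:
    sentences = tuple(
        filtered
        for sent in doc.sentences
        if (filtered := tuple(t for t in sent if t not in words))
    )
    return replace(
        doc, sentences=sentences, provenance_flags=doc.provenance_flags | {flag}
    )


def filter_blocklist(doc: TokenizedDocument, blocklist: WordList) -> TokenizedDocument:
    """Remove class-label mentions and other label-revealing words.

    Sentences left empty are dropped; surviving tokens keep their order.
    """
    if blocklist.purpose != "label_blocklist":
        raise ValueError("expected a word list with purpose 'label_blocklist'")
    return _filter(doc, blocklist.words, "blocklist_filtered")


def filter_stopwords(doc: TokenizedDocument, stopwords: WordList) -> TokenizedDocument:
    """Remove stop words (function words carrying little content)."""
    if stopwords.purpose != "stopwords":
        raise ValueError("expected a word list with purpose 'stopwords'")
    return _filter(doc, stopwords.words, "stopwords_removed")


def preprocess_corpus(
    corpus: Corpus,
    blocklist: WordList | None = None,
    stopwords: WordList | None = None,
) -> dict[str, TokenizedDocument]:
    """Full chain: clean -> split -> tokenize -> blocklist -> stop words.

    Passing ``stopwords=None`` reproduces the sentiment-stage variant where
    stop words are retained (they carry the negators and intensifiers a
    lexicon may score).  Records whose document ends up with zero tokens are
    kept (downstream stages decide whether that is an error).
    """
    docs = tokenize_corpus(corpus)
    if blocklist is not None:
        docs = {rid: filter_blocklist(d, blocklist) for rid, d in docs.items()}
    if stopwords is not None:
        docs = {rid: filter_stopwords(d, stopwords) for rid, d in docs.items()}
    return docs


def docs_to_jsonl(docs: dict[str, TokenizedDocument], path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for rid in docs:
            d = docs[rid]
            fh.write(
                json.dumps(
                    {
                        "record_id": d.record_id,
                        "sentences": [list(s) for s in d.sentences],
                        "provenance_flags": sorted(d.provenance_flags),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def docs_from_jsonl(path) -> dict[str, TokenizedDocument]:
    import json

    docs: dict[str, TokenizedDocument] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            docs[obj["record_id"]] = TokenizedDocument(
                record_id=obj["record_id"],
                sentences=tuple(tuple(s) for s in obj["sentences"]),
                provenance_flags=frozenset(obj.get("provenance_flags", [])),
            )
    return docs
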