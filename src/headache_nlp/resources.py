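"""Access to the packaged word-list fixtures."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .corpus_io import WordList, read_wordlist


def _data_path(name: str) -> Path:
    return Path(str(files("headache_nlp").joinpath("data", name)))


def default_stopwords() -> WordList:
    """The bundled Dutch stop-word list."""
    return read_wordlist(_data_path("stopwords_nl.txt"), purpose="stopwords")


def default_blocklist() -> WordList:
    """The bundled class-label / label-revealing-term blocklist."""
    return read_wordlist(_data_path("blocklist_nl.txt"), purpose="label_blocklist")
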