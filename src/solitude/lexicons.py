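"""Loaders for the editable lexicon files the pipeline depends on.

All lexicons are plain-text configuration shipped as package data and
overridable by path: a valence lexicon for sentiment, a filler-word list
(multiword entries allowed), a relationship word -> category map, a
communication phrase -> frequency/mode map, and the coarse-POS dictionaries.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

import yaml


def _read_data_text(name: str, path: str | Path | None) -> str:
    if path is not None:
        return Path(path).read_text(encoding="utf-8")
    return (resources.files("solitude.data") / name).read_text(encoding="utf-8")


def _parse_two_column(text: str) -> List[Tuple[str, str]]:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        rows.append((key.strip(), value.strip()))
    return rows


def load_sentiment_lexicon(path: str | Path | None = None) -> Dict[str, float]:
    """token -> valence map (case-folded keys)."""
    return {k.lower(): float(v)
            for k, v in _parse_two_column(_read_data_text("sentiment.txt", path))}


def load_filler_lexicon(path: str | Path | None = None) -> List[str]:
    """Filler entries, each a space-separated (possibly multiword) phrase."""
    text = _read_data_text("fillers.txt", path)
    return [line.strip().lower() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def load_relationship_lexicon(path: str | Path | None = None) -> Dict[str, str]:
    """relationship word -> category map; every word maps to one category."""
    rows = _parse_two_column(_read_data_text("relationships.txt", path))
    lexicon: Dict[str, str] = {}
    for word, category in rows:
        word = word.lower()
        if word in lexicon and lexicon[word] != category:
            raise ValueError(f"word {word!r} mapped to two categories")
        lexicon[word] = category
    return lexicon


def load_communication_lexicon(path: str | Path | None = None):
    """Return (phrase -> contacts-per-month, phrase -> mode) maps."""
    raw = yaml.safe_load(_read_data_text("communication.yaml", path))
    freq = {str(k).lower(): float(v) for k, v in raw["frequency"].items()}
    if any(v <= 0 for v in freq.values()):
        raise ValueError("communication frequencies must be positive")
    mode = {str(k).lower(): str(v) for k, v in raw["mode"].items()}
    return freq, mode


def load_pos_lexicon(path: str | Path | None = None) -> Dict[str, str]:
    """word -> coarse tag dictionary for the packaged tagger."""
    return {k.lower(): v
            for k, v in _parse_two_column(_read_data_text("pos_lexicon.txt", path))}


def load_tag_mapping(path: str | Path | None = None) -> Dict[str, str]:
    """External tagset -> coarse tagset mapping (default: Penn Treebank)."""
    return dict(_parse_two_column(_read_data_text("penn_to_coarse.txt", path)))
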