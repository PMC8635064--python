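"""Coarse part-of-speech tagging behind a minimal tagger contract.

A *tagger* is any callable ``tokens -> tags`` returning one tag per token
from the 8-class coarse tag set::

    noun  verb  adjective  adverb  pronoun  interjection  filler  other

The packaged default is a deterministic dictionary tagger with suffix
heuristics for out-of-vocabulary words — adequate for the templated
conversational speech this package processes and for exercising the POS
feature suite.  Richer taggers plug in through :class:`MappedTagger`, which
folds an external tagset onto the coarse set via a shipped mapping file.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Sequence

from .lexicons import load_pos_lexicon, load_tag_mapping

COARSE_TAGS = ("noun", "verb", "adjective", "adverb", "pronoun",
               "interjection", "filler", "other")

Tagger = Callable[[Sequence[str]], List[str]]

_SUFFIX_RULES = (
    ("ly", "adverb"),
    ("ing", "verb"),
    ("ed", "verb"),
    ("tion", "noun"),
    ("sion", "noun"),
    ("ment", "noun"),
    ("ness", "noun"),
    ("ity", "noun"),
    ("ship", "noun"),
    ("hood", "noun"),
    ("ful", "adjective"),
    ("ous", "adjective"),
    ("ive", "adjective"),
    ("able", "adjective"),
)


class DictionaryTagger:
    """Deterministic word-list tagger with suffix fallbacks.

    Unknown words default to ``noun`` (open-class prior for content words);
    purely non-alphabetic tokens tag ``other``.
    """

    def __init__(self, lexicon: Dict[str, str] | None = None):
        self.lexicon = dict(load_pos_lexicon() if lexicon is None else lexicon)
        bad = set(self.lexicon.values()) - set(COARSE_TAGS)
        if bad:
            raise ValueError(f"unknown coarse tags in lexicon: {sorted(bad)}")

    def tag_word(self, token: str) -> str:
        word = token.lower()
        if word in self.lexicon:
            return self.lexicon[word]
        if not any(c.isalpha() for c in word):
            return "other"
        # s-stripped plural/3sg lookup before suffix heuristics
        if word.endswith("s") and word[:-1] in self.lexicon:
            return self.lexicon[word[:-1]]
        for suffix, tag in _SUFFIX_RULES:
            if len(word) > len(suffix) + 2 and word.endswith(suffix):
                return tag
        return "noun"

    def __call__(self, tokens: Sequence[str]) -> List[str]:
        return [self.tag_word(t) for t in tokens]


class MappedTagger:
    """Adapter folding an external tagger's tagset onto the coarse set.

    ``base`` is a callable ``tokens -> external tags``; ``mapping`` defaults
    to the shipped Penn-Treebank table.  Unmapped tags raise.
    """

    def __init__(self, base: Tagger, mapping: Dict[str, str] | None = None):
        self.base = base
        self.mapping = load_tag_mapping() if mapping is None else dict(mapping)

    def __call__(self, tokens: Sequence[str]) -> List[str]:
        out = []
        for token, tag in zip(tokens, self.base(tokens)):
            if tag not in self.mapping:
                raise KeyError(
                    f"tag {tag!r} (token {token!r}) missing from tag mapping")
            out.append(self.mapping[tag])
        return out


def default_tagger() -> DictionaryTagger:
    return DictionaryTagger()
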