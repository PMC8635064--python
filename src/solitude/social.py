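"""Pronoun-density and relationship/communication extraction.

These features are pure dictionary counts: no anaphora or coreference
resolution is attempted, so repeated or co-referent mentions each count and
relationship totals can overestimate the number of distinct people (e.g.
"I have children. A son and a daughter." counts three mentions in the
``children`` category).  That overestimation semantics is intentional and
relied upon by the tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .features import word_tokenize


@dataclass(frozen=True)
class PronounInventory:
    """Pronoun classes counted for density features.

    Second-person pronouns are excluded by design: in an interview they
    mostly address the interviewer, not a social contact.
    """

    first_singular: frozenset = frozenset({"i", "me", "my", "mine"})
    first_plural: frozenset = frozenset({"we", "our", "us", "ours"})
    third: frozenset = frozenset({"he", "she", "they", "them", "their"})
    excluded_second: frozenset = frozenset({"you", "your", "yours"})

    def __post_init__(self) -> None:
        sets = [self.first_singular, self.first_plural, self.third,
                self.excluded_second]
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("pronoun classes must be pairwise disjoint")


DEFAULT_INVENTORY = PronounInventory()


def pronoun_densities(
    tokens: Sequence[str],
    inventory: PronounInventory = DEFAULT_INVENTORY,
) -> Dict[str, float]:
    """Occurrence count of each pronoun class divided by total token count.

    Tokens are case-folded for matching.  Zero tokens yield zero densities
    with the flag set.
    """
    n = len(tokens)
    if n == 0:
        return {"first_singular": 0.0, "first_plural": 0.0, "third": 0.0,
                "degenerate": 1.0}
    lowered = [t.lower() for t in tokens]
    def density(words: frozenset) -> float:
        return sum(1 for t in lowered if t in words) / n
    return {"first_singular": density(inventory.first_singular),
            "first_plural": density(inventory.first_plural),
            "third": density(inventory.third),
            "degenerate": 0.0}


def _fold_token(token: str, lexicon: Dict[str, str]) -> Optional[str]:
    """Lexicon lookup with simple s-stripping plural folding."""
    word = token.lower()
    if word in lexicon:
        return word
    if word.endswith("s") and word[:-1] in lexicon:
        return word[:-1]
    return None


def count_relationships(
    response_text: str, lexicon: Dict[str, str]
) -> Dict[str, int]:
    """Count relationship-word mentions by category (pure word counting)."""
    if not lexicon:
        raise ValueError("empty relationship lexicon")
    counts: Counter = Counter()
    for token in word_tokenize(response_text):
        key = _fold_token(token, lexicon)
        if key is not None:
            counts[lexicon[key]] += 1
    return dict(counts)


def _match_phrases(
    tokens: List[str], phrases: Sequence[str]
) -> List[str]:
    """Longest-match phrase occurrences over a case-folded token stream."""
    by_len = sorted({tuple(p.split()) for p in phrases},
                    key=len, reverse=True)
    matched: List[str] = []
    i = 0
    while i < len(tokens):
        for phrase in by_len:
            k = len(phrase)
            if tuple(tokens[i:i + k]) == phrase:
                matched.append(" ".join(phrase))
                i += k
                break
        else:
            i += 1
    return matched


@dataclass
class CommunicationProfile:
    frequency_per_month: Optional[float]  # None when no frequency phrase hit
    modes: Set[str] = field(default_factory=set)


def communication_profile(
    response_text: str,
    frequency_lexicon: Dict[str, float],
    mode_lexicon: Dict[str, str],
) -> CommunicationProfile:
    """Communication frequency and modes from predefined American-English
    phrases.

    Frequency is the *maximum* matched contacts-per-month (the most frequent
    stated contact); modes are the union of matched mode phrases.  When no
    frequency phrase matches the frequency is reported missing, not zero.
    """
    if not frequency_lexicon or not mode_lexicon:
        raise ValueError("empty communication lexicon")
    tokens = [t.lower() for t in word_tokenize(response_text)]
    freq_hits = _match_phrases(tokens, list(frequency_lexicon))
    mode_hits = _match_phrases(tokens, list(mode_lexicon))
    frequency = (max(frequency_lexicon[p] for p in freq_hits)
                 if freq_hits else None)
    modes = {mode_lexicon[p] for p in mode_hits}
    return CommunicationProfile(frequency_per_month=frequency, modes=modes)


DEFAULT_NEGATION_PATTERNS = ("no one", "nobody", "not really")


def detect_none_understood(
    response_text: str,
    relationship_lexicon: Dict[str, str],
    patterns: Sequence[str] = DEFAULT_NEGATION_PATTERNS,
) -> bool:
    """True when a negation pattern matches and no relationship word
    co-occurs in the same response ("Nobody but my daughter" is False)."""
    tokens = [t.lower() for t in word_tokenize(response_text)]
    if any(_fold_token(t, relationship_lexicon) for t in tokens):
        return False
    for pattern in patterns:
        phrase = tuple(pattern.lower().split())
        k = len(phrase)
        if any(tuple(tokens[i:i + k]) == phrase
               for i in range(len(tokens) - k + 1)):
            return True
    return False


@dataclass
class SocialProfile:
    """Per-participant social features pooled from the located responses."""

    important_counts: Dict[str, int]
    understood_counts: Dict[str, int]
    none_understood: bool
    comm_frequency_per_month: Optional[float]
    modes: Set[str]
    pronoun_density: Dict[str, float]  # {scope}_{class} -> density

    @property
    def important_total(self) -> int:
        return sum(self.important_counts.values())

    @property
    def understood_total(self) -> int:
        return sum(self.understood_counts.values())


def build_social_profile(
    whole_transcript_text: str,
    section_text: str,
    q1_response: str,
    q3_response: str,
    q4_response: str,
    relationship_lexicon: Dict[str, str],
    frequency_lexicon: Dict[str, float],
    mode_lexicon: Dict[str, str],
    inventory: PronounInventory = DEFAULT_INVENTORY,
) -> SocialProfile:
    """Assemble the social profile: important relationships from Q1, feeling
    understood from Q3, communication from Q4, pronoun densities for both
    the whole-transcript and relationship-section scopes."""
    comm = communication_profile(q4_response, frequency_lexicon, mode_lexicon)
    density: Dict[str, float] = {}
    for scope, text in (("transcript", whole_transcript_text),
                        ("section", section_text)):
        d = pronoun_densities(word_tokenize(text), inventory)
        for cls in ("first_singular", "first_plural", "third"):
            density[f"{scope}_{cls}"] = d[cls]
    return SocialProfile(
        important_counts=count_relationships(q1_response, relationship_lexicon),
        understood_counts=count_relationships(q3_response, relationship_lexicon),
        none_understood=detect_none_understood(q3_response,
                                               relationship_lexicon),
        comm_frequency_per_month=comm.frequency_per_month,
        modes=comm.modes,
        pronoun_density=density,
    )
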