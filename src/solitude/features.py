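"""Linguistic feature suite computed from a text span.

Covers the feature families used to characterize interview responses:
part-of-speech profile, vocabulary richness (type-token ratio, Brunét's W,
Honoré's R), filled pauses, syntactic complexity (Yngve depth), pairwise
sentence similarity, lexicon-based sentiment aggregates, and response-length
statistics.  Aggregate dispersion uses the population SD throughout.

Degenerate inputs (empty token streams, single sentences, hapax-only
vocabularies) are returned as zero/capped values accompanied by an explicit
flag rather than raising: short conversational responses make these cases
routine.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .tagger import COARSE_TAGS, Tagger

# ---------------------------------------------------------------------------
# Tokenization


@dataclass
class TokenizedText:
    """Sentence-segmented tokens with parallel coarse POS tags."""

    sentences: List[List[str]]
    pos_tags: List[List[str]]

    def __post_init__(self) -> None:
        if len(self.sentences) != len(self.pos_tags):
            raise ValueError("sentences and tags not parallel")
        for sent, tags in zip(self.sentences, self.pos_tags):
            if len(sent) != len(tags):
                raise ValueError("tags not parallel to tokens within sentence")

    @property
    def tokens(self) -> List[str]:
        return [t for sent in self.sentences for t in sent]

    @property
    def tags(self) -> List[str]:
        return [t for tags in self.pos_tags for t in tags]


_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")
_WORD_RE = re.compile(r"[A-Za-z0-9'\-]+")


def split_sentences(text: str) -> List[str]:
    return [s for s in _SENT_SPLIT_RE.split(text.strip()) if s.strip()]


def word_tokenize(text: str) -> List[str]:
    """Case-preserving word tokenizer; punctuation is stripped."""
    return _WORD_RE.findall(text)


def tokenize_and_tag(text: str, tagger: Tagger) -> TokenizedText:
    """Sentence-split, tokenize and coarse-POS-tag a text span.

    Deterministic for a fixed tagger; empty text yields zero sentences.
    Tagger failures propagate annotated with the offending sentence.
    """
    sentences: List[List[str]] = []
    tags: List[List[str]] = []
    for sentence in split_sentences(text):
        tokens = word_tokenize(sentence)
        if not tokens:
            continue
        try:
            sent_tags = list(tagger(tokens))
        except Exception as exc:
            raise RuntimeError(f"tagger failed on {sentence!r}") from exc
        sentences.append(tokens)
        tags.append(sent_tags)
    return TokenizedText(sentences=sentences, pos_tags=tags)


# ---------------------------------------------------------------------------
# POS profile


def pos_profile(tt: TokenizedText) -> Dict[str, float]:
    """Per-tag frequency and ratio features plus the pronoun:noun ratio.

    ``freq_<tag>``  = count(tag) / total tokens.
    ``ratio_<tag>`` = count(tag) / open-class token count (non-"other" tags);
    the convention distinguishing the two normalizations is this package's.
    Zero tokens (or zero nouns for the pronoun:noun ratio) yield 0 with the
    ``degenerate`` flag set.
    """
    counts = Counter(tt.tags)
    n = sum(counts.values())
    open_n = n - counts.get("other", 0)
    out: Dict[str, float] = {}
    for tag in COARSE_TAGS:
        out[f"freq_{tag}"] = counts.get(tag, 0) / n if n else 0.0
        out[f"ratio_{tag}"] = counts.get(tag, 0) / open_n if open_n else 0.0
    nouns = counts.get("noun", 0)
    out["pronoun_noun_ratio"] = (counts.get("pronoun", 0) / nouns
                                 if nouns else 0.0)
    out["degenerate"] = float(n == 0 or nouns == 0)
    return out


# ---------------------------------------------------------------------------
# Vocabulary richness

#: Honoré's statistic diverges when every type is a hapax; the denominator is
#: floored at this value and the result flagged.
HONORE_EPSILON = 1e-3

BRUNET_EXPONENT = -0.165


@dataclass
class VocabularyRichness:
    type_token_ratio: float
    brunet_index: float
    honore_statistic: float
    degenerate: bool = False
    honore_capped: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {
            "type_token_ratio": self.type_token_ratio,
            "brunet_index": self.brunet_index,
            "honore_statistic": self.honore_statistic,
        }


def vocabulary_richness(tokens: Sequence[str]) -> VocabularyRichness:
    """TTR, Brunét's index W and Honoré's statistic R over case-folded types.

    With N tokens, V types and V1 hapax types:
    TTR = V/N;  W = N^(V^-0.165) (lower = richer);
    R = 100 ln(N) / (1 - V1/V), capped when V1 = V.
    """
    n = len(tokens)
    if n == 0:
        return VocabularyRichness(0.0, 0.0, 0.0, degenerate=True)
    counts = Counter(t.lower() for t in tokens)
    v = len(counts)
    v1 = sum(1 for c in counts.values() if c == 1)
    ttr = v / n
    brunet = n ** (v ** BRUNET_EXPONENT)
    denom = 1.0 - v1 / v
    capped = denom < HONORE_EPSILON
    honore = 100.0 * math.log(n) / max(denom, HONORE_EPSILON)
    return VocabularyRichness(ttr, brunet, honore, honore_capped=capped)


# ---------------------------------------------------------------------------
# Filled pauses


def filler_frequency(tt: TokenizedText, filler_lexicon: Sequence[str]) -> float:
    """Fraction of tokens opening a filler occurrence.

    Entries may be multiword ("you know"); each is matched as a token n-gram
    by a sliding window within sentences and counted once per occurrence.
    Zero tokens yield 0.
    """
    if not filler_lexicon:
        raise ValueError("empty filler lexicon")
    phrases = [tuple(p.lower().split()) for p in filler_lexicon]
    total = len(tt.tokens)
    if total == 0:
        return 0.0
    count = 0
    for sentence in tt.sentences:
        lowered = [t.lower() for t in sentence]
        for phrase in phrases:
            k = len(phrase)
            count += sum(1 for i in range(len(lowered) - k + 1)
                         if tuple(lowered[i:i + k]) == phrase)
    return count / total


# ---------------------------------------------------------------------------
# Syntactic complexity (Yngve depth)

#: A parse tree is either a token (str) or a sequence of child subtrees.
ParseTree = Union[str, Sequence["ParseTree"]]


def yngve_depths(tree: ParseTree) -> List[float]:
    """Per-word Yngve depth, in word order.

    Children of each node are indexed right-to-left starting at 0 (rightmost
    child = 0); a word's depth is the sum of child indices along its
    root-to-leaf path.  Deeply left-branching structure therefore scores
    high, right-branching scores low.
    """
    depths: List[float] = []

    def walk(node: ParseTree, acc: float) -> None:
        if isinstance(node, str):
            depths.append(acc)
            return
        children = list(node)
        if not children:
            raise ValueError("internal node with no children")
        last = len(children) - 1
        for i, child in enumerate(children):
            walk(child, acc + (last - i))

    walk(tree, 0.0)
    return depths


def fallback_parse(tokens: Sequence[str]) -> ParseTree:
    """Deterministic strictly right-branching binary tree over tokens.

    Used when no constituency parser adapter is configured; yields Yngve
    depths [1, ..., 1, 0] (total n-1), a flat lower bound on complexity.
    """
    if not tokens:
        raise ValueError("cannot parse an empty token list")
    if len(tokens) == 1:
        return tokens[0]
    return (tokens[0], fallback_parse(tokens[1:]))


def yngve_statistics(
    sentences: Sequence[Sequence[str]],
    parser=fallback_parse,
) -> Dict[str, float]:
    """Per-sentence Yngve depths aggregated across a span.

    ``yngve_mean``   mean over sentences of the per-sentence mean depth;
    ``yngve_total``  sum of all per-sentence depth totals;
    ``yngve_median`` median of per-sentence mean depths.
    """
    per_sentence_means: List[float] = []
    total = 0.0
    for sentence in sentences:
        if not sentence:
            continue
        depths = yngve_depths(parser(list(sentence)))
        per_sentence_means.append(float(np.mean(depths)))
        total += float(np.sum(depths))
    if not per_sentence_means:
        return {"yngve_mean": 0.0, "yngve_total": 0.0, "yngve_median": 0.0}
    return {
        "yngve_mean": float(np.mean(per_sentence_means)),
        "yngve_total": total,
        "yngve_median": float(np.median(per_sentence_means)),
    }


# ---------------------------------------------------------------------------
# Sentence similarity


def _count_cosine(a: Counter, b: Counter) -> float:
    shared = set(a) & set(b)
    dot = sum(a[t] * b[t] for t in shared)
    na = math.sqrt(sum(c * c for c in a.values()))
    nb = math.sqrt(sum(c * c for c in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


def sentence_similarity_stats(
    sentences: Sequence[Sequence[str]],
) -> Dict[str, float]:
    """Aggregates of cosine similarity between all unordered sentence pairs.

    Sentences are bag-of-words raw term-count vectors (case-folded).  Fewer
    than two sentences yields all-zero statistics with the flag set.
    """
    counters = [Counter(t.lower() for t in s) for s in sentences]
    if len(counters) < 2:
        return {"sentence_similarity_mean": 0.0,
                "sentence_similarity_median": 0.0,
                "sentence_similarity_sd": 0.0,
                "sentence_similarity_max": 0.0,
                "degenerate": 1.0}
    sims = [
        _count_cosine(counters[i], counters[j])
        for i in range(len(counters))
        for j in range(i + 1, len(counters))
    ]
    arr = np.asarray(sims)
    return {"sentence_similarity_mean": float(arr.mean()),
            "sentence_similarity_median": float(np.median(arr)),
            "sentence_similarity_sd": float(arr.std()),
            "sentence_similarity_max": float(arr.max()),
            "degenerate": 0.0}


# ---------------------------------------------------------------------------
# Sentiment

#: Normalization constant of the compound score s / sqrt(s^2 + alpha).
SENTIMENT_ALPHA = 15.0


@dataclass(frozen=True)
class SentimentScore:
    pos: float
    neg: float
    neu: float
    compound: float

    def __post_init__(self) -> None:
        if abs(self.pos + self.neg + self.neu - 1.0) > 1e-6:
            raise ValueError("pos + neg + neu must sum to 1")
        if not -1.0 <= self.compound <= 1.0:
            raise ValueError("compound outside [-1, 1]")


def sentiment_score(
    sentence: Sequence[str], lexicon: Dict[str, float]
) -> SentimentScore:
    """Additive lexicon sentiment for one sentence.

    The raw valence sum s maps to compound = s / sqrt(s^2 + 15); pos/neg/neu
    are the normalized proportions of positive-valence, negative-valence and
    zero-valence token mass.  Capitalization/punctuation intensity boosting
    of the full VADER-style scorers is deliberately not applied.
    """
    if not lexicon:
        raise ValueError("empty sentiment lexicon")
    if not sentence:
        return SentimentScore(0.0, 0.0, 1.0, 0.0)
    s = 0.0
    pos_mass = neg_mass = 0.0
    neu_count = 0
    for token in sentence:
        valence = lexicon.get(token.lower(), 0.0)
        s += valence
        if valence > 0:
            pos_mass += valence
        elif valence < 0:
            neg_mass += -valence
        else:
            neu_count += 1
    total = pos_mass + neg_mass + neu_count
    if total == 0:  # only possible for an all-hit, exactly-cancelling edge
        return SentimentScore(0.0, 0.0, 1.0, 0.0)
    compound = s / math.sqrt(s * s + SENTIMENT_ALPHA)
    return SentimentScore(pos_mass / total, neg_mass / total,
                          neu_count / total, compound)


def aggregate_sentiment(scores: Sequence[SentimentScore]) -> Dict[str, float]:
    """Mean/median/population-SD/max per sentiment channel across sentences."""
    out: Dict[str, float] = {}
    channels = ("pos", "neg", "neu", "compound")
    if not scores:
        for ch in channels:
            for stat in ("mean", "median", "sd", "max"):
                out[f"sentiment_{ch}_{stat}"] = 0.0
        out["degenerate"] = 1.0
        return out
    for ch in channels:
        values = np.asarray([getattr(s, ch) for s in scores])
        out[f"sentiment_{ch}_mean"] = float(values.mean())
        out[f"sentiment_{ch}_median"] = float(np.median(values))
        out[f"sentiment_{ch}_sd"] = float(values.std())
        out[f"sentiment_{ch}_max"] = float(values.max())
    out["degenerate"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Response length


def response_length_stats(responses: Sequence[str]) -> Dict[str, float]:
    """Length statistics over a participant's located responses."""
    if not responses:
        return {"response_length_total_words": 0.0,
                "response_length_total_chars": 0.0,
                "response_length_mean_words": 0.0,
                "response_length_median_chars": 0.0,
                "response_length_min_words": 0.0,
                "degenerate": 1.0}
    words = [len(word_tokenize(r)) for r in responses]
    chars = [len(r) for r in responses]
    return {"response_length_total_words": float(sum(words)),
            "response_length_total_chars": float(sum(chars)),
            "response_length_mean_words": float(np.mean(words)),
            "response_length_median_chars": float(np.median(chars)),
            "response_length_min_words": float(min(words)),
            "degenerate": 0.0}


# ---------------------------------------------------------------------------
# Full suite


def linguistic_feature_vector(
    responses: Sequence[str],
    tagger: Tagger,
    sentiment_lexicon: Dict[str, float],
    filler_lexicon: Sequence[str],
    parser=fallback_parse,
) -> Dict[str, float]:
    """All linguistic features for one participant's relationship-section
    responses, keyed by the stable registry names."""
    text = " ".join(responses)
    tt = tokenize_and_tag(text, tagger)
    features: Dict[str, float] = {}
    profile = pos_profile(tt)
    profile.pop("degenerate", None)
    features.update(profile)
    features.update(vocabulary_richness(tt.tokens).as_dict())
    features["filler_frequency"] = filler_frequency(tt, filler_lexicon)
    features.update(yngve_statistics(tt.sentences, parser=parser))
    sim = sentence_similarity_stats(tt.sentences)
    sim.pop("degenerate", None)
    features.update(sim)
    scores = [sentiment_score(s, sentiment_lexicon) for s in tt.sentences]
    agg = aggregate_sentiment(scores)
    agg.pop("degenerate", None)
    features.update(agg)
    lengths = response_length_stats(list(responses))
    lengths.pop("degenerate", None)
    features.update(lengths)
    return features
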