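"""Linguistic feature operations against hand-computed and brute-force
oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solitude.features import (SentimentScore, TokenizedText,
                               aggregate_sentiment, fallback_parse,
                               filler_frequency, pos_profile,
                               response_length_stats, sentence_similarity_stats,
                               sentiment_score, tokenize_and_tag,
                               vocabulary_richness, yngve_depths,
                               yngve_statistics)


def yngve_oracle(tree):
    """Materialize every root-to-leaf path and sum right-to-left indices."""
    depths = []

    def walk(node, path):
        if isinstance(node, str):
            depths.append(float(sum(path)))
            return
        children = list(node)
        for i, child in enumerate(children):
            walk(child, path + [len(children) - 1 - i])

    walk(tree, [])
    return depths


def random_tree(rng, n_leaves):
    leaves = [f"w{i}" for i in range(n_leaves)]

    def build(tokens):
        if len(tokens) == 1:
            return tokens[0]
        n_children = int(rng.integers(2, min(len(tokens), 4) + 1))
        cuts = sorted(rng.choice(np.arange(1, len(tokens)),
                                 size=n_children - 1, replace=False))
        parts = np.split(np.array(tokens, dtype=object), cuts)
        return tuple(build(list(p)) for p in parts)

    return build(leaves)


class TestTokenizeAndTag:
    def test_empty_text_gives_zero_sentences(self):
        tt = tokenize_and_tag("", lambda toks: ["other"] * len(toks))
        assert tt.sentences == []

    def test_dictionary_tagger_fixture(self):
        mapping = {"i": "pronoun", "run": "verb"}
        tt = tokenize_and_tag("I run.", lambda ts: [mapping[t.lower()]
                                                    for t in ts])
        assert tt.tags == ["pronoun", "verb"]

    def test_two_sentences_partition_tokens(self):
        tt = tokenize_and_tag("One two. Three four five.",
                              lambda ts: ["other"] * len(ts))
        assert [len(s) for s in tt.sentences] == [2, 3]


class TestPosProfile:
    def test_direct_counts(self):
        tt = TokenizedText([["a", "b", "c", "d"]],
                           [["noun", "noun", "verb", "pronoun"]])
        profile = pos_profile(tt)
        assert profile["freq_noun"] == pytest.approx(0.5)
        assert profile["pronoun_noun_ratio"] == pytest.approx(0.5)

    def test_single_tag_saturates(self):
        tt = TokenizedText([["a", "b"]], [["verb", "verb"]])
        profile = pos_profile(tt)
        assert profile["freq_verb"] == 1.0
        assert profile["freq_noun"] == 0.0

    def test_mixed_fixture_hand_enumeration(self):
        tags = ["noun", "verb", "verb", "pronoun", "adverb", "noun",
                "other", "filler", "adjective", "noun"]
        tt = TokenizedText([["w"] * 10], [tags])
        profile = pos_profile(tt)
        assert profile["freq_noun"] == pytest.approx(3 / 10)
        assert profile["freq_verb"] == pytest.approx(2 / 10)
        assert profile["ratio_noun"] == pytest.approx(3 / 9)  # 9 non-other
        assert profile["pronoun_noun_ratio"] == pytest.approx(1 / 3)

    def test_zero_tokens_flagged(self):
        profile = pos_profile(TokenizedText([], []))
        assert profile["freq_noun"] == 0.0
        assert profile["degenerate"] == 1.0


class TestVocabularyRichness:
    def test_repeated_token_fixture(self):
        r = vocabulary_richness(["the"] * 4)
        assert r.type_token_ratio == pytest.approx(0.25)
        assert r.honore_statistic == pytest.approx(100 * math.log(4), rel=1e-6)

    def test_formula_evaluation_n100(self):
        # N=100, V=50 (25 singletons, 25 triples): W ~ 11.19, R ~ 921.03
        tokens = [f"s{i}" for i in range(25)]
        for i in range(25):
            tokens += [f"t{i}"] * 3
        r = vocabulary_richness(tokens)
        assert len(tokens) == 100
        assert r.brunet_index == pytest.approx(100 ** (50 ** -0.165), rel=1e-9)
        assert r.brunet_index == pytest.approx(11.19, abs=0.005)
        assert r.honore_statistic == pytest.approx(100 * math.log(100) / 0.5,
                                                   rel=1e-9)
        assert r.honore_statistic == pytest.approx(921.03, abs=0.005)

    def test_single_token(self):
        r = vocabulary_richness(["word"])
        assert r.type_token_ratio == 1.0
        assert r.brunet_index == pytest.approx(1.0)
        assert r.honore_capped

    def test_empty_flagged(self):
        assert vocabulary_richness([]).degenerate

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=30))
    def test_ttr_non_increasing_under_self_concatenation(self, tokens):
        once = vocabulary_richness(tokens).type_token_ratio
        twice = vocabulary_richness(tokens * 2).type_token_ratio
        assert twice <= once + 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("abcde"), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_brunet_invariant_to_token_order(self, tokens, rnd):
        shuffled = list(tokens)
        rnd.shuffle(shuffled)
        assert (vocabulary_richness(tokens).brunet_index
                == pytest.approx(vocabulary_richness(shuffled).brunet_index))


class TestFillerFrequency:
    def test_single_word_fillers(self):
        tt = TokenizedText([["um", "I", "um", "left"]], [["filler"] * 4])
        assert filler_frequency(tt, ["um", "uh"]) == pytest.approx(0.5)

    def test_no_fillers(self):
        tt = TokenizedText([["hello", "there"]], [["other"] * 2])
        assert filler_frequency(tt, ["um"]) == 0.0

    def test_multiword_entry_counted_per_occurrence(self):
        tokens = "you know I mean you know".split()
        tt = TokenizedText([tokens], [["other"] * len(tokens)])
        # sliding-window oracle: "you know" occurs twice in 6 tokens
        assert filler_frequency(tt, ["you know"]) == pytest.approx(2 / 6)


class TestYngve:
    def test_single_word_tree(self):
        assert yngve_depths("word") == [0.0]

    def test_hand_enumerated_tree(self):
        tree = (("the", "cat"), ("sat",))  # (S (NP the cat) (VP sat))
        assert yngve_depths(tree) == [2.0, 1.0, 0.0]

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_left_branching_chain_maximal_first_depth(self, n):
        tree = "w0"
        for i in range(1, n):
            tree = (tree, f"w{i}")
        assert yngve_depths(tree)[0] == n - 1

    def test_random_trees_match_path_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tree = random_tree(rng, int(rng.integers(1, 7)))
            assert yngve_depths(tree) == yngve_oracle(tree)


class TestFallbackParse:
    def test_single_token_is_leaf(self):
        assert fallback_parse(["hi"]) == "hi"

    def test_three_tokens_depths(self):
        assert yngve_depths(fallback_parse(["a", "b", "c"])) == [1.0, 1.0, 0.0]

    @pytest.mark.parametrize("n", range(1, 7))
    def test_total_depth_closed_form(self, n):
        tokens = [f"w{i}" for i in range(n)]
        assert sum(yngve_depths(fallback_parse(tokens))) == n - 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fallback_parse([])

    def test_statistics_aggregation(self):
        stats = yngve_statistics([["a", "b", "c"], ["d", "e"]])
        assert stats["yngve_total"] == pytest.approx(3.0)  # (3-1) + (2-1)
        assert stats["yngve_mean"] == pytest.approx((2 / 3 + 1 / 2) / 2)


class TestSentenceSimilarity:
    def test_identical_sentences(self):
        stats = sentence_similarity_stats([["a", "b"], ["a", "b"]])
        assert stats["sentence_similarity_mean"] == pytest.approx(1.0)
        assert stats["sentence_similarity_sd"] == pytest.approx(0.0)

    def test_disjoint_vocabularies(self):
        stats = sentence_similarity_stats([["a"], ["b"], ["c"]])
        assert stats["sentence_similarity_max"] == 0.0

    def test_three_sentences_match_bruteforce(self):
        sents = [["the", "cat", "sat"], ["the", "dog"], ["cat", "dog", "dog"]]

        def cos(x, y):
            vocab = sorted(set(x) | set(y))
            a = np.array([x.count(t) for t in vocab], dtype=float)
            b = np.array([y.count(t) for t in vocab], dtype=float)
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        expected = [cos(sents[0], sents[1]), cos(sents[0], sents[2]),
                    cos(sents[1], sents[2])]
        stats = sentence_similarity_stats(sents)
        assert stats["sentence_similarity_mean"] == pytest.approx(
            np.mean(expected))
        assert stats["sentence_similarity_max"] == pytest.approx(max(expected))
        assert stats["sentence_similarity_sd"] == pytest.approx(
            np.std(expected))

    def test_symmetric_under_reordering(self):
        sents = [["a", "b"], ["b", "c"], ["c", "d", "a"]]
        forward = sentence_similarity_stats(sents)
        backward = sentence_similarity_stats(sents[::-1])
        assert forward == backward

    def test_fewer_than_two_sentences_flagged(self):
        stats = sentence_similarity_stats([["only", "one"]])
        assert stats["degenerate"] == 1.0
        assert stats["sentence_similarity_mean"] == 0.0


LEXICON = {"good": 2.0, "bad": -2.0, "awful": -3.0}


class TestSentiment:
    def test_no_lexicon_hits_is_neutral(self):
        score = sentiment_score(["walk", "home"], LEXICON)
        assert score.compound == 0.0
        assert score.neu == 1.0

    def test_single_positive_token_compound(self):
        score = sentiment_score(["good"], LEXICON)
        assert score.compound == pytest.approx(2 / math.sqrt(4 + 15))
        assert score.pos == pytest.approx(1.0)

    def test_antisymmetric_cancellation(self):
        score = sentiment_score(["good", "bad"], LEXICON)
        assert score.compound == 0.0
        assert score.pos == pytest.approx(score.neg)

    def test_empty_sentence(self):
        score = sentiment_score([], LEXICON)
        assert score.neu == 1.0 and score.compound == 0.0

    def test_channels_sum_to_one(self):
        for tokens in (["good", "walk"], ["awful", "bad", "good", "x"]):
            s = sentiment_score(tokens, LEXICON)
            assert s.pos + s.neg + s.neu == pytest.approx(1.0, abs=1e-9)


class TestAggregateSentiment:
    def test_single_score(self):
        agg = aggregate_sentiment([SentimentScore(0.2, 0.1, 0.7, 0.4)])
        assert agg["sentiment_compound_mean"] == pytest.approx(0.4)
        assert agg["sentiment_compound_sd"] == 0.0
        assert agg["sentiment_compound_max"] == pytest.approx(0.4)

    def test_symmetric_compounds(self):
        scores = [SentimentScore(1.0, 0.0, 0.0, 0.5),
                  SentimentScore(0.0, 1.0, 0.0, -0.5)]
        agg = aggregate_sentiment(scores)
        assert agg["sentiment_compound_mean"] == pytest.approx(0.0)
        assert agg["sentiment_compound_sd"] == pytest.approx(0.5)
        assert agg["sentiment_compound_max"] == pytest.approx(0.5)

    def test_four_scores_match_recomputation(self):
        rng = np.random.default_rng(3)
        scores = []
        for _ in range(4):
            p, n = rng.uniform(0, 0.4, size=2)
            scores.append(SentimentScore(p, n, 1 - p - n,
                                         float(rng.uniform(-1, 1))))
        agg = aggregate_sentiment(scores)
        for ch in ("pos", "neg", "neu", "compound"):
            values = np.array([getattr(s, ch) for s in scores])
            assert agg[f"sentiment_{ch}_mean"] == pytest.approx(values.mean())
            assert agg[f"sentiment_{ch}_median"] == pytest.approx(
                np.median(values))
            assert agg[f"sentiment_{ch}_sd"] == pytest.approx(values.std())
            assert agg[f"sentiment_{ch}_max"] == pytest.approx(values.max())

    def test_empty_list_flagged(self):
        agg = aggregate_sentiment([])
        assert agg["degenerate"] == 1.0


class TestResponseLength:
    def test_two_responses(self):
        stats = response_length_stats(["a b", "c"])
        assert stats["response_length_total_words"] == 3
        assert stats["response_length_min_words"] == 1

    def test_empty_response_gives_zero_minimum(self):
        stats = response_length_stats(["some words", ""])
        assert stats["response_length_min_words"] == 0

    def test_five_responses_hand_counts(self):
        responses = ["one two three", "four", "", "five six", "seven"]
        stats = response_length_stats(responses)
        assert stats["response_length_total_words"] == 7
        assert stats["response_length_total_chars"] == sum(
            len(r) for r in responses)
        assert stats["response_length_mean_words"] == pytest.approx(7 / 5)
        assert stats["response_length_median_chars"] == pytest.approx(
            np.median([len(r) for r in responses]))
        assert stats["response_length_min_words"] == 0
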