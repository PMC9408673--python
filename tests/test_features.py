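"""The nine-feature system: PMI, subject relevance, structure, polarity,
publisher behaviour, regulatory updates and theta elimination."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_clause, make_message
from epiwatch.corpus import Corpus, Publisher
from epiwatch.features import (
    FEATURE_NAMES,
    build_corpus_stats,
    eliminate_publishers,
    extract_features,
    f1_subject_relevance,
    f5_emotional_intensity,
    feature_matrix,
    pmi,
    publisher_features,
    text_structure_features,
    update_false_history,
)


def stats_from_docs(docs):
    return build_corpus_stats([d.split() for d in docs])


class TestPMI:
    def test_perfect_cooccurrence_in_four_docs(self):
        # a in 2 docs, b in 2 docs, both together in 2 of 4 -> log 2
        stats = stats_from_docs(["a b", "a b", "c", "d"])
        assert pmi("a", "b", stats) == pytest.approx(math.log(2))

    def test_independent_words_have_zero_pmi(self):
        # p(a)=1/2, p(b)=1/2, p(ab)=1/4 = p(a)p(b)
        stats = stats_from_docs(["a b", "a", "b", "c"])
        assert pmi("a", "b", stats) == pytest.approx(0.0)

    def test_never_cooccurring_words_have_negative_infinite_pmi(self):
        stats = stats_from_docs(["a", "b"])
        assert pmi("a", "b", stats) == -math.inf

    def test_smoothing_keeps_value_finite(self):
        stats = stats_from_docs(["a", "b"])
        assert math.isfinite(pmi("a", "b", stats, smoothing=1e-9))

    def test_empty_corpus_rejected(self):
        stats = build_corpus_stats([])
        with pytest.raises(ValueError):
            pmi("a", "b", stats)

    @given(st.lists(st.lists(st.sampled_from("abcde"), min_size=1, max_size=4),
                    min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_on_random_corpora(self, docs):
        stats = build_corpus_stats(docs)
        for a in "abc":
            for b in "cde":
                assert pmi(a, b, stats, 1e-9) == pytest.approx(
                    pmi(b, a, stats, 1e-9)
                )

    @given(st.lists(st.lists(st.sampled_from("abcde"), min_size=1, max_size=5),
                    min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_document_counting(self, docs):
        """Independent oracle: recount frequencies with raw loops."""
        stats = build_corpus_stats(docs)
        n = len(docs)
        sets = [set(d) for d in docs]
        for a, b in [("a", "b"), ("c", "d"), ("a", "e")]:
            pa = sum(a in s for s in sets) / n
            pb = sum(b in s for s in sets) / n
            pab = sum(a in s and b in s for s in sets) / n
            s = 1e-9
            want = math.log((pab + s) / ((pa + s) * (pb + s)))
            assert pmi(a, b, stats, s) == pytest.approx(want)


class TestSubjectRelevance:
    def test_no_nouns_scores_zero(self):
        stats = stats_from_docs(["a b"])
        msg = make_message(clauses=[make_clause([("runs", "verb")])])
        assert f1_subject_relevance(msg, ["a"], stats) == 0.0

    def test_single_perfect_pair_scores_log2(self):
        stats = stats_from_docs(["n f", "n f", "x", "y"])
        msg = make_message(clauses=[make_clause([("n", "noun")])])
        assert f1_subject_relevance(msg, ["f"], stats) == pytest.approx(math.log(2))

    def test_unrelated_nouns_clip_to_zero(self):
        stats = stats_from_docs(["n", "f", "n", "f"])
        msg = make_message(clauses=[make_clause([("n", "noun")])])
        assert f1_subject_relevance(msg, ["f"], stats) == 0.0

    def test_empty_feature_words_rejected(self):
        stats = stats_from_docs(["a"])
        msg = make_message(clauses=[make_clause([("a", "noun")])])
        with pytest.raises(ValueError):
            f1_subject_relevance(msg, [], stats)

    def test_equals_brute_force_double_loop(self):
        docs = ["n1 f1 x", "n1 n2 f2", "f1 f2", "n2 y", "n1 f1"]
        stats = stats_from_docs(docs)
        feature_words = ["f1", "f2"]
        msg = make_message(
            clauses=[make_clause([("n1", "noun"), ("n2", "noun"), ("v", "verb")])]
        )
        total, count = 0.0, 0
        for noun in ["n1", "n2"]:
            for fw in feature_words:
                total += max(pmi(noun, fw, stats, 1e-9), 0.0)
                count += 1
        assert f1_subject_relevance(msg, feature_words, stats, 1e-9) == pytest.approx(
            total / count
        )


class TestTextStructure:
    def test_counts_content_tokens_and_clauses(self):
        msg = make_message(
            clauses=[
                make_clause([("a", "noun"), ("b", "other")]),
                make_clause([("c", "verb"), ("d", "adverb")]),
            ],
            raw=100,
            effective=80,
        )
        assert text_structure_features(msg) == (3, 2, 0.8)

    def test_empty_message(self):
        msg = make_message(clauses=[], raw=0, effective=0)
        assert text_structure_features(msg) == (0, 0, 0.0)


class TestEmotionalIntensity:
    @pytest.mark.parametrize(
        "polarities,expected",
        [
            (["positive"] * 3 + ["negative"], 0.75),
            (["neutral"] * 4, 0.5),
            (["negative"] * 4, 0.0),
            (["positive", "neutral", "negative"], 0.5),
        ],
    )
    def test_positive_share_of_polarized_clauses(self, polarities, expected):
        msg = make_message(
            clauses=[make_clause([("w", "other")], p) for p in polarities]
        )
        assert f5_emotional_intensity(msg) == pytest.approx(expected)


class TestPublisherFeatures:
    def test_field_passthrough(self):
        pub = Publisher("p", name_is_real=True, platform_tier=3, history_count=120)
        assert publisher_features(pub) == (1, 3, 120)

    def test_pseudonymous_low_tier(self):
        pub = Publisher("p", name_is_real=False, platform_tier=1, history_count=0)
        assert publisher_features(pub) == (0, 1, 0)


class TestFalseHistory:
    @pytest.mark.parametrize(
        "classified,expected",
        [
            ([], 0.0),
            (["false_info"] * 2 + ["true_info"] * 2, 0.5),
            (["false_info"] * 4, 1.0),
        ],
    )
    def test_false_fraction_of_classified(self, classified, expected):
        pub = Publisher("p", name_is_real=True, platform_tier=2)
        assert update_false_history(pub, classified).false_history_prob == expected


class TestElimination:
    def make_corpus(self, probs):
        pubs = {
            pid: Publisher(pid, True, 2, 10, false_history_prob=p)
            for pid, p in probs.items()
        }
        msgs = [
            make_message(f"m{pid}{k}", pid) for pid in probs for k in range(3)
        ]
        return Corpus(msgs, pubs)

    def test_clean_publishers_keep_everything(self):
        corpus = self.make_corpus({"a": 0.0, "b": 0.0})
        assert len(eliminate_publishers(corpus, 0.5)) == 6

    def test_flagged_publisher_messages_removed(self):
        corpus = self.make_corpus({"a": 0.6, "b": 0.1})
        out = eliminate_publishers(corpus, 0.5)
        assert len(out) == 3
        assert all(m.publisher_id == "b" for m in out.messages)

    def test_theta_zero_removes_all(self):
        corpus = self.make_corpus({"a": 0.0, "b": 0.9})
        assert len(eliminate_publishers(corpus, 0.0)) == 0

    def test_idempotent(self):
        corpus = self.make_corpus({"a": 0.7, "b": 0.2})
        once = eliminate_publishers(corpus, 0.5)
        twice = eliminate_publishers(once, 0.5)
        assert twice.messages == once.messages

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_theta(self, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        corpus = self.make_corpus({"a": 0.3, "b": 0.55, "c": 0.8})
        kept_lo = {m.message_id for m in eliminate_publishers(corpus, lo).messages}
        kept_hi = {m.message_id for m in eliminate_publishers(corpus, hi).messages}
        assert kept_lo <= kept_hi

    def test_theta_out_of_range_rejected(self):
        corpus = self.make_corpus({"a": 0.0})
        with pytest.raises(ValueError):
            eliminate_publishers(corpus, 1.5)


class TestExtractFeatures:
    def test_eight_classification_features_plus_regulatory(self):
        stats = stats_from_docs(["a b"])
        pub = Publisher("p", True, 2, 5)
        msg = make_message(clauses=[make_clause([("a", "noun")])])
        fv = extract_features(msg, pub, ["b"], stats, smoothing=1e-9)
        assert len(fv.classification_values()) == 8
        assert len(fv.values()) == 9

    def test_neutral_empty_fixture_composes_trivial_cases(self):
        stats = stats_from_docs(["a b"])
        pub = Publisher("p", name_is_real=False, platform_tier=1, history_count=0)
        msg = make_message(clauses=[], raw=0, effective=0)
        fv = extract_features(msg, pub, ["b"], stats)
        assert fv.values() == (0, 0, 0, 0, 0.5, 0, 1, 0, 0)

    def test_deterministic(self, small_corpus):
        stats = stats_from_docs(["virus mask", "vaccine"])
        msg = small_corpus.messages[0]
        pub = small_corpus.publishers["p1"]
        a = extract_features(msg, pub, ["virus"], stats, 1e-9)
        b = extract_features(msg, pub, ["virus"], stats, 1e-9)
        assert a == b

    def test_feature_matrix_shape_and_bounds(self, small_corpus):
        stats = build_corpus_stats(
            [[t for t, _ in m.tokens()] for m in small_corpus.messages]
        )
        df = feature_matrix(small_corpus, ["virus"], stats, smoothing=1e-9)
        assert list(df.columns) == list(FEATURE_NAMES) + ["label"]
        assert len(df) == 3
        assert df["f4"].between(0, 1).all()
        assert df["f5"].between(0, 1).all()
        assert df["f7"].isin([1, 2, 3]).all()
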