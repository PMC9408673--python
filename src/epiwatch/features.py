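"""The nine-feature identification system for false epidemic information.

Eight classification features are extracted from four levels:

* coarse granularity — F1 subject relevance: mean positive pointwise mutual
  information (PMI) between the message's nouns and a fixed list of epidemic
  subject feature words, estimated from document-level co-occurrence counts;
* fine granularity — F2 number of feature words (nouns + verbs + adjectives
  + adverbs), F3 number of clauses, F4 effective length E/T;
* emotional orientation — F5 emotional intensity P/(P+R), the share of
  positive evaluation clauses among polarized clauses;
* publisher behaviour — F6 real-name flag, F7 platform tier (1-3),
  F8 historical message volume.

A ninth *regulatory* feature F9 tracks each publisher's running probability
of releasing false information; it starts at 0 and is raised as the
classifier flags the publisher's messages.  Once F9 reaches a threshold
theta, every message from that publisher is eliminated from the corpus.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Corpus, Message, Publisher

__all__ = [
    "CorpusStats",
    "FeatureVector",
    "FEATURE_NAMES",
    "build_corpus_stats",
    "pmi",
    "f1_subject_relevance",
    "text_structure_features",
    "f5_emotional_intensity",
    "publisher_features",
    "update_false_history",
    "eliminate_publishers",
    "extract_features",
    "feature_matrix",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9")

#: number of classification features (the regulatory feature F9 is separate)
N_CLASSIFICATION_FEATURES = 8


@dataclass(frozen=True)
class CorpusStats:
    """Document-frequency statistics for PMI estimation.

    ``word_doc_freq[w]`` counts documents containing ``w`` at least once;
    ``pair_doc_freq[frozenset({a,b})]`` counts documents containing both.
    Probabilities are these frequencies divided by ``doc_count``.
    """

    doc_count: int
    word_doc_freq: Mapping[str, int]
    pair_doc_freq: Mapping[frozenset, int]

    def p_word(self, w: str) -> float:
        return self.word_doc_freq.get(w, 0) / self.doc_count

    def p_pair(self, a: str, b: str) -> float:
        if a == b:
            return self.p_word(a)
        return self.pair_doc_freq.get(frozenset((a, b)), 0) / self.doc_count


def build_corpus_stats(
    documents: Iterable[Iterable[str]],
    vocabulary: set[str] | None = None,
) -> CorpusStats:
    """Count document frequencies over token documents.

    ``vocabulary`` restricts pair counting (pairs are quadratic in distinct
    words per document); single-word frequencies are always complete.
    """
    word_freq: Counter = Counter()
    pair_freq: Counter = Counter()
    n = 0
    for doc in documents:
        n += 1
        words = set(doc)
        word_freq.update(words)
        pool = sorted(words & vocabulary) if vocabulary is not None else sorted(words)
        for a, b in combinations(pool, 2):
            pair_freq[frozenset((a, b))] += 1
    return CorpusStats(n, dict(word_freq), dict(pair_freq))


@dataclass(frozen=True)
class FeatureVector:
    """F1..F8 classification features plus the regulatory feature F9."""

    f1_subject_relevance: float
    f2_feature_word_count: int
    f3_clause_count: int
    f4_effective_length: float
    f5_emotional_intensity: float
    f6_publisher_name: int
    f7_publisher_level: int
    f8_history_amount: int
    f9_false_history: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f4_effective_length <= 1.0:
            raise ValueError("f4 must be in [0,1]")
        if not 0.0 <= self.f5_emotional_intensity <= 1.0:
            raise ValueError("f5 must be in [0,1]")
        if self.f6_publisher_name not in (0, 1):
            raise ValueError("f6 must be 0 or 1")
        if self.f7_publisher_level not in (1, 2, 3):
            raise ValueError("f7 must be in {1,2,3}")
        if not 0.0 <= self.f9_false_history <= 1.0:
            raise ValueError("f9 must be in [0,1]")

    def classification_values(self) -> tuple[float, ...]:
        """The 8 classification features, F9 excluded."""
        return (
            self.f1_subject_relevance,
            float(self.f2_feature_word_count),
            float(self.f3_clause_count),
            self.f4_effective_length,
            self.f5_emotional_intensity,
            float(self.f6_publisher_name),
            float(self.f7_publisher_level),
            float(self.f8_history_amount),
        )

    def values(self) -> tuple[float, ...]:
        return self.classification_values() + (self.f9_false_history,)


def pmi(word_a: str, word_b: str, stats: CorpusStats, smoothing: float = 0.0) -> float:
    """Pointwise mutual information log p(a,b) / (p(a) p(b)).

    Probabilities are document frequencies over ``stats.doc_count`` with
    additive smoothing ``smoothing`` on each probability; natural log.
    Symmetric in its word arguments.
    """
    if stats.doc_count <= 0:
        raise ValueError("corpus statistics are empty (doc_count = 0)")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    pa = stats.p_word(word_a) + smoothing
    pb = stats.p_word(word_b) + smoothing
    pab = stats.p_pair(word_a, word_b) + smoothing
    if pab == 0.0 or pa == 0.0 or pb == 0.0:
        return -math.inf
    return math.log(pab / (pa * pb))


def f1_subject_relevance(
    message: Message,
    feature_words: Sequence[str],
    stats: CorpusStats,
    smoothing: float = 0.0,
) -> float:
    """Subject relevance: mean positive PMI over all (noun, feature word) pairs.

    Negative PMI encodes topical irrelevance and is clipped at zero; a
    message without nouns scores 0.
    """
    if not feature_words:
        raise ValueError("feature word list must be nonempty")
    nouns = message.nouns()
    if not nouns:
        return 0.0
    total = 0.0
    count = 0
    for n_word in nouns:
        for f_word in feature_words:
            v = pmi(n_word, f_word, stats, smoothing)
            total += max(v, 0.0)
            count += 1
    return total / count


def text_structure_features(message: Message) -> tuple[int, int, float]:
    """(W, S, E/T): feature-word count, clause count, effective length ratio.

    W counts tokens tagged noun/verb/adjective/adverb across all clauses;
    the ratio is 0 when the raw character count is 0.
    """
    content_tags = {"noun", "verb", "adjective", "adverb"}
    w = sum(1 for _, p in message.tokens() if p in content_tags)
    s = len(message.clauses)
    ratio = (
        message.effective_char_count / message.raw_char_count
        if message.raw_char_count > 0
        else 0.0
    )
    return w, s, ratio


def f5_emotional_intensity(message: Message) -> float:
    """P/(P+R) over positive vs negative evaluation clauses.

    Neutral clauses are excluded; a fully neutral message returns 0.5
    (maximally non-extreme), since extremes in either direction are what
    signal over-praise or over-belittlement.
    """
    p = sum(1 for c in message.clauses if c.polarity == "positive")
    r = sum(1 for c in message.clauses if c.polarity == "negative")
    if p + r == 0:
        return 0.5
    return p / (p + r)


def publisher_features(publisher: Publisher) -> tuple[int, int, int]:
    """(F6, F7, F8): real-name indicator, platform tier, history volume."""
    return (
        int(publisher.name_is_real),
        publisher.platform_tier,
        publisher.history_count,
    )


def update_false_history(
    publisher: Publisher, classified: Sequence[str]
) -> Publisher:
    """Raise the publisher's false-history probability from classifier output.

    The probability becomes the fraction of the publisher's classified
    messages labelled ``false_info`` (0 when nothing has been classified —
    the initial state).
    """
    if not classified:
        prob = 0.0
    else:
        prob = sum(1 for c in classified if c == "false_info") / len(classified)
    return Publisher(
        publisher_id=publisher.publisher_id,
        name_is_real=publisher.name_is_real,
        platform_tier=publisher.platform_tier,
        history_count=publisher.history_count,
        false_history_prob=prob,
    )


def eliminate_publishers(corpus: Corpus, theta: float = 0.5) -> Corpus:
    """Remove all messages of publishers whose false-history probability >= theta.

    Idempotent, and monotone in theta: a larger threshold removes a subset
    of what a smaller one removes.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0,1], got {theta}")
    flagged = {
        pid for pid, p in corpus.publishers.items() if p.false_history_prob >= theta
    }
    kept = [m for m in corpus.messages if m.publisher_id not in flagged]
    return corpus.with_messages(kept)


def extract_features(
    message: Message,
    publisher: Publisher,
    feature_words: Sequence[str],
    stats: CorpusStats,
    smoothing: float = 0.0,
) -> FeatureVector:
    """Assemble the full F1..F9 vector for one message."""
    f1 = f1_subject_relevance(message, feature_words, stats, smoothing)
    w, s, ratio = text_structure_features(message)
    f5 = f5_emotional_intensity(message)
    f6, f7, f8 = publisher_features(publisher)
    return FeatureVector(
        f1_subject_relevance=f1,
        f2_feature_word_count=w,
        f3_clause_count=s,
        f4_effective_length=ratio,
        f5_emotional_intensity=f5,
        f6_publisher_name=f6,
        f7_publisher_level=f7,
        f8_history_amount=f8,
        f9_false_history=publisher.false_history_prob,
    )


def feature_matrix(
    corpus: Corpus,
    feature_words: Sequence[str],
    stats: CorpusStats,
    smoothing: float = 0.0,
    include_f9: bool = False,
) -> pd.DataFrame:
    """Feature table for a corpus: one row per message, columns f1..f9 (+label).

    ``include_f9`` controls whether F9 is meant for the classifier; the
    column is always present so exports carry the full Table-1 system, but
    downstream training selects columns.
    """
    rows = []
    for m in corpus.messages:
        fv = extract_features(
            m, corpus.publishers[m.publisher_id], feature_words, stats, smoothing
        )
        rows.append(fv.values() + (m.label,))
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])
    df.index = pd.Index([m.message_id for m in corpus.messages], name="message_id")
    df.attrs["classifier_features"] = list(
        FEATURE_NAMES if include_f9 else FEATURE_NAMES[:8]
    )
    return df
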