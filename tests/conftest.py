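"""Shared fixtures: tiny hand-built corpora with known counts."""

from datetime import date

import pytest
from hypothesis import settings

from epiwatch.corpus import Clause, Corpus, Message, Publisher

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


def make_clause(tokens, polarity="neutral"):
    """tokens: list of (word, pos) or plain words (tagged noun)."""
    toks = tuple(
        (t, "noun") if isinstance(t, str) else tuple(t) for t in tokens
    )
    return Clause(toks, polarity)


def make_message(
    mid="m1",
    publisher_id="p1",
    day=date(2020, 2, 4),
    clauses=(),
    raw=100,
    effective=80,
    places=(),
    label=None,
):
    return Message(
        message_id=mid,
        publisher_id=publisher_id,
        timestamp=day,
        clauses=tuple(clauses),
        raw_char_count=raw,
        effective_char_count=effective,
        places=tuple(places),
        label=label,
    )


@pytest.fixture
def publishers():
    return {
        "p1": Publisher("p1", name_is_real=True, platform_tier=3, history_count=120),
        "p2": Publisher("p2", name_is_real=False, platform_tier=1, history_count=0),
    }


@pytest.fixture
def small_corpus(publishers):
    """3 messages from 2 publishers, mixed content."""
    msgs = [
        make_message(
            "m1", "p1", date(2020, 2, 4),
            clauses=[
                make_clause([("virus", "noun"), ("spreads", "verb")], "negative"),
                make_clause([("mask", "noun"), ("helps", "verb")], "positive"),
            ],
            raw=100, effective=80, places=["city_00a"], label="true_info",
        ),
        make_message(
            "m2", "p1", date(2020, 2, 5),
            clauses=[make_clause([("vaccine", "noun")], "positive")],
            raw=50, effective=40, places=[], label="true_info",
        ),
        make_message(
            "m3", "p2", date(2020, 2, 5),
            clauses=[
                make_clause([("miracle", "noun"), ("cure", "noun")], "positive"),
            ],
            raw=60, effective=20, places=["city_01b"], label="false_info",
        ),
    ]
    return Corpus(msgs, publishers)
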