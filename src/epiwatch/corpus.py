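"""Data model and JSON-lines I/O for annotated epidemic message corpora.

A corpus bundles three record kinds:

* :class:`Message` — one item of epidemic information, carrying pre-annotated
  clauses (tokens with coarse part-of-speech tags and a clause-level
  evaluation polarity), character counts, place mentions, a timestamp and an
  optional truth label;
* :class:`Publisher` — the account that released a message, with the
  behavioural attributes used as classification features (real-name flag,
  platform tier, history volume) plus the running false-history probability;
* :class:`WebPage` — a node of the web-link graph from which reliable
  sources are scored.

Annotations (segmentation, POS tags, clause polarity) are *input data*: real
deployments plug in their own tagger. :func:`annotate_text` is a deliberately
naive lexicon-lookup baseline for raw text, provided so the package is
runnable end to end without any NLP dependency.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "POS_TAGS",
    "POLARITIES",
    "WebPage",
    "Publisher",
    "Clause",
    "Message",
    "Corpus",
    "CorpusError",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "read_link_graph",
    "write_link_graph",
    "annotate_text",
    "effective_char_count",
]

POS_TAGS = ("noun", "verb", "adjective", "adverb", "other")
POLARITIES = ("positive", "negative", "neutral")

#: characters that do not carry information content; used when counting the
#: "effective" length of a message.  Whitespace, punctuation and URLs are
#: invalid by default; the list is configurable via ``invalid_patterns``.
DEFAULT_INVALID_PATTERNS = (
    r"https?://\S+",
    r"\s",
    r"[^\w一-鿿]",
)


class CorpusError(Exception):
    """Base class for corpus I/O and validation failures."""


class CorpusParseError(CorpusError):
    """A line of a corpus file is not well-formed JSON or lacks fields."""


class CorpusValidationError(CorpusError):
    """A structurally parsed corpus violates a model invariant."""


@dataclass(frozen=True)
class WebPage:
    """One node of the web-link graph.

    ``out_links`` holds the page ids this page links to.  Self-links and
    links to unknown pages are removed during transfer-matrix construction,
    not here, so round-trips preserve the file content.
    """

    page_id: int
    url: str
    out_links: frozenset[int] = frozenset()
    text: str = ""

    def __post_init__(self) -> None:
        if self.page_id < 1:
            raise CorpusValidationError(f"page_id must be >= 1, got {self.page_id}")
        object.__setattr__(self, "out_links", frozenset(self.out_links))


@dataclass(frozen=True)
class Publisher:
    """Account metadata behind the publisher-behaviour features.

    ``false_history_prob`` is the regulatory state: the running probability
    that this publisher releases false information.  It starts at 0 for every
    unseen publisher and is raised as the classifier flags their messages.
    """

    publisher_id: str
    name_is_real: bool
    platform_tier: int
    history_count: int = 0
    false_history_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.platform_tier not in (1, 2, 3):
            raise CorpusValidationError(
                f"platform_tier must be in {{1,2,3}}, got {self.platform_tier}"
            )
        if self.history_count < 0:
            raise CorpusValidationError("history_count must be >= 0")
        if not 0.0 <= self.false_history_prob <= 1.0:
            raise CorpusValidationError("false_history_prob must be in [0,1]")


@dataclass(frozen=True)
class Clause:
    """One clause: ordered (token, pos) pairs plus an evaluation polarity."""

    tokens: tuple[tuple[str, str], ...]
    polarity: str = "neutral"

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise CorpusValidationError(f"unknown polarity {self.polarity!r}")
        norm = []
        for tok, pos in self.tokens:
            if pos not in POS_TAGS:
                raise CorpusValidationError(f"unknown POS tag {pos!r}")
            norm.append((str(tok), pos))
        object.__setattr__(self, "tokens", tuple(norm))

    def nouns(self) -> tuple[str, ...]:
        return tuple(t for t, p in self.tokens if p == "noun")


@dataclass(frozen=True)
class Message:
    message_id: str
    publisher_id: str
    timestamp: date
    clauses: tuple[Clause, ...] = ()
    raw_char_count: int = 0
    effective_char_count: int = 0
    places: tuple[str, ...] = ()
    label: str | None = None  # "true_info" | "false_info" | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "clauses", tuple(self.clauses))
        object.__setattr__(self, "places", tuple(self.places))
        if self.effective_char_count > self.raw_char_count:
            raise CorpusValidationError(
                f"message {self.message_id}: effective_char_count "
                f"{self.effective_char_count} > raw_char_count {self.raw_char_count}"
            )
        if self.raw_char_count < 0:
            raise CorpusValidationError("raw_char_count must be >= 0")
        if self.label not in (None, "true_info", "false_info"):
            raise CorpusValidationError(f"unknown label {self.label!r}")

    def nouns(self) -> list[str]:
        """All nouns of the message in clause order (the subject list)."""
        out: list[str] = []
        for c in self.clauses:
            out.extend(c.nouns())
        return out

    def tokens(self) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for c in self.clauses:
            out.extend(c.tokens)
        return out


@dataclass
class Corpus:
    """Messages + publishers (+ optional link graph) as one unit of work."""

    messages: list[Message] = field(default_factory=list)
    publishers: dict[str, Publisher] = field(default_factory=dict)
    pages: list[WebPage] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for m in self.messages:
            if m.publisher_id not in self.publishers:
                raise CorpusValidationError(
                    f"message {m.message_id} references unknown publisher "
                    f"{m.publisher_id!r}"
                )
        ids = [m.message_id for m in self.messages]
        if len(set(ids)) != len(ids):
            raise CorpusValidationError("duplicate message_id in corpus")
        if self.pages is not None:
            pids = [p.page_id for p in self.pages]
            if len(set(pids)) != len(pids):
                raise CorpusValidationError("duplicate page_id in corpus")

    def with_messages(self, messages: Sequence[Message]) -> "Corpus":
        return Corpus(list(messages), dict(self.publishers), self.pages)

    def with_publishers(self, publishers: Mapping[str, Publisher]) -> "Corpus":
        return Corpus(list(self.messages), dict(publishers), self.pages)

    def __len__(self) -> int:
        return len(self.messages)


# ---------------------------------------------------------------------------
# serialization

def _clause_to_json(c: Clause) -> dict:
    return {"tokens": [[t, p] for t, p in c.tokens], "polarity": c.polarity}


def _message_to_json(m: Message) -> dict:
    return {
        "kind": "message",
        "message_id": m.message_id,
        "publisher_id": m.publisher_id,
        "timestamp": m.timestamp.isoformat(),
        "clauses": [_clause_to_json(c) for c in m.clauses],
        "raw_char_count": m.raw_char_count,
        "effective_char_count": m.effective_char_count,
        "places": list(m.places),
        "label": m.label,
    }


def _publisher_to_json(p: Publisher) -> dict:
    return {
        "kind": "publisher",
        "publisher_id": p.publisher_id,
        "name_is_real": p.name_is_real,
        "platform_tier": p.platform_tier,
        "history_count": p.history_count,
        "false_history_prob": p.false_history_prob,
    }


_REQUIRED_MESSAGE_FIELDS = ("message_id", "publisher_id", "timestamp")


def _parse_timestamp(raw: str) -> date:
    try:
        return date.fromisoformat(raw)
    except ValueError:
        return datetime.fromisoformat(raw).date()


def _message_from_json(rec: dict, lineno: int) -> Message:
    for f in _REQUIRED_MESSAGE_FIELDS:
        if f not in rec or rec[f] is None:
            raise CorpusValidationError(
                f"line {lineno}: message record missing field {f!r}"
            )
    try:
        ts = _parse_timestamp(rec["timestamp"])
    except (ValueError, TypeError) as exc:
        raise CorpusValidationError(
            f"line {lineno}: unparseable timestamp {rec['timestamp']!r}"
        ) from exc
    clauses = tuple(
        Clause(tuple((t, p) for t, p in c["tokens"]), c.get("polarity", "neutral"))
        for c in rec.get("clauses", [])
    )
    return Message(
        message_id=str(rec["message_id"]),
        publisher_id=str(rec["publisher_id"]),
        timestamp=ts,
        clauses=clauses,
        raw_char_count=int(rec.get("raw_char_count", 0)),
        effective_char_count=int(rec.get("effective_char_count", 0)),
        places=tuple(rec.get("places", [])),
        label=rec.get("label"),
    )


def _publisher_from_json(rec: dict, lineno: int) -> Publisher:
    for f in ("publisher_id", "name_is_real", "platform_tier"):
        if f not in rec:
            raise CorpusValidationError(
                f"line {lineno}: publisher record missing field {f!r}"
            )
    return Publisher(
        publisher_id=str(rec["publisher_id"]),
        name_is_real=bool(rec["name_is_real"]),
        platform_tier=int(rec["platform_tier"]),
        history_count=int(rec.get("history_count", 0)),
        false_history_prob=float(rec.get("false_history_prob", 0.0)),
    )


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus file (messages and publishers interleaved).

    Each line is one record with a ``kind`` of ``"message"`` or
    ``"publisher"``.  Unknown fields are preserved in spirit but ignored.

    Raises
    ------
    CorpusParseError
        if a line is not valid JSON, naming the line number.
    CorpusValidationError
        if a record lacks required fields or a message references an
        unknown publisher.
    """
    path = Path(path)
    messages: list[Message] = []
    publishers: dict[str, Publisher] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {lineno}: malformed JSON: {exc}") from exc
            kind = rec.get("kind", "message")
            if kind == "publisher":
                p = _publisher_from_json(rec, lineno)
                publishers[p.publisher_id] = p
            elif kind == "message":
                messages.append(_message_from_json(rec, lineno))
            else:
                raise CorpusValidationError(f"line {lineno}: unknown kind {kind!r}")
    return Corpus(messages, publishers)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus as JSON lines; publishers first, then messages.

    ``read_corpus(write_corpus(c))`` reproduces ``c`` field for field.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus.publishers.values():
            fh.write(json.dumps(_publisher_to_json(p), ensure_ascii=False) + "\n")
        for m in corpus.messages:
            fh.write(json.dumps(_message_to_json(m), ensure_ascii=False) + "\n")


def read_link_graph(path: str | Path) -> list[WebPage]:
    """Read a JSON-lines link-graph file of WebPage records."""
    path = Path(path)
    pages: list[WebPage] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {lineno}: malformed JSON: {exc}") from exc
            if "page_id" not in rec:
                raise CorpusValidationError(f"line {lineno}: missing page_id")
            pages.append(
                WebPage(
                    page_id=int(rec["page_id"]),
                    url=str(rec.get("url", "")),
                    out_links=frozenset(int(x) for x in rec.get("out_links", [])),
                    text=str(rec.get("text", "")),
                )
            )
    seen = [p.page_id for p in pages]
    if len(set(seen)) != len(seen):
        raise CorpusValidationError("duplicate page_id in link graph")
    return pages


def write_link_graph(pages: Iterable[WebPage], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in pages:
            rec = {
                "page_id": p.page_id,
                "url": p.url,
                "out_links": sorted(p.out_links),
                "text": p.text,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# naive fallback annotator

def effective_char_count(
    text: str, invalid_patterns: Sequence[str] = DEFAULT_INVALID_PATTERNS
) -> int:
    """Count characters that survive removal of the invalid-character patterns.

    Counting is in Unicode code points.  Whitespace, punctuation and URL
    substrings are invalid by default.
    """
    cleaned = text
    for pat in invalid_patterns:
        cleaned = re.sub(pat, "", cleaned)
    return len(cleaned)


_CLAUSE_SPLIT = re.compile(r"[.!?;,。！？；，\n]+")


def annotate_text(
    text: str,
    pos_lexicon: Mapping[str, str],
    sentiment_lexicon: Mapping[str, int],
    invalid_patterns: Sequence[str] = DEFAULT_INVALID_PATTERNS,
) -> tuple[tuple[Clause, ...], int, int]:
    """Baseline annotator: lexicon lookup for POS, lexicon sign for polarity.

    This is a deliberately simple stand-in for a production tagger: clauses
    are split on sentence-internal punctuation, each token's POS comes from
    ``pos_lexicon`` (default ``other``), and clause polarity is the sign of
    the summed sentiment-lexicon hits (ties are neutral).

    Returns ``(clauses, raw_char_count, effective_char_count)``.
    """
    clauses: list[Clause] = []
    for chunk in _CLAUSE_SPLIT.split(text):
        words = chunk.split()
        if not words:
            continue
        toks = tuple((w, pos_lexicon.get(w, "other")) for w in words)
        score = sum(sentiment_lexicon.get(w, 0) for w in words)
        pol = "positive" if score > 0 else "negative" if score < 0 else "neutral"
        clauses.append(Clause(toks, pol))
    return tuple(clauses), len(text), effective_char_count(text, invalid_patterns)
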