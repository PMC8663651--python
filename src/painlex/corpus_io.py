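"""Post records, text cleaning, and the two relevance filters.

Cleaning removes @-mentions, hyperlinks, and symbol runs, lowercases, and
keeps hashtag words with the ``#`` stripped. Round 1 keeps posts where
``pain`` and a target descriptor lie within a hop limit of each other on
the post's word graph; round 2 requires a descriptor together with a
pain-condition mention.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .word_graph import build_word_graph, within_hops

_MENTION_RE = re.compile(r"@\w+")
_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.co/\S+)", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


@dataclass
class Post:
    """One social-media record.

    ``tokens`` is empty until :func:`clean_posts` (or ``with_tokens``)
    has been applied; downstream filters require it populated.
    """

    id: str
    platform: str
    timestamp: str
    text: str
    tokens: list = field(default_factory=list)

    def with_tokens(self) -> "Post":
        """Return a copy with ``tokens`` populated from ``text``."""
        return replace(self, tokens=clean_text(self.text))


@dataclass
class FilterConfig:
    """Configuration for the relevance filters.

    ``hop_limit`` is inclusive ("within 3 hops" keeps distance 3);
    ``window`` is the word-graph adjacency window.
    """

    descriptor_list: list = field(default_factory=list)
    condition_list: list = field(default_factory=list)
    hop_limit: int = 3
    window: int = 1
    manual_exclusions: list = field(default_factory=list)

    def __post_init__(self):
        if self.hop_limit < 1:
            raise ValueError(f"hop_limit must be >= 1, got {self.hop_limit}")


def clean_text(raw: str) -> list:
    """Tokenize *raw* into lowercase word tokens.

    Usernames (``@name``), URLs (http/https/www/t.co forms) and runs of
    non-alphanumeric symbols are dropped; hashtag words survive with the
    ``#`` stripped. Idempotent: cleaning already-clean text is a no-op.

    >>> clean_text("@bob my back pain is UNBEARABLE http://t.co/x")
    ['my', 'back', 'pain', 'is', 'unbearable']
    """
    if not raw:
        return []
    text = raw.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    return _TOKEN_RE.findall(text)


def clean_posts(posts: Iterable[Post]) -> list:
    """Populate tokens on every post; returns new Post objects."""
    return [p.with_tokens() for p in posts]


def _phrase_tokens(term: str) -> list:
    return term.lower().split()


def contains_phrase(tokens: Sequence[str], term: str) -> bool:
    """Whole-token, phrase-aware membership test.

    A multiword term matches only as a run of consecutive tokens.
    """
    words = _phrase_tokens(term)
    if not words:
        return False
    if len(words) == 1:
        return words[0] in tokens
    n = len(words)
    return any(list(tokens[i : i + n]) == words for i in range(len(tokens) - n + 1))


def relevance_filter_round1(post: Post, cfg: FilterConfig) -> bool:
    """Round-1 inclusion: ``pain`` plus a descriptor within the hop limit.

    Multiword descriptors must appear as consecutive tokens; the hop
    distance is measured from the phrase head.
    """
    if not cfg.descriptor_list:
        raise ValueError("descriptor_list must be non-empty for round-1 filtering")
    if "pain" not in post.tokens:
        return False
    graph = build_word_graph(post.tokens, window=cfg.window)
    for term in cfg.descriptor_list:
        if not contains_phrase(post.tokens, term):
            continue
        head = _phrase_tokens(term)[0]
        if within_hops(graph, "pain", head, cfg.hop_limit):
            return True
    return False


def relevance_filter_round2(post: Post, cfg: FilterConfig) -> bool:
    """Round-2 inclusion: at least one descriptor AND one pain condition."""
    if not cfg.descriptor_list:
        raise ValueError("descriptor_list must be non-empty for round-2 filtering")
    if not cfg.condition_list:
        raise ValueError("condition_list must be non-empty for round-2 filtering")
    has_descriptor = any(contains_phrase(post.tokens, d) for d in cfg.descriptor_list)
    if not has_descriptor:
        return False
    return any(contains_phrase(post.tokens, c) for c in cfg.condition_list)


def apply_manual_exclusions(posts: Sequence[Post], cfg: FilterConfig):
    """Partition posts into (kept, removed, removal_log).

    Each exclusion entry is a regex tried as a full match on the post id
    and as a search over the raw text (encoding the study's manual
    scrutiny as configuration). The log maps removed post id -> the
    pattern that fired.
    """
    compiled = []
    for pattern in cfg.manual_exclusions:
        try:
            compiled.append((pattern, re.compile(pattern)))
        except re.error as exc:
            raise ValueError(f"malformed exclusion pattern {pattern!r}: {exc}") from exc
    kept, removed, log = [], [], {}
    for post in posts:
        hit = None
        for pattern, rx in compiled:
            if rx.fullmatch(post.id) or rx.search(post.text):
                hit = pattern
                break
        if hit is None:
            kept.append(post)
        else:
            removed.append(post)
            log[post.id] = hit
    return kept, removed, log


# ---------------------------------------------------------------------------
# I/O


def write_posts_jsonl(posts: Iterable[Post], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in posts:
            rec = {"id": p.id, "platform": p.platform, "timestamp": p.timestamp, "text": p.text}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_posts_jsonl(path) -> list:
    posts = []
    seen = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if not rec.get("id"):
                raise ValueError("post record missing non-empty id")
            if rec["id"] in seen:
                raise ValueError(f"duplicate post id {rec['id']!r}")
            seen.add(rec["id"])
            posts.append(
                Post(
                    id=str(rec["id"]),
                    platform=rec.get("platform", ""),
                    timestamp=rec.get("timestamp", ""),
                    text=rec.get("text", ""),
                )
            )
    return posts


def write_posts_csv(posts: Iterable[Post], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "platform", "timestamp", "text"])
        for p in posts:
            writer.writerow([p.id, p.platform, p.timestamp, p.text])


def read_posts_csv(path) -> list:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        return [
            Post(id=row["id"], platform=row["platform"], timestamp=row["timestamp"], text=row["text"])
            for row in csv.DictReader(fh)
        ]
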