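"""Rule-based sarcasm scoring on [0,1] and the strict >threshold removal.

The study's trained classifier is proprietary; this module keeps its
contract (a deterministic [0,1] rating, posts strictly above the
threshold removed) behind a pluggable scorer. The default scorer sums
weighted surface features and squashes the activation through
``2 / (1 + exp(-a)) - 1``, which anchors zero activation at exactly 0.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus_io import Post

_INTERJECTIONS = frozenset(
    {"yeah", "right", "sure", "totally", "obviously", "wow", "oh", "gee", "bravo"}
)
_POSITIVE = frozenset(
    {"love", "loving", "great", "awesome", "fantastic", "wonderful", "perfect", "best", "thrilled"}
)
_NEGATIVE_CONTEXT = frozenset(
    {"pain", "hurt", "hurts", "broken", "worst", "hate", "terrible", "awful", "sick", "agony"}
)
_ELONGATED_RE = re.compile(r"([a-zA-Z])\1{2,}")
_BURST_RE = re.compile(r"(!{2,}|\?!|!\?)")
_SCARE_QUOTE_RE = re.compile(r"\"\w+\"|'\w+'(?!\w)")

DEFAULT_FEATURE_WEIGHTS = {
    "marker_hits": 2.0,
    "interjections": 0.6,
    "elongated": 0.5,
    "punct_bursts": 0.4,
    "scare_quotes": 0.5,
    "juxtaposition": 0.8,
}


@dataclass
class SarcasmConfig:
    threshold: float = 0.7
    scorer: str = "default"
    feature_weights: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_WEIGHTS))
    markers: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0,1], got {self.threshold}")


@dataclass
class SarcasmScore:
    post_id: str
    rating: float
    feature_trace: dict = field(default_factory=dict)


def squash(activation: float) -> float:
    """Map a non-negative activation to [0,1); squash(0) == 0 exactly."""
    return 2.0 / (1.0 + math.exp(-activation)) - 1.0


def extract_features(post: Post, cfg: SarcasmConfig) -> dict:
    """Raw feature counts for the default scorer (tokens + raw text)."""
    tokens = post.tokens
    marker_tokens = {t for m in cfg.markers for t in m.lower().split()}
    return {
        "marker_hits": sum(1 for t in tokens if t in marker_tokens),
        "interjections": sum(1 for t in tokens if t in _INTERJECTIONS),
        "elongated": len(_ELONGATED_RE.findall(post.text)),
        "punct_bursts": len(_BURST_RE.findall(post.text)),
        "scare_quotes": len(_SCARE_QUOTE_RE.findall(post.text)),
        "juxtaposition": int(
            any(t in _POSITIVE for t in tokens) and any(t in _NEGATIVE_CONTEXT for t in tokens)
        ),
    }


def _default_scorer(post: Post, cfg: SarcasmConfig) -> SarcasmScore:
    if not post.tokens:
        return SarcasmScore(post_id=post.id, rating=0.0, feature_trace={})
    features = extract_features(post, cfg)
    trace = {
        name: cfg.feature_weights.get(name, 0.0) * count
        for name, count in features.items()
    }
    activation = sum(trace.values())
    return SarcasmScore(post_id=post.id, rating=squash(activation), feature_trace=trace)


_SCORERS: dict[str, Callable[[Post, SarcasmConfig], SarcasmScore]] = {
    "default": _default_scorer,
}


def register_scorer(name: str, fn: Callable[[Post, SarcasmConfig], SarcasmScore]) -> None:
    """Register a replacement scorer (e.g. a trained classifier wrapper)."""
    _SCORERS[name] = fn


def score_sarcasm(post: Post, cfg: SarcasmConfig) -> SarcasmScore:
    """Deterministic sarcasm rating in [0,1] for one cleaned post."""
    try:
        scorer = _SCORERS[cfg.scorer]
    except KeyError:
        raise ValueError(f"unknown sarcasm scorer {cfg.scorer!r}") from None
    score = scorer(post, cfg)
    if not 0.0 <= score.rating <= 1.0:
        raise ValueError(f"scorer produced out-of-range rating {score.rating}")
    return score


def filter_sarcastic(posts: Sequence[Post], cfg: SarcasmConfig):
    """Partition posts into (kept, removed, scores).

    A post is removed iff its rating is STRICTLY greater than the
    threshold — a rating of exactly 0.70 survives the default 0.7 cut.
    """
    kept, removed, scores = [], [], []
    for post in posts:
        score = score_sarcasm(post, cfg)
        scores.append(score)
        if score.rating > cfg.threshold:
            removed.append(post)
        else:
            kept.append(post)
    return kept, removed, scores


def write_scores_csv(scores: Iterable[SarcasmScore], cfg: SarcasmConfig, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "rating", "removed_flag"])
        for s in scores:
            writer.writerow([s.post_id, f"{s.rating:.6f}", int(s.rating > cfg.threshold)])
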